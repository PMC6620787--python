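"""Community overview: screening, alpha diversity, Venn partition, core OTUs.

Reads the simulated OTU table, applies the low-occupancy screen
(>= 2 samples and >= 20 reads), rarefies to the minimum sample depth for
Shannon/observed-OTU diversity, partitions OTUs across the W / Y / mature
groups, calls the mature core microbiome at >95% prevalence, and builds
the core-OTU Spearman correlation network (BH-FDR at 0.05).
"""

import json
from pathlib import Path

import pandas as pd

from daquscope.otu_core import (
    alpha_diversity,
    filter_low_occupancy,
    prevalence_core,
    read_otu_table,
    venn_partition,
    write_otu_table,
)
from daquscope.stats import core_correlation_network

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20190702


def main() -> None:
    table = read_otu_table(OUT / "otu_table.tsv", OUT / "metadata.tsv")
    screened = filter_low_occupancy(table)
    print(f"screen: {table.n_otus} -> {screened.n_otus} OTUs "
          f"(>=2 samples and >=20 reads)")
    write_otu_table(screened, OUT / "otu_table.screened.tsv")

    depth = int(screened.counts.sum(axis=0).min())
    div = alpha_diversity(screened, depth=depth, seed=SEED)
    div["group"] = screened.metadata.loc[div.index, "group"]
    div.to_csv(OUT / "alpha_diversity.tsv", sep="\t")
    print(f"alpha diversity at depth {depth}: mean Shannon "
          f"{div['shannon'].mean():.2f} bits, "
          f"mean observed OTUs {div['observed_otus'].mean():.0f}")

    grouping = screened.metadata.loc[screened.sample_ids, "supergroup"].to_dict()
    venn = venn_partition(screened, grouping, groups=["W", "Y", "mature"])
    regions = {"&".join(sorted(k)): v for k, v in venn.region_counts.items()}
    with open(OUT / "venn.json", "w") as fh:
        json.dump({"regions": regions, "totals": venn.group_totals}, fh, indent=1)
    shared = venn.region_counts.get(frozenset(["W", "Y", "mature"]), 0)
    print(f"venn: totals {venn.group_totals}; shared by all three groups: {shared}")

    mature = screened.samples_in_group("B0", "B1", "B2", "B3", "B4", "B5")
    core = prevalence_core(screened, mature, threshold=0.95)
    print(f"mature core (>95% of {len(mature)} samples): "
          f"{len(core.core_otu_ids)} OTUs")
    pd.Series(core.prevalence).loc[core.core_otu_ids].rename("prevalence").to_csv(
        OUT / "core_otus.tsv", sep="\t"
    )

    if len(core.core_otu_ids) >= 2:
        net = core_correlation_network(screened.select_samples(mature), core)
        net.rho.to_csv(OUT / "core_network_rho.tsv", sep="\t")
        net.p_adjusted.to_csv(OUT / "core_network_padj.tsv", sep="\t")
        n_sig = int(net.significant.to_numpy().sum() // 2)
        print(f"core network: {n_sig} significant pairs of "
              f"{len(core.core_otu_ids) * (len(core.core_otu_ids) - 1) // 2} "
              f"(BH-FDR <= 0.05)")


if __name__ == "__main__":
    main()
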