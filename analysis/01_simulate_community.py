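"""Generate the synthetic starter-community dataset used by the 16S analyses.

Emulates the study design: two immature starter groups (white W and
yellow Y, 27 samples each) and six mature batches B0-B5 (131 samples),
300 OTUs, Dirichlet-multinomial counts at depths above the 988-read
rarefaction floor.  Five marker OTUs are spiked 8-fold (log2FC = 3) in
the yellow group, and a handful of OTUs are made exclusive to single
groups so the Venn regions are non-trivial.

Writes the OTU table, sample metadata and the ground-truth registry to
results/.
"""

import json
from pathlib import Path

from daquscope.otu_core import write_otu_table
from daquscope.simulate import CommunitySpec, simulate_community, simulate_properties

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20190701


def build_spec(seed: int = SEED) -> CommunitySpec:
    return CommunitySpec(
        n_otus=300,
        markers=[(i, "Y", 3.0) for i in range(5)],
        exclusives=[(10, "W"), (11, "Y"), (12, "B0"), (13, "B3")],
        seed=seed,
    )


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table, truth = simulate_community(build_spec())
    write_otu_table(table, OUT / "otu_table.tsv", OUT / "metadata.tsv")
    truth.to_json(OUT / "community_truth.json")

    mature = table.select_samples(
        table.samples_in_group("B0", "B1", "B2", "B3", "B4", "B5")
    )
    # plant property links on prevalent OTUs: Spearman targets are only
    # well-defined without heavy zero-count ties
    prevalence = (mature.counts > 0).mean(axis=1).sort_values(ascending=False)
    dense = [o for o in prevalence.index if not o.startswith("OTU0000")][:2]
    props, prop_truth = simulate_properties(
        mature,
        links=[(dense[0], "SA", 0.6), (dense[1], "AC", -0.5)],
        seed=SEED + 1,
    )
    props.to_csv(OUT / "properties.tsv", sep="\t")
    prop_truth.to_json(OUT / "properties_truth.json")

    print(f"community: {table.n_otus} OTUs x {table.n_samples} samples")
    print(f"groups: {table.metadata['group'].value_counts().to_dict()}")
    print(f"spiked markers: {[m[0] for m in truth.marker_otus]}")
    print(f"properties: {props.shape[0]} mature samples x {props.shape[1]} indices")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
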