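"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its spec and seed, and emits a
:class:`TruthRecord` describing what was planted (marker OTUs, LCA
assignments, EC mass ratios, OTU-property correlations) so recovery can
be measured without re-reading any configuration.

The community generator emulates the starter-study design: grouped
compositional count data (Dirichlet-multinomial) with optional spiked
fold-changes and group-exclusive OTUs; its defaults mirror the study's
shape — two immature groups of 27 samples (white W, yellow Y) and six
mature batches totalling 131 samples, with sequencing depths drawn above
the 988-read rarefaction floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu_core import OtuTable
from .taxonomy import RANKS, TaxonomyTree, HitRecord

__all__ = [
    "CommunitySpec",
    "TruthRecord",
    "DEFAULT_GROUPS",
    "simulate_community",
    "simulate_taxonomy",
    "simulate_hits",
    "hits_to_frame",
    "write_hits",
    "write_taxonomy",
    "simulate_gene_profiles",
    "simulate_properties",
    "PROPERTY_NAMES",
]

# study shape: immature white/yellow, mature batches B0..B5 (131 samples)
DEFAULT_GROUPS: tuple[tuple[str, int], ...] = (
    ("W", 27),
    ("Y", 27),
    ("B0", 26),
    ("B1", 24),
    ("B2", 4),
    ("B3", 32),
    ("B4", 30),
    ("B5", 15),
)

PROPERTY_NAMES = ("AC", "SU", "MO", "ST", "SA", "LI", "PA", "CA")

_GENUS_POOL = (
    "Bacillus", "Saccharopolyspora", "Melghirimyces", "Staphylococcus",
    "Brevibacterium", "Oceanobacillus", "Lactobacillus", "Thermoactinomyces",
    "Kroppenstedtia", "Lentibacillus", "Virgibacillus", "Streptomyces",
)


@dataclass
class TruthRecord:
    """Ground truth planted by a generator, sufficient for recovery tests."""

    seed: int
    spec: dict = field(default_factory=dict)
    marker_otus: list | None = None
    planted_lcas: dict | None = None
    planted_correlations: list | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


@dataclass
class CommunitySpec:
    """Design of a simulated grouped community.

    ``markers`` lists ``(otu_index, group_label, log2_fold_change)`` spikes;
    ``exclusives`` lists ``(otu_index, group_label)`` OTUs whose baseline is
    zeroed outside their group.  ``overdispersion`` is the Dirichlet
    concentration scale (50 gives realistic OTU-table noise); depths are
    drawn uniformly from ``depth_range``.
    """

    groups: Sequence[tuple[str, int]] = DEFAULT_GROUPS
    n_otus: int = 300
    base_log_mean: float = 0.0
    base_log_sd: float = 1.5
    markers: Sequence[tuple[int, str, float]] = ()
    exclusives: Sequence[tuple[int, str]] = ()
    overdispersion: float = 50.0
    depth_range: tuple[int, int] = (988, 20000)
    seed: int = 0

    def __post_init__(self) -> None:
        labels = {g for g, _ in self.groups}
        for idx, g, _ in self.markers:
            if not 0 <= idx < self.n_otus:
                raise ValueError(f"marker index {idx} out of range")
            if g not in labels:
                raise ValueError(f"marker group {g!r} not in spec groups")
        for idx, g in self.exclusives:
            if not 0 <= idx < self.n_otus:
                raise ValueError(f"exclusive index {idx} out of range")
            if g not in labels:
                raise ValueError(f"exclusive group {g!r} not in spec groups")
        if self.depth_range[0] < 1 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError(f"bad depth_range {self.depth_range}")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs at least one sample")


def _lineages(n_otus: int, rng: np.random.Generator) -> dict[str, str]:
    out = {}
    for i in range(n_otus):
        genus = _GENUS_POOL[int(rng.integers(len(_GENUS_POOL)))]
        out[f"OTU{i + 1:05d}"] = (
            f"p_Firmicutes;o_Bacillales;f_Bacillaceae;g_{genus}"
        )
    return out


def simulate_community(spec: CommunitySpec) -> tuple[OtuTable, TruthRecord]:
    """Grouped Dirichlet-multinomial OTU counts with planted group effects.

    Per sample: proportions ~ Dirichlet(c * baseline * group multipliers),
    counts ~ Multinomial(depth, proportions).  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    baseline = rng.lognormal(spec.base_log_mean, spec.base_log_sd, spec.n_otus)
    if spec.markers:
        # planted effects are defined on OTUs of representative abundance:
        # pin marker baselines to the median so "log2FC = x" means the same
        # effect whatever the lognormal draw put at those indices
        med = float(np.median(baseline))
        for idx, _, _ in spec.markers:
            baseline[idx] = med
    otu_ids = [f"OTU{i + 1:05d}" for i in range(spec.n_otus)]
    group_weights: dict[str, np.ndarray] = {}
    for g, _ in spec.groups:
        w = baseline.copy()
        for idx, mg, lfc in spec.markers:
            if mg == g:
                w[idx] *= 2.0**lfc
        for idx, eg in spec.exclusives:
            if eg != g:
                w[idx] = 0.0
        group_weights[g] = w
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for g, n in spec.groups:
        w = group_weights[g]
        alpha = spec.overdispersion * w / w.sum()
        for k in range(n):
            sid = f"{g}.{k + 1:02d}"
            # Dirichlet via gammas so zero baseline gives exact zeros
            gam = np.where(alpha > 0, rng.gamma(np.where(alpha > 0, alpha, 1.0)), 0.0)
            if gam.sum() == 0:
                raise ValueError("degenerate all-zero composition")
            props = gam / gam.sum()
            depth = int(rng.integers(spec.depth_range[0], spec.depth_range[1] + 1))
            cols[sid] = rng.multinomial(depth, props)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "group": g,
                    "batch": g if g.startswith("B") else "",
                    "supergroup": "mature" if g.startswith("B") else g,
                }
            )
    counts = pd.DataFrame(cols, index=otu_ids).astype(np.int64)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    table = OtuTable(counts=counts, metadata=meta, lineage=_lineages(spec.n_otus, rng))
    truth = TruthRecord(
        seed=spec.seed,
        spec={
            "groups": list(spec.groups),
            "n_otus": spec.n_otus,
            "overdispersion": spec.overdispersion,
            "depth_range": spec.depth_range,
        },
        marker_otus=[(otu_ids[i], g, lfc) for i, g, lfc in spec.markers],
        extras={"exclusive_otus": [(otu_ids[i], g) for i, g in spec.exclusives]},
    )
    return table, truth


# -- taxonomy --------------------------------------------------------------------

_DEFAULT_KINGDOMS = ("Bacteria", "Archaea", "Fungi", "Viruses", "Metazoa", "Viridiplantae")


def simulate_taxonomy(
    n_per_rank: Mapping[str, int] | None = None, seed: int = 0
) -> TaxonomyTree:
    """Balanced ranked tree rooted at ``root``.

    ``n_per_rank`` maps each rank below root to its branching factor; the
    default grows 6 kingdoms (the four microbial ones plus animal and plant
    clades, so microbe-retention paths are exercised) and branches modestly
    below.  Kingdom nodes take the canonical names in order.
    """
    branching = {
        "kingdom": 6, "phylum": 2, "class": 1, "order": 2,
        "family": 1, "genus": 2, "species": 2,
    }
    if n_per_rank:
        branching.update(n_per_rank)
    if any(b < 1 for b in branching.values()):
        raise ValueError("branching factors must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: dict[str, tuple[str, str, str]] = {"root": ("root", "root", "root")}
    frontier = ["root"]
    counter = 0
    for rank in RANKS[1:]:
        nxt = []
        for parent in frontier:
            for j in range(branching[rank]):
                counter += 1
                nid = f"t{counter}"
                if rank == "kingdom":
                    name = _DEFAULT_KINGDOMS[j % len(_DEFAULT_KINGDOMS)]
                    if j >= len(_DEFAULT_KINGDOMS):
                        name = f"{name}_{j}"
                else:
                    name = f"{rank[0]}{counter}"
                nodes[nid] = (parent, rank, name)
                nxt.append(nid)
        frontier = nxt
    del rng  # reserved for future stochastic shapes; tree is deterministic
    return TaxonomyTree(nodes=nodes, root="root")


# -- alignment hits ---------------------------------------------------------------


def simulate_hits(
    n_genes: int,
    tree: TaxonomyTree,
    clade_rank_of_truth: str = "genus",
    decoy_rate: float = 0.3,
    seed: int = 0,
    stress: bool = False,
) -> tuple[list[HitRecord], TruthRecord]:
    """Alignment hits with a planted LCA per gene.

    For each gene a truth node at ``clade_rank_of_truth`` (with >= 2
    children) is drawn; 3-10 in-clade hits span at least two of its child
    subtrees, with identity >= 65, query coverage >= 80 and e-values within
    10x of the best, so the filter cascade provably retains them and their
    LCA is exactly the truth node.  With probability ``decoy_rate`` a gene
    also receives off-clade decoy hits engineered to fail at least one
    filter (or, with ``stress=True``, to pass them all, dragging the
    assignment up to an ancestor of the truth).
    """
    if not 0 <= decoy_rate < 1:
        raise ValueError("decoy_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    candidates = [
        n
        for n in sorted(tree.nodes)
        if tree.rank(n) == clade_rank_of_truth and len(tree.children(n)) >= 2
    ]
    if not candidates:
        raise ValueError(
            f"tree has no rank-{clade_rank_of_truth} node with >= 2 children"
        )
    all_leaves = tree.leaves_under(tree.root)
    hits: list[HitRecord] = []
    planted: dict[str, str] = {}
    for g in range(n_genes):
        gene = f"gene{g + 1:06d}"
        truth = candidates[int(rng.integers(len(candidates)))]
        planted[gene] = truth
        kids = tree.children(truth)
        two = rng.choice(len(kids), size=2, replace=False)
        clade_leaves = tree.leaves_under(truth)
        n_hits = int(rng.integers(3, 11))
        subjects = [
            tree.leaves_under(kids[i])[0] for i in two
        ]  # guarantee >= 2 child subtrees
        while len(subjects) < n_hits:
            subjects.append(clade_leaves[int(rng.integers(len(clade_leaves)))])
        qlen = int(rng.integers(100, 401))
        min_aln = int(np.ceil(0.8 * qlen))
        e_min = 10.0 ** rng.uniform(-60, -20)
        for h, subj in enumerate(subjects):
            factor = 1.0 if h == 0 else rng.uniform(1.0, 10.0)
            hits.append(
                HitRecord(
                    query_id=gene,
                    subject_id=f"ref_{subj}_{h}",
                    pct_identity=float(rng.uniform(65.0, 100.0)),
                    aln_length=int(rng.integers(min_aln, qlen + 1)),
                    query_length=qlen,
                    evalue=e_min * factor,
                    bitscore=float(rng.uniform(80, 300)),
                    subject_taxon=subj,
                )
            )
        if rng.uniform() < decoy_rate:
            out_leaves = [l for l in all_leaves if l not in set(clade_leaves)]
            for d in range(int(rng.integers(1, 4))):
                subj = out_leaves[int(rng.integers(len(out_leaves)))]
                ident = float(rng.uniform(65.0, 100.0))
                aln = int(rng.integers(min_aln, qlen + 1))
                ev = e_min * rng.uniform(1.0, 10.0)
                if not stress:  # break exactly one randomly chosen filter
                    mode = int(rng.integers(3))
                    if mode == 0:
                        ident = float(rng.uniform(20.0, 64.5))
                    elif mode == 1:
                        aln = int(rng.integers(10, max(min_aln - 1, 11)))
                    else:
                        ev = e_min * rng.uniform(11.0, 1000.0)
                hits.append(
                    HitRecord(
                        query_id=gene,
                        subject_id=f"decoy_{subj}_{d}",
                        pct_identity=ident,
                        aln_length=aln,
                        query_length=qlen,
                        evalue=ev,
                        bitscore=float(rng.uniform(40, 200)),
                        subject_taxon=subj,
                    )
                )
    truth_rec = TruthRecord(
        seed=seed,
        spec={
            "n_genes": n_genes,
            "clade_rank": clade_rank_of_truth,
            "decoy_rate": decoy_rate,
            "stress": stress,
        },
        planted_lcas=planted,
    )
    return hits, truth_rec


def hits_to_frame(hits: Sequence[HitRecord]) -> pd.DataFrame:
    """Render hit records in the 14-column tabular alignment layout."""
    rows = []
    for h in hits:
        rows.append(
            (
                h.query_id, h.subject_id, h.pct_identity, h.aln_length,
                0, 0, 1, h.aln_length, 1, h.aln_length,
                h.evalue, h.bitscore, h.query_length, h.subject_taxon,
            )
        )
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        "qlen", "staxid",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_hits(hits: Sequence[HitRecord], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False, header=False)


def write_taxonomy(tree: TaxonomyTree, path) -> None:
    with open(path, "w") as fh:
        for n in sorted(tree.nodes):
            p, r, name = tree.nodes[n]
            fh.write(f"{n}\t{p}\t{r}\t{name}\n")


# -- gene profiles -----------------------------------------------------------------


def simulate_gene_profiles(
    n_genes: int,
    samples: Sequence[str],
    ec_pool: Mapping[str, float],
    tree: TaxonomyTree | None = None,
    frac_annotated: float = 0.8,
    gene_log_sd: float = 1.0,
    seed: int = 0,
):
    """Gene catalog with planted per-EC mass ratios.

    ``ec_pool`` maps EC -> target relative mass.  Annotated genes are dealt
    round-robin across the pool (equal gene counts per EC) and each gene's
    lognormal base weight is multiplied by its EC's mass factor, so the
    expected *total* mass ratio between two ECs equals the ratio of their
    pool values.  Per-sample abundances are Dirichlet draws around those
    weights (each sample sums to 1).  Taxon labels come from genus-level
    clades of ``tree`` when given.

    Imports of :mod:`daquscope.functional` are deferred to avoid a cycle.
    """
    from .functional import GeneProfile

    if not ec_pool:
        raise ValueError("ec_pool must be non-empty")
    rng = np.random.default_rng(seed)
    ecs = sorted(ec_pool)
    n_annot = int(round(frac_annotated * n_genes))
    gene_ec: list[str | None] = [ecs[i % len(ecs)] for i in range(n_annot)]
    gene_ec += [None] * (n_genes - n_annot)
    weights = np.empty(n_genes)
    for i, e in enumerate(gene_ec):
        base = rng.lognormal(0.0, gene_log_sd)
        weights[i] = base if e is None else base * ec_pool[e]
    genus_nodes = (
        [n for n in sorted(tree.nodes) if tree.rank(n) == "genus"] if tree else []
    )
    alpha = weights / weights.sum() * n_genes
    abund = {s: rng.dirichlet(alpha) for s in samples}
    profiles = []
    for i in range(n_genes):
        taxon = (
            genus_nodes[int(rng.integers(len(genus_nodes)))] if genus_nodes else "UNKNOWN"
        )
        profiles.append(
            GeneProfile(
                gene_id=f"gene{i + 1:06d}",
                abundance={s: float(abund[s][i]) for s in samples},
                ko=f"K{10000 + i % 500:05d}" if gene_ec[i] is not None else None,
                ec=gene_ec[i],
                taxon=taxon,
                taxon_label=tree.name(taxon) if tree and taxon in tree.nodes else None,
            )
        )
    truth = TruthRecord(
        seed=seed,
        spec={"n_genes": n_genes, "frac_annotated": frac_annotated},
        extras={"ec_target_mass": dict(ec_pool)},
    )
    return profiles, truth


# -- physicochemical properties ------------------------------------------------------


def simulate_properties(
    table: OtuTable,
    links: Sequence[tuple[str, str, float]] = (),
    property_names: Sequence[str] = PROPERTY_NAMES,
    seed: int = 0,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Per-sample property table with Gaussian-copula links to OTUs.

    Each link ``(otu_id, property, rho)`` plants a target Spearman
    correlation between the property and the OTU's relative abundance by
    mixing the OTU's normal scores with independent noise at the Pearson
    equivalent ``2 sin(pi rho / 6)``.  Unlinked properties are independent
    Gaussians.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    link_map = {}
    for otu, prop, rho in links:
        if otu not in table.counts.index:
            raise KeyError(f"unknown OTU {otu!r} in property link")
        if prop not in property_names:
            raise KeyError(f"unknown property {prop!r}")
        if not abs(rho) < 1:
            raise ValueError("|rho| must be < 1")
        link_map[prop] = (otu, rho)
    totals = table.counts.sum(axis=0)
    rel = table.counts / totals
    n = table.n_samples
    cols = {}
    for prop in property_names:
        if prop in link_map:
            otu, rho = link_map[prop]
            x = rel.loc[otu].to_numpy()
            z = sps.norm.ppf((sps.rankdata(x) - 0.5) / n)
            r = 2 * np.sin(np.pi * rho / 6)  # Pearson giving target Spearman
            vals = r * z + np.sqrt(1 - r**2) * rng.standard_normal(n)
        else:
            vals = rng.standard_normal(n)
        cols[prop] = 10.0 + 2.0 * vals  # arbitrary assay-like units
    props = pd.DataFrame(cols, index=table.sample_ids)
    truth = TruthRecord(
        seed=seed,
        spec={"n_samples": n, "properties": list(property_names)},
        planted_correlations=[list(l) for l in links],
    )
    return props, truth
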