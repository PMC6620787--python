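"""Filter-cascade LCA taxonomic assignment of genes from tabular alignment hits.

A gene's protein alignments against a reference database are screened in
two stages — (1) query coverage >= 80% and identity >= 65%, (2) e-value
within 10x of the minimum among stage-1 survivors — and the gene is
assigned to the lowest common ancestor of the surviving subject taxa.
Genes with no hits (or no survivors) are UNKNOWN.  Kingdom-level
partitioning then pools everything outside {Bacteria, Archaea, Fungi,
Viruses} into "Others", and microbe retention keeps only the four
microbial kingdoms (optionally renormalizing their abundance to 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RANKS",
    "UNKNOWN",
    "MICROBIAL_KINGDOMS",
    "TaxonomyTree",
    "HitRecord",
    "GeneAnnotation",
    "read_taxonomy",
    "read_hits",
    "match_pct",
    "filter_hits",
    "lca",
    "annotate_gene",
    "annotate_genes",
    "kingdom_profile",
    "retain_microbial",
]

RANKS = ("root", "kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}
UNKNOWN = "UNKNOWN"
MICROBIAL_KINGDOMS = frozenset({"Bacteria", "Archaea", "Fungi", "Viruses"})


@dataclass
class TaxonomyTree:
    """Rooted tree over the 8 canonical ranks.

    ``nodes`` maps node_id -> (parent_id, rank, name); the root is its own
    parent.  Nodes at non-canonical ranks are collapsed onto their nearest
    canonical ancestor at load time.
    """

    nodes: dict[str, tuple[str, str, str]]
    root: str

    def __post_init__(self) -> None:
        roots = [n for n, (p, _, _) in self.nodes.items() if p == n or p is None]
        if len(roots) != 1 or roots[0] != self.root:
            raise ValueError(f"tree must have exactly one root, found {roots}")
        for n in self.nodes:
            seen = set()
            cur = n
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle through node {cur!r}")
                seen.add(cur)
                cur = self.parent(cur)
                if cur not in self.nodes:
                    raise ValueError(f"node {cur!r} unreachable from root")

    def parent(self, node: str) -> str:
        return self.nodes[node][0]

    def rank(self, node: str) -> str:
        return self.nodes[node][1]

    def name(self, node: str) -> str:
        return self.nodes[node][2]

    def path_to_root(self, node: str) -> list[str]:
        """Ancestor chain from ``node`` up to and including the root."""
        if node not in self.nodes:
            raise KeyError(f"unknown taxonomy node {node!r}")
        path = [node]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def ancestor_at_rank(self, node: str, rank: str) -> str | None:
        for a in self.path_to_root(node):
            if self.rank(a) == rank:
                return a
        return None

    def children(self, node: str) -> list[str]:
        if not hasattr(self, "_children"):
            idx: dict[str, list[str]] = {n: [] for n in self.nodes}
            for n, (p, _, _) in self.nodes.items():
                if p != n:
                    idx[p].append(n)
            self._children = idx
        return self._children[node]

    def leaves_under(self, node: str) -> list[str]:
        out = []
        stack = [node]
        while stack:
            cur = stack.pop()
            kids = self.children(cur)
            if not kids:
                out.append(cur)
            stack.extend(kids)
        return sorted(out)


@dataclass
class HitRecord:
    """One tabular alignment hit (12 standard columns + qlen + staxid)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    query_length: int
    evalue: float
    bitscore: float
    subject_taxon: str = ""
    ko: str | None = None  # functional hits: KO of the subject

    def __post_init__(self) -> None:
        if not 0 <= self.pct_identity <= 100:
            raise ValueError(f"pct_identity out of [0, 100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")


@dataclass
class GeneAnnotation:
    gene_id: str
    taxon: str = UNKNOWN
    rank: str = UNKNOWN
    kingdom: str = UNKNOWN


# -- I/O -------------------------------------------------------------------------


def read_taxonomy(path) -> TaxonomyTree:
    """Read a 4-column TSV taxonomy (node_id, parent_id, rank, name).

    Non-canonical ranks are collapsed onto the nearest canonical ancestor.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, names=["node", "parent", "rank", "name"],
                     header=None, comment="#")
    raw = {r["node"]: (r["parent"], r["rank"], r["name"]) for _, r in df.iterrows()}
    roots = [n for n, (p, _, _) in raw.items() if p == n or pd.isna(p)]
    if len(roots) != 1:
        raise ValueError(f"expected one root, found {roots}")
    root = roots[0]

    def canonical_parent(node: str) -> str:
        p = raw[node][0]
        while p != node and raw[p][1] not in _RANK_DEPTH and p != root:
            node, p = p, raw[p][0]
        return p

    nodes = {}
    for n, (p, rank, name) in raw.items():
        if rank not in _RANK_DEPTH and n != root:
            continue  # collapsed away
        nodes[n] = (canonical_parent(n) if n != root else n, rank, name)
    return TaxonomyTree(nodes=nodes, root=root)


def read_hits(path) -> list[HitRecord]:
    """Read a 14-column tabular hit file: the standard 12 alignment columns
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore) plus qlen and staxid."""
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        "qlen", "staxid",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, header=None, comment="#")
    return [
        HitRecord(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            pct_identity=float(r.pident),
            aln_length=int(r.length),
            query_length=int(r.qlen),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
            subject_taxon=str(r.staxid),
        )
        for _, r in df.iterrows()
    ]


# -- the cascade -----------------------------------------------------------------


def match_pct(hit: HitRecord, divisor: str = "query") -> float:
    """Percentage of the query (default) or subject sequence covered by the
    alignment, capped at 100 (gapped alignments can exceed the query)."""
    if divisor == "query":
        length = hit.query_length
    else:
        raise ValueError(f"unknown divisor {divisor!r}")
    if length <= 0:
        raise ValueError(f"non-positive query length for {hit.query_id!r}")
    return min(100.0, 100.0 * hit.aln_length / length)


def filter_hits(
    hits: Sequence[HitRecord],
    min_match: float = 80.0,
    min_identity: float = 65.0,
    evalue_factor: float = 10.0,
    evalue_stage: str = "post",
) -> list[HitRecord]:
    """Two-stage hit filter for one query.

    Stage 1 keeps hits with ``match_pct >= min_match`` and
    ``pct_identity >= min_identity`` (inclusive boundaries).  Stage 2
    computes the minimum e-value over stage-1 survivors (default;
    ``evalue_stage="pre"`` uses the pre-filter minimum) and keeps hits with
    ``evalue <= evalue_factor * e_min``.  An e-value minimum of exactly 0
    keeps only exact-zero hits.
    """
    if not hits:
        raise ValueError("hit list must be non-empty")
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"mixed query ids in one filter call: {sorted(queries)}")
    stage1 = [
        h
        for h in hits
        if match_pct(h) >= min_match and h.pct_identity >= min_identity
    ]
    if not stage1:
        return []
    pool = hits if evalue_stage == "pre" else stage1
    e_min = min(h.evalue for h in pool)
    cutoff = evalue_factor * e_min  # 0 if e_min == 0: only exact zeros survive
    return [h for h in stage1 if h.evalue <= cutoff]


def lca(taxa: Iterable[str], tree: TaxonomyTree) -> str:
    """Lowest common ancestor: the deepest node that is ancestor-or-self of
    every input node."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("need at least one taxon")
    common: list[str] | None = None
    for t in taxa:
        path = tree.path_to_root(t)[::-1]  # root first
        if common is None:
            common = path
        else:
            keep = 0
            for a, b in zip(common, path):
                if a != b:
                    break
                keep += 1
            common = common[:keep]
        if len(common) == 1:
            break
    assert common
    return common[-1]


def annotate_gene(
    gene_id: str,
    hits: Sequence[HitRecord],
    tree: TaxonomyTree,
    min_match: float = 80.0,
    min_identity: float = 65.0,
    evalue_factor: float = 10.0,
) -> GeneAnnotation:
    """Assign one gene to the LCA of its filtered hits (UNKNOWN if none)."""
    if not hits:
        return GeneAnnotation(gene_id=gene_id)
    survivors = filter_hits(hits, min_match, min_identity, evalue_factor)
    if not survivors:
        return GeneAnnotation(gene_id=gene_id)
    node = lca([h.subject_taxon for h in survivors], tree)
    kingdom_node = tree.ancestor_at_rank(node, "kingdom")
    kingdom = tree.name(kingdom_node) if kingdom_node else "unclassified"
    return GeneAnnotation(
        gene_id=gene_id, taxon=node, rank=tree.rank(node), kingdom=kingdom
    )


def annotate_genes(
    hits: Sequence[HitRecord], tree: TaxonomyTree, gene_ids: Sequence[str] | None = None,
    **thresholds,
) -> list[GeneAnnotation]:
    """Group a mixed hit table by query and annotate every gene.

    ``gene_ids`` may list genes with no hits at all (annotated UNKNOWN).
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    ids = list(gene_ids) if gene_ids is not None else sorted(by_query)
    return [annotate_gene(g, by_query.get(g, []), tree, **thresholds) for g in ids]


# -- kingdom partition ------------------------------------------------------------


def kingdom_profile(
    annotations: Sequence[GeneAnnotation], abundances: Mapping[str, float]
) -> dict[str, float]:
    """Abundance fractions per kingdom category.

    Categories: ``Unknown`` (no surviving alignment), the four microbial
    kingdoms, and ``Others`` (plants, animals, protists and genes whose
    assignment sits above kingdom rank).  Fractions sum to 1.
    """
    missing = [a.gene_id for a in annotations if a.gene_id not in abundances]
    if missing:
        raise KeyError(f"genes missing from abundances: {missing[:5]}")
    total = float(sum(abundances[a.gene_id] for a in annotations))
    if total <= 0:
        raise ValueError("total abundance mass must be positive")
    out = {k: 0.0 for k in ("Unknown", "Bacteria", "Archaea", "Fungi", "Viruses", "Others")}
    for a in annotations:
        w = float(abundances[a.gene_id]) / total
        if a.taxon == UNKNOWN:
            out["Unknown"] += w
        elif a.kingdom in MICROBIAL_KINGDOMS:
            out[a.kingdom] += w
        else:
            out["Others"] += w
    return out


def retain_microbial(
    annotations: Sequence[GeneAnnotation],
    abundances: Mapping[str, float],
    renormalize: bool = True,
) -> tuple[list[GeneAnnotation], dict[str, float]]:
    """Keep genes annotated to microbes (bacteria, archaea, fungi, viruses).

    With ``renormalize`` (default) the retained abundances are rescaled to
    sum to 1, giving within-microbe proportions.
    """
    kept = [a for a in annotations if a.kingdom in MICROBIAL_KINGDOMS]
    mass = float(sum(abundances[a.gene_id] for a in kept))
    if mass <= 0:
        raise ValueError("no microbial abundance mass to retain")
    scale = 1.0 / mass if renormalize else 1.0
    return kept, {a.gene_id: abundances[a.gene_id] * scale for a in kept}
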