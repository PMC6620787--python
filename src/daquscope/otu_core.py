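"""OTU-table data model, I/O, screening, normalization, diversity and presence calls.

The central container is :class:`OtuTable`: an integer count matrix
(OTUs x samples) with per-sample metadata and an optional rank-prefixed
lineage string per OTU (``p_``/``o_``/``f_``/``g_`` convention).  All
16S-side analyses in this package operate on it.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "VennPartition",
    "CoreSet",
    "read_otu_table",
    "write_otu_table",
    "filter_low_occupancy",
    "relative_abundance",
    "css_normalize",
    "adaptive_css_quantile",
    "rarefy",
    "alpha_diversity",
    "prevalence_core",
    "venn_partition",
]


@dataclass
class OtuTable:
    """Integer OTU count matrix with sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, rows indexed by OTU id, columns by
        sample id.
    metadata : pandas.DataFrame
        One row per sample (index = sample id).  Must contain a ``group``
        column; extra columns are preserved.
    lineage : dict, optional
        Map ``otu_id -> lineage string`` (semicolon-delimited, rank-prefixed,
        e.g. ``"p_Firmicutes;o_Bacillales;f_Bacillaceae;g_Bacillus"``).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    lineage: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dup}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at OTU {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        missing = [s for s in c.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        if self.lineage is not None:
            unknown = [o for o in self.lineage if o not in c.index]
            if unknown:
                raise ValueError(f"lineage for unknown OTUs: {unknown[:5]}")

    # -- convenience accessors -------------------------------------------------

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def groups(self) -> pd.Series:
        """Group label per sample, in table column order."""
        return self.metadata.loc[self.sample_ids, "group"]

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return OtuTable(
            counts=self.counts[list(sample_ids)].copy(),
            metadata=self.metadata.loc[list(sample_ids)].copy(),
            lineage=dict(self.lineage) if self.lineage else None,
        )

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        missing = [o for o in otu_ids if o not in self.counts.index]
        if missing:
            raise KeyError(f"unknown OTU ids: {missing}")
        lineage = None
        if self.lineage:
            lineage = {o: self.lineage[o] for o in otu_ids if o in self.lineage}
        return OtuTable(
            counts=self.counts.loc[list(otu_ids)].copy(),
            metadata=self.metadata.copy(),
            lineage=lineage,
        )

    def samples_in_group(self, *group_labels: str) -> list[str]:
        g = self.groups()
        return [s for s in self.sample_ids if g[s] in group_labels]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.metadata.loc[self.sample_ids].equals(
                other.metadata.loc[other.sample_ids]
            )
            and (self.lineage or {}) == (other.lineage or {})
        )


@dataclass
class VennPartition:
    """Counts of OTUs per non-empty group-subset region of a Venn diagram."""

    region_counts: dict[frozenset, int]
    group_totals: dict[str, int]

    def total_otus(self) -> int:
        return sum(self.region_counts.values())


@dataclass
class CoreSet:
    """OTUs whose prevalence in a sample subset strictly exceeds a threshold."""

    core_otu_ids: list[str]
    prevalence: dict[str, float]
    threshold: float = 0.95


# -- I/O ----------------------------------------------------------------------

_HEADER = "#OTU ID"


def read_otu_table(path, metadata_path) -> OtuTable:
    """Read a QIIME-style tab-separated OTU table plus a metadata table.

    The table's first row is ``#OTU ID<TAB>sample1<TAB>...``; an optional
    trailing ``taxonomy`` column carries the lineage strings.  Metadata is
    tab-separated with at least ``sample_id`` and ``group`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#").strip() if i == 0 else c for i, c in enumerate(df.columns)]
    df = df.set_index(df.columns[0])
    lineage = None
    if df.columns[-1].lower() == "taxonomy":
        lineage = {o: t for o, t in df.iloc[:, -1].items() if isinstance(t, str) and t}
        df = df.iloc[:, :-1]
    parsed = {}
    for col in df.columns:
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"unparseable count at OTU {row!r}, sample {col!r}"
            ) from exc
        if (vals < 0).any():
            row = vals.index[vals < 0][0]
            raise ValueError(f"negative count at OTU {row!r}, sample {col!r}")
        parsed[col] = vals.astype(np.int64)
    counts = pd.DataFrame(parsed, index=df.index)
    meta = pd.read_csv(
        metadata_path, sep="\t", dtype=str, keep_default_na=False
    ).set_index("sample_id")
    return OtuTable(counts=counts, metadata=meta, lineage=lineage)


def write_otu_table(table: OtuTable, path, metadata_path=None) -> None:
    """Write an OtuTable in the format read by :func:`read_otu_table`."""
    df = table.counts.copy()
    if table.lineage:
        df["taxonomy"] = [table.lineage.get(o, "") for o in df.index]
    df.index.name = _HEADER
    df.to_csv(path, sep="\t")
    if metadata_path is not None:
        meta = table.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


# -- screening and normalization ----------------------------------------------


def filter_low_occupancy(
    table: OtuTable, min_samples: int = 2, min_total: int = 20
) -> OtuTable:
    """Remove rare OTUs: keep those present in >= ``min_samples`` samples AND
    with total count >= ``min_total``.

    This negates the removal rule "present in only one sample or with less
    than 20 tags" used to screen the 185-sample starter table down to its
    752 analysis OTUs.
    """
    occ = (table.counts > 0).sum(axis=1)
    tot = table.counts.sum(axis=1)
    keep = table.counts.index[(occ >= min_samples) & (tot >= min_total)]
    return table.select_otus(list(keep))


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    return table.counts / totals


def _type1_quantile(sorted_vals: np.ndarray, q: float) -> float:
    """Lower empirical (type-1) quantile of a sorted array."""
    n = len(sorted_vals)
    idx = max(int(math.ceil(q * n)) - 1, 0)
    return float(sorted_vals[idx])


def adaptive_css_quantile(table: OtuTable, rel_tol: float = 0.1) -> float:
    """Data-driven choice of the CSS quantile.

    Scans the quantile grid and returns the smallest quantile at which the
    median across samples of the relative deviation of per-sample quantiles
    from the reference (median) quantile curve starts to destabilize —
    the usual cumulative-sum-scaling heuristic.  Falls back to 0.5 when the
    scan is degenerate or would pick a quantile below 0.5.
    """
    grid = np.arange(0.05, 1.0, 0.01)
    positives = [
        np.sort(col[col > 0].to_numpy()) for _, col in table.counts.items()
    ]
    if any(len(p) == 0 for p in positives):
        raise ValueError("every sample must have a positive count")
    qmat = np.array(
        [[_type1_quantile(p, q) for p in positives] for q in grid], dtype=float
    )
    ref = np.median(qmat, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = np.nanmedian(np.abs(qmat - ref[:, None]) / np.where(ref[:, None] > 0, ref[:, None], np.nan), axis=1)
    if not np.isfinite(dev).any():
        return 0.5
    diffs = np.abs(np.diff(dev))
    scale = np.nanmax(np.abs(dev)) or 1.0
    unstable = np.flatnonzero(diffs > rel_tol * scale)
    if len(unstable) == 0:
        return 0.5
    q = float(grid[unstable[0]])
    return max(q, 0.5)


def css_normalize(
    table: OtuTable, quantile: float | str = "adaptive", scale: float = 1000.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Cumulative sum scaling (CSS) normalization.

    For each sample ``j`` the scaling factor is
    ``s_j = sum of counts c_ij with c_ij <= q_j`` where ``q_j`` is the chosen
    quantile (type-1) of the sample's *positive* counts; normalized values
    are ``c_ij / s_j * scale``.  Mitigates sequencing-depth bias driven by a
    few high-count OTUs.

    Returns
    -------
    (normalized, factors)
        The normalized OTUs x samples matrix and the per-sample ``s_j``.
    """
    if quantile == "adaptive":
        q = adaptive_css_quantile(table)
        logger.info("adaptive CSS quantile: %.2f", q)
    else:
        q = float(quantile)
        if not 0 < q <= 1:
            raise ValueError(f"quantile must be in (0, 1], got {q}")
    factors: dict[str, float] = {}
    norm = pd.DataFrame(index=table.counts.index, dtype=float)
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        pos = np.sort(col[col > 0])
        if len(pos) == 0:
            raise ValueError(f"sample {s!r} has no positive count")
        qv = _type1_quantile(pos, q)
        sj = float(col[col <= qv].sum())
        if sj <= 0:
            raise ValueError(f"zero CSS scaling factor for sample {s!r}")
        factors[s] = sj
        norm[s] = col / sj * scale
    return norm, factors


# -- rarefaction and diversity -------------------------------------------------


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with total count below ``depth`` are dropped with a warning
    (minimum-count convention: the study rarefied at its observed minimum,
    988 reads).  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    keep_cols: list[str] = []
    new_cols: dict[str, np.ndarray] = {}
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        total = int(col.sum())
        if total < depth:
            logger.warning(
                "sample %r dropped: total %d < rarefaction depth %d", s, total, depth
            )
            warnings.warn(
                f"sample {s!r} dropped: total {total} < depth {depth}", stacklevel=2
            )
            continue
        new_cols[s] = rng.multivariate_hypergeometric(col, depth)
        keep_cols.append(s)
    counts = pd.DataFrame(new_cols, index=table.counts.index).astype(np.int64)
    return OtuTable(
        counts=counts[keep_cols] if keep_cols else counts,
        metadata=table.metadata.loc[keep_cols].copy(),
        lineage=dict(table.lineage) if table.lineage else None,
    )


def shannon_index(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of a count vector (default bits)."""
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        return float("nan")
    p = c / c.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def alpha_diversity(
    table: OtuTable,
    depth: int,
    seed: int,
    base: float = 2.0,
    iterations: int = 1,
) -> pd.DataFrame:
    """Per-sample Shannon index and observed-OTU count on a rarefied table.

    With ``iterations > 1`` the metrics are averaged over independent
    rarefaction draws (a single seeded draw is the default).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    acc: list[pd.DataFrame] = []
    for it in range(iterations):
        r = rarefy(table, depth, seed + it)
        rows = {
            s: {
                "shannon": shannon_index(r.counts[s].to_numpy(), base=base),
                "observed_otus": int((r.counts[s] > 0).sum()),
            }
            for s in r.sample_ids
        }
        acc.append(pd.DataFrame.from_dict(rows, orient="index"))
    out = acc[0] if len(acc) == 1 else sum(acc) / len(acc)
    return out


# -- prevalence and Venn --------------------------------------------------------


def prevalence_core(
    table: OtuTable, sample_subset: Sequence[str], threshold: float = 0.95
) -> CoreSet:
    """Core-microbiome call: OTUs present (nonzero) in strictly more than
    ``threshold`` of the given samples.

    The strict ``>`` mirrors "present in more than 95% mature starter
    samples"; with 20 samples and threshold 0.95 an OTU must appear in all
    20 (> 19) to qualify.
    """
    subset = list(sample_subset)
    if not subset:
        raise ValueError("sample subset must be non-empty")
    sub = table.select_samples(subset)
    prev = ((sub.counts > 0).sum(axis=1) / len(subset)).to_dict()
    core = [o for o in sub.otu_ids if prev[o] > threshold]
    return CoreSet(core_otu_ids=core, prevalence=prev, threshold=threshold)


def venn_partition(
    table: OtuTable,
    grouping: Mapping[str, str] | None = None,
    groups: Iterable[str] | None = None,
) -> VennPartition:
    """Partition OTUs by which groups they are present in (Venn regions).

    An OTU is "present in" a group iff it has a nonzero count in at least one
    sample of that group.  Region counts cover every non-empty subset of the
    groups (7 regions for 3 groups).
    """
    if grouping is None:
        grouping = table.groups().to_dict()
    labels = list(groups) if groups is not None else sorted(set(grouping.values()))
    members: dict[str, list[str]] = {g: [] for g in labels}
    for s in table.sample_ids:
        g = grouping.get(s)
        if g is None:
            raise ValueError(f"sample {s!r} has no group assignment")
        if g in members:
            members[g].append(s)
    empty = [g for g, ss in members.items() if not ss]
    if empty:
        raise ValueError(f"groups with zero samples: {empty}")
    presence = {
        g: set(table.counts.index[(table.counts[ss] > 0).any(axis=1)])
        for g, ss in members.items()
    }
    region_counts: dict[frozenset, int] = {}
    for otu in table.otu_ids:
        region = frozenset(g for g in labels if otu in presence[g])
        if region:
            region_counts[region] = region_counts.get(region, 0) + 1
    group_totals = {g: len(presence[g]) for g in labels}
    return VennPartition(region_counts=region_counts, group_totals=group_totals)
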