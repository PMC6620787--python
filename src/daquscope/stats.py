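"""Permutation and rank statistics for community comparison and association.

Spearman correlation with BH-FDR adjustment, Wilcoxon rank-sum,
Bray-Curtis dissimilarity, PERMANOVA, the Mantel test, core-OTU
correlation networks and OTU-vs-property screens.

All permutation p-values use the ``(1 + b) / (1 + B)`` estimator, where
``b`` counts permuted statistics at least as extreme as the observed one,
except in exhaustive mode where every distinct relabelling (identity
included) is enumerated and ``p = b / B``.
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .otu_core import CoreSet, OtuTable, relative_abundance

__all__ = [
    "PermutationTestResult",
    "CorrelationNetwork",
    "spearman",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "bray_curtis",
    "permanova",
    "mantel",
    "core_correlation_network",
    "property_screen",
]


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None = None
    method: str = ""


@dataclass
class CorrelationNetwork:
    """Pairwise Spearman network over core OTUs with BH-adjusted p-values."""

    rho: pd.DataFrame
    p_adjusted: pd.DataFrame
    significant: pd.DataFrame
    labels: dict[str, str]
    alpha: float = 0.05


# -- Spearman ------------------------------------------------------------------


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float(rx @ ry / denom)


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    p-value from the t-approximation with n - 2 df; for n <= ``exact_max_n``
    the exact permutation distribution of rho is enumerated instead.
    Constant input yields ``(nan, nan)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- Wilcoxon rank-sum ----------------------------------------------------------


def _rank_sum_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating all group assignments of the pooled
    mid-ranks.  Handles ties naturally via mid-ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    n = len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev_obs - 1e-9:
            count += 1
    return float(w_obs), count / total


def wilcoxon_rank_sum(a, b, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of all group assignments when both samples have at
    most ``exact_max_n`` observations; otherwise the normal approximation
    with tie correction and continuity correction.  Returns the rank-sum
    statistic W of the first sample and the two-sided p.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        return _rank_sum_exact_p(a, b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = 2 * sps.norm.sf(max(z, 0.0))
    return w, float(min(p, 1.0))


# -- distances ------------------------------------------------------------------


def bray_curtis(table) -> pd.DataFrame:
    """Sample-by-sample Bray-Curtis dissimilarity.

    Accepts an :class:`OtuTable` (converted to relative abundances first,
    the package default for community comparison) or a raw non-negative
    matrix (features x samples as DataFrame, or samples x features array).
    """
    if isinstance(table, OtuTable):
        mat = relative_abundance(table).to_numpy().T
        names = table.sample_ids
    elif isinstance(table, pd.DataFrame):
        mat = table.to_numpy().T
        names = list(table.columns)
    else:
        mat = np.asarray(table, dtype=float)
        names = list(range(mat.shape[0]))
    if np.any(mat < 0):
        raise ValueError("abundances must be non-negative")
    zero_rows = np.flatnonzero(mat.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: {[names[i] for i in zero_rows]}"
        )
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=names, columns=names)


def _check_distance(D) -> np.ndarray:
    D = np.asarray(D, dtype=float) if not isinstance(D, pd.DataFrame) else D.to_numpy(dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must have zero diagonal")
    return D


# -- PERMANOVA -------------------------------------------------------------------


def _pseudo_f(D2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    """One-way PERMANOVA pseudo-F from a squared-distance matrix."""
    n = D2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_t = D2[iu].sum() / n
    ss_w = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_w += np.triu(sub, 1).sum() / len(idx)
    g = len(uniq)
    denom = ss_w / (n - g)
    if denom == 0:
        return float("inf")
    return ((ss_t - ss_w) / (g - 1)) / denom


def permanova(
    D, labels, n_perm: int = 999, seed: int | None = None, exhaustive: bool = False
) -> PermutationTestResult:
    """One-way PERMANOVA: permutational multivariate analysis of variance.

    pseudo-F = [(SS_T - SS_W)/(g-1)] / [SS_W/(n-g)] with total and
    within-group sums of squared distances computed from the distance
    matrix directly.  The p-value permutes group labels; ``exhaustive=True``
    enumerates every labelling (small n only) and returns ``b / B``.
    """
    D = _check_distance(D)
    labels = np.asarray(labels)
    n = D.shape[0]
    if len(labels) != n:
        raise ValueError("labels length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    if not D.any():
        raise ValueError("degenerate all-zero distance matrix")
    D2 = D**2
    f_obs = _pseudo_f(D2, labels, uniq)
    if exhaustive:
        b = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            f = _pseudo_f(D2, labels[list(perm)], uniq)
            total += 1
            if f >= f_obs - 1e-12:
                b += 1
        return PermutationTestResult(f_obs, b / total, total, seed, "permanova/exhaustive")
    rng = np.random.default_rng(seed)
    b = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if _pseudo_f(D2, lab, uniq) >= f_obs - 1e-12:
            b += 1
    return PermutationTestResult(
        f_obs, (1 + b) / (1 + n_perm), n_perm, seed, "permanova"
    )


# -- Mantel ----------------------------------------------------------------------


def mantel(
    D1,
    D2,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "spearman",
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Mantel test of association between two distance matrices.

    The statistic correlates the upper-triangle entries (rank-based by
    default); significance permutes rows and columns of ``D2``
    simultaneously.  Two-sided.  A constant matrix makes the statistic
    undefined (returned as nan with p = nan).
    """
    D1 = _check_distance(D1)
    D2 = _check_distance(D2)
    if D1.shape != D2.shape:
        raise ValueError("distance matrices must have identical shape")
    n = D1.shape[0]
    iu = np.triu_indices(n, 1)

    def corr(v1, v2):
        if method == "spearman":
            v1, v2 = sps.rankdata(v1), sps.rankdata(v2)
        elif method != "pearson":
            raise ValueError(f"unknown method {method!r}")
        return _rank_corr(np.asarray(v1, float), np.asarray(v2, float))

    v1 = D1[iu]
    r_obs = corr(v1, D2[iu])
    if math.isnan(r_obs):
        warnings.warn("Mantel statistic undefined (constant matrix)", stacklevel=2)
        return PermutationTestResult(float("nan"), float("nan"), 0, seed, "mantel")
    if exhaustive:
        b = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r = corr(v1, D2[np.ix_(p, p)][iu])
            total += 1
            if abs(r) >= abs(r_obs) - 1e-12:
                b += 1
        return PermutationTestResult(r_obs, b / total, total, seed, "mantel/exhaustive")
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = corr(v1, D2[np.ix_(p, p)][iu])
        if abs(r) >= abs(r_obs) - 1e-12:
            b += 1
    return PermutationTestResult(
        r_obs, (1 + b) / (1 + n_perm), n_perm, seed, "mantel"
    )


# -- networks and screens ---------------------------------------------------------


def _display_label(otu_id: str, lineage: str | None) -> str:
    """"taxon_lastdigits" display name: last lineage field plus the last
    three digits of the OTU's original name."""
    digits = re.sub(r"\D", "", otu_id)
    suffix = digits[-3:] if digits else otu_id[-3:]
    if lineage:
        taxon = lineage.split(";")[-1].strip()
    else:
        taxon = "unclassified"
    return f"{taxon}_{suffix}"


def core_correlation_network(
    table: OtuTable, core: CoreSet | list[str] | None = None, alpha: float = 0.05
) -> CorrelationNetwork:
    """All-pairs Spearman network over core OTUs, BH-adjusted across the
    C(k,2) pairs, with a significance mask at ``alpha``."""
    ids = (
        core.core_otu_ids
        if isinstance(core, CoreSet)
        else (list(core) if core is not None else table.otu_ids)
    )
    if len(ids) < 2:
        raise ValueError("need at least 2 core OTUs")
    sub = table.select_otus(ids)
    rel = relative_abundance(sub)
    k = len(ids)
    rho = np.eye(k)
    praw = []
    pairs = list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        r, p = spearman(rel.iloc[i].to_numpy(), rel.iloc[j].to_numpy())
        rho[i, j] = rho[j, i] = r
        praw.append(p)
    padj = bh_fdr(np.nan_to_num(np.array(praw), nan=1.0))
    pmat = np.ones((k, k))
    np.fill_diagonal(pmat, 0.0)
    for (i, j), p in zip(pairs, padj):
        pmat[i, j] = pmat[j, i] = p
    sig = pmat <= alpha
    np.fill_diagonal(sig, False)
    labels = {
        o: _display_label(o, (table.lineage or {}).get(o)) for o in ids
    }
    return CorrelationNetwork(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        p_adjusted=pd.DataFrame(pmat, index=ids, columns=ids),
        significant=pd.DataFrame(sig, index=ids, columns=ids),
        labels=labels,
        alpha=alpha,
    )


def property_screen(
    table: OtuTable, properties: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Spearman screen of every OTU against each physicochemical property.

    ``properties`` is samples x properties; samples with any missing value
    for a property are dropped for that property (with a warning).  BH
    adjustment is applied within each property across OTUs — each property
    is its own test family.
    """
    shared = [s for s in table.sample_ids if s in properties.index]
    if not shared:
        raise ValueError("no overlapping samples between table and properties")
    rel = relative_abundance(table.select_samples(shared))
    out: dict[str, pd.DataFrame] = {}
    for prop in properties.columns:
        vals = properties.loc[shared, prop].astype(float)
        ok = vals.notna()
        if not ok.all():
            warnings.warn(
                f"property {prop!r}: dropping {int((~ok).sum())} samples with "
                "missing values",
                stacklevel=2,
            )
        use = vals[ok]
        if len(use) < 3:
            raise ValueError(f"property {prop!r}: fewer than 3 usable samples")
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for otu in rel.index:
                r, p = spearman(rel.loc[otu, use.index].to_numpy(), use.to_numpy())
                rows.append((otu, r, p))
        df = pd.DataFrame(rows, columns=["otu", "rho", "p"]).set_index("otu")
        praw = df["p"].fillna(1.0).to_numpy()
        df["p_adjusted"] = bh_fdr(praw)
        df["significant"] = df["p_adjusted"] <= alpha
        out[prop] = df
    return out
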