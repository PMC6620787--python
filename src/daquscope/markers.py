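"""LOOCV stability selection of marker OTUs.

The procedure mirrors the marker-discovery design used for the 54
immature-starter samples: in every leave-one-out fold, an all-relevant
shadow-feature selector is run on the training samples only; a random
forest classifier is then fit on the selected features, the held-out
sample is predicted, and the permutation-importance rank of every
selected feature is recorded.  Features selected in more than a stated
fraction of folds (default 90%) are the markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance

from .otu_core import OtuTable, css_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionParams",
    "MarkerReport",
    "marker_cutoff",
    "shadow_feature_select",
    "loocv_markers",
    "rank_frequency_table",
]


@dataclass
class SelectionParams:
    """Tuning knobs of the stability-selection procedure.

    ``n_trees`` — trees per ensemble (selector iterations and final
    classifiers); ``max_iterations`` — cap on shadow-feature iterations;
    ``alpha`` — significance level of the binomial shadow-comparison test;
    ``frequency_threshold`` — fraction of folds a feature must exceed to be
    a marker; ``tentative_policy`` — what to do with features undecided at
    the iteration cap (``"drop"`` or ``"median_fix"``).
    """

    n_trees: int = 500
    max_iterations: int = 100
    alpha: float = 0.05
    frequency_threshold: float = 0.9
    seed: int = 0
    tentative_policy: str = "drop"
    # trees per shadow iteration (None = n_trees). Small ensembles are much
    # faster and suffice at small feature counts because hit evidence
    # aggregates binomially across iterations; at hundreds of features the
    # full ensemble is needed to resolve importances above the shadow max.
    selector_trees: int | None = None
    importance: str = "impurity"  # selector-internal importance: impurity|permutation
    normalization: str = "pooled"  # css on the full table ("pooled") or "per_fold"

    def __post_init__(self) -> None:
        if not 0 < self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must be in (0, 1]")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.tentative_policy not in ("drop", "median_fix"):
            raise ValueError(f"unknown tentative_policy {self.tentative_policy!r}")


@dataclass
class MarkerReport:
    """Everything the LOOCV produces, per OTU and per fold."""

    n_folds: int
    feature_ids: list[str]
    selected_fold_count: dict[str, int]
    rank_histogram: dict[str, dict[int, int]]
    importance_values: dict[str, list[float]]
    predictions: list[dict]  # per fold: sample, true, predicted (None if skipped)
    accuracy: float
    cutoff: int
    markers: list[str]
    params: SelectionParams | None = None


def marker_cutoff(n_folds: int, frequency_threshold: float) -> int:
    """Smallest integer k with k > frequency_threshold * n_folds.

    With 54 folds and a more-than-90% rule this is 49.
    """
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if not 0 < frequency_threshold <= 1:
        raise ValueError("frequency_threshold must be in (0, 1]")
    t = frequency_threshold * n_folds
    nearest = round(t)
    if abs(t - nearest) < 1e-9:  # product is an integer up to float error
        return int(nearest) + 1
    return int(np.floor(t)) + 1


# -- shadow-feature all-relevant selection ---------------------------------------


def _iteration_importances(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, params: SelectionParams
) -> np.ndarray:
    """Importances of [real | shadow] features for one selector iteration."""
    n, p = X.shape
    shadows = X.copy()
    for j in range(p):  # permute each column independently
        shadows[:, j] = shadows[rng.permutation(n), j]
    Xa = np.hstack([X, shadows])
    clf = ExtraTreesClassifier(
        n_estimators=params.selector_trees or params.n_trees,
        max_features="sqrt",
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    clf.fit(Xa, y)
    if params.importance == "permutation":
        imp = permutation_importance(
            clf, Xa, y, n_repeats=5, random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).importances_mean
    else:
        imp = clf.feature_importances_
    return imp


def shadow_feature_select(
    X,
    y,
    params: SelectionParams | None = None,
    return_history: bool = False,
):
    """All-relevant feature selection against shuffled shadow copies.

    Each iteration augments ``X`` with a shuffled ("shadow") copy of every
    still-undecided feature, fits a randomized-tree ensemble, and scores a
    *hit* for a feature whose importance exceeds the maximum shadow
    importance.  After each iteration a two-sided binomial test (at
    ``alpha``) on the hit count confirms features that beat the shadows
    significantly more often than chance and rejects those that do so
    significantly less often; rejected features leave the model.  Features
    still undecided at ``max_iterations`` are tentative and handled by
    ``tentative_policy``.  The binomial test is Bonferroni-corrected for
    the number of starting features (the established multiple-testing
    default of this family of selectors).  Deterministic given
    ``params.seed``.

    Returns the set of confirmed feature indices (column numbers), or
    ``(confirmed, history)`` with per-feature importance history when
    ``return_history`` is true.
    """
    params = params or SelectionParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels must contain at least two classes")
    if class_counts.min() < 2:
        raise ValueError("need >= 2 samples per class")
    n, p = X.shape
    rng = np.random.default_rng(params.seed)
    active = list(range(p))
    hits = np.zeros(p, dtype=int)
    trials = 0
    confirmed: set[int] = set()
    rejected: set[int] = set()
    history: dict[int, list[float]] = {j: [] for j in range(p)}
    shadow_max_hist: list[float] = []
    for _ in range(params.max_iterations):
        if not active:
            break
        imp = _iteration_importances(X[:, active], y, rng, params)
        real, shadow = imp[: len(active)], imp[len(active):]
        smax = shadow.max() if len(shadow) else 0.0
        shadow_max_hist.append(float(smax))
        for k, j in enumerate(active):
            history[j].append(float(real[k]))
            if real[k] > smax:
                hits[j] += 1
        trials += 1
        # decide undecided features on the accumulated binomial evidence
        # (two-sided test at alpha, Bonferroni-corrected across features)
        alpha_adj = params.alpha / p
        h = hits[active]
        p_hi = 2 * sps.binom.sf(h - 1, trials, 0.5)
        p_lo = 2 * sps.binom.cdf(h, trials, 0.5)
        still: list[int] = []
        for k, j in enumerate(active):
            if h[k] > trials / 2 and p_hi[k] < alpha_adj:
                confirmed.add(j)
            elif h[k] < trials / 2 and p_lo[k] < alpha_adj:
                rejected.add(j)
            else:
                still.append(j)
        active = still
    if active:  # tentative at the cap
        logger.info("%d features tentative after %d iterations", len(active), trials)
        if params.tentative_policy == "median_fix":
            med_shadow = float(np.median(shadow_max_hist)) if shadow_max_hist else 0.0
            for j in active:
                if np.median(history[j]) > med_shadow:
                    confirmed.add(j)
    out = sorted(confirmed)
    if return_history:
        return out, history
    return out


# -- LOOCV -----------------------------------------------------------------------


def _fold_seed(master: int, fold: int) -> int:
    return int(np.random.SeedSequence([master, fold]).generate_state(1)[0] % (2**31 - 1))


def loocv_markers(table: OtuTable, params: SelectionParams | None = None) -> MarkerReport:
    """Leave-one-out stability selection on a two-group OTU table.

    One fold per sample: the held-out sample is never seen by the selector
    or the classifier of its fold.  Input counts are CSS-normalized (on the
    full table by default, matching the published pipeline order; set
    ``params.normalization = "per_fold"`` for the leakage-free variant that
    renormalizes inside each training fold).  Importance recorded per fold
    is permutation mean decrease in accuracy; rank 1 is the largest.
    """
    params = params or SelectionParams()
    groups = table.groups()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 3:
        raise ValueError("need >= 3 samples per class for LOOCV")
    feature_ids = table.otu_ids
    samples = table.sample_ids
    y_all = np.array([0 if groups[s] == labels[0] else 1 for s in samples])
    if params.normalization == "pooled":
        norm, _ = css_normalize(table, quantile=0.5)
        X_all = norm.to_numpy().T  # samples x OTUs
    elif params.normalization == "per_fold":
        X_all = None
    else:
        raise ValueError(f"unknown normalization {params.normalization!r}")

    n = len(samples)
    sel_count = {o: 0 for o in feature_ids}
    rank_hist: dict[str, dict[int, int]] = {o: {} for o in feature_ids}
    imp_vals: dict[str, list[float]] = {o: [] for o in feature_ids}
    predictions: list[dict] = []
    n_correct = 0
    for i in range(n):
        train_idx = [k for k in range(n) if k != i]
        fseed = _fold_seed(params.seed, i)
        if X_all is not None:
            X_train, X_test = X_all[train_idx], X_all[[i]]
        else:
            sub = table.select_samples([samples[k] for k in train_idx])
            norm, factors = css_normalize(sub, quantile=0.5)
            X_train = norm.to_numpy().T
            # held-out sample scaled with its own CSS factor from the fold rule
            held = table.select_samples([samples[i]])
            X_test = css_normalize(held, quantile=0.5)[0].to_numpy().T
        y_train = y_all[train_idx]
        fold_params = SelectionParams(
            n_trees=params.n_trees,
            max_iterations=params.max_iterations,
            alpha=params.alpha,
            frequency_threshold=params.frequency_threshold,
            seed=fseed,
            tentative_policy=params.tentative_policy,
            importance=params.importance,
            selector_trees=params.selector_trees,
        )
        selected = shadow_feature_select(X_train, y_train, fold_params)
        if not selected:
            logger.warning("fold %d: empty selection, classifier skipped", i)
            predictions.append(
                {"sample": samples[i], "true": int(y_all[i]), "predicted": None}
            )
            continue
        for j in selected:
            sel_count[feature_ids[j]] += 1
        clf = RandomForestClassifier(
            n_estimators=params.n_trees,
            max_features="sqrt",
            random_state=fseed,
            n_jobs=1,
        )
        clf.fit(X_train[:, selected], y_train)
        pred = int(clf.predict(X_test[:, selected])[0])
        predictions.append(
            {"sample": samples[i], "true": int(y_all[i]), "predicted": pred}
        )
        if pred == y_all[i]:
            n_correct += 1
        # mean decrease accuracy of the fold's classifier
        mda = permutation_importance(
            clf,
            X_train[:, selected],
            y_train,
            scoring="accuracy",
            n_repeats=5,
            random_state=fseed,
            n_jobs=1,
        ).importances_mean
        order = np.argsort(-mda, kind="stable")  # rank 1 = largest MDA
        for rank_pos, k in enumerate(order, start=1):
            oid = feature_ids[selected[k]]
            rank_hist[oid][rank_pos] = rank_hist[oid].get(rank_pos, 0) + 1
            imp_vals[oid].append(float(mda[k]))
    cutoff = marker_cutoff(n, params.frequency_threshold)
    markers = [o for o in feature_ids if sel_count[o] >= cutoff]
    return MarkerReport(
        n_folds=n,
        feature_ids=feature_ids,
        selected_fold_count=sel_count,
        rank_histogram=rank_hist,
        importance_values=imp_vals,
        predictions=predictions,
        accuracy=n_correct / n,
        cutoff=cutoff,
        markers=markers,
        params=params,
    )


def rank_frequency_table(report: MarkerReport, min_folds: int = 10) -> pd.DataFrame:
    """Rank-frequency rows for OTUs used in more than ``min_folds``
    classifiers, sorted by total selection count descending.

    One row per OTU; columns ``rank_1 .. rank_R`` hold the number of folds
    in which the OTU held that importance rank, and sum to its usage count.
    """
    used = [
        o
        for o in report.feature_ids
        if sum(report.rank_histogram[o].values()) > min_folds
    ]
    if not used:
        return pd.DataFrame(columns=["otu", "used_in", "selected_in"]).set_index("otu")
    max_rank = max(r for o in used for r in report.rank_histogram[o])
    rows = []
    for o in used:
        hist = report.rank_histogram[o]
        row = {
            "otu": o,
            "used_in": sum(hist.values()),
            "selected_in": report.selected_fold_count[o],
        }
        for r in range(1, max_rank + 1):
            row[f"rank_{r}"] = hist.get(r, 0)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("otu")
    return df.sort_values("selected_in", ascending=False)
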