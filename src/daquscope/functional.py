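"""EC-level functional profiling of a metagenomic gene catalog.

Genes carry relative abundances per sample plus optional KO/EC and taxon
annotations.  KO assignment keeps the best functional hit with bit score
strictly greater than 60; EC abundances aggregate gene mass per enzyme;
pathway profiles intersect the observed enzymes with a pathway's EC list
(starch-to-glucose and cellulose hydrolysis maps ship with the package);
heatmap values use the log10(x + 1e-8) display transform; per-enzyme
taxon breakdowns pool taxa below 1% into "Others (<1%)".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .taxonomy import UNKNOWN, HitRecord

__all__ = [
    "GeneProfile",
    "PathwayMap",
    "load_pathway_map",
    "read_gene_profiles",
    "write_gene_profiles",
    "assign_best_ko",
    "ec_abundance",
    "pathway_profile",
    "display_log",
    "taxon_breakdown",
]

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|-)$")
OTHERS_LABEL = "Others (<1%)"


@dataclass
class GeneProfile:
    """One gene of the catalog: per-sample relative abundance + annotations."""

    gene_id: str
    abundance: dict[str, float]
    ko: str | None = None
    ec: str | None = None
    taxon: str = UNKNOWN
    taxon_label: str | None = None  # display name of the lowest assigned level

    def __post_init__(self) -> None:
        bad = {s: a for s, a in self.abundance.items() if a < 0}
        if bad:
            raise ValueError(f"negative abundances for {self.gene_id!r}: {bad}")
        if self.ec is not None and not _EC_RE.match(self.ec):
            raise ValueError(f"malformed EC number {self.ec!r}")


@dataclass
class PathwayMap:
    name: str
    ec_numbers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bad = [e for e in self.ec_numbers if not _EC_RE.match(e)]
        if bad:
            raise ValueError(f"malformed EC numbers in map {self.name!r}: {bad}")


def load_pathway_map(source) -> PathwayMap:
    """Load a pathway map: one EC per line, ``#``-prefixed header names the map.

    ``source`` is a file path, or the name of a bundled map
    (``"starch_glucose"`` or ``"cellulose"``).
    """
    if isinstance(source, str) and "/" not in source and not source.endswith(".txt"):
        text = (
            resources.files("daquscope.data").joinpath(f"{source}.txt").read_text()
        )
        name = source
    else:
        with open(source) as fh:
            text = fh.read()
        name = str(source)
    ecs = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            name = line.lstrip("#").strip() or name
            continue
        ecs.append(line.split("\t")[0].strip())
    return PathwayMap(name=name, ec_numbers=frozenset(ecs))


# -- I/O -------------------------------------------------------------------------


def read_gene_profiles(path) -> list[GeneProfile]:
    """Read a tab-separated gene profile: gene_id, sample columns, then
    ko / ec / taxon_id annotation columns (empty = unannotated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ann_cols = [c for c in ("ko", "ec", "taxon_id", "taxon_label") if c in df.columns]
    sample_cols = [c for c in df.columns[1:] if c not in ann_cols]
    out = []
    for _, r in df.iterrows():
        out.append(
            GeneProfile(
                gene_id=r.iloc[0],
                abundance={s: float(r[s]) for s in sample_cols},
                ko=r["ko"] if "ko" in ann_cols and pd.notna(r["ko"]) else None,
                ec=r["ec"] if "ec" in ann_cols and pd.notna(r["ec"]) else None,
                taxon=(
                    r["taxon_id"]
                    if "taxon_id" in ann_cols and pd.notna(r["taxon_id"])
                    else UNKNOWN
                ),
                taxon_label=(
                    r["taxon_label"]
                    if "taxon_label" in ann_cols and pd.notna(r["taxon_label"])
                    else None
                ),
            )
        )
    return out


def write_gene_profiles(profiles: Sequence[GeneProfile], path) -> None:
    samples = list(profiles[0].abundance) if profiles else []
    rows = []
    for g in profiles:
        row = {"gene_id": g.gene_id, **{s: g.abundance[s] for s in samples}}
        row["ko"] = g.ko or ""
        row["ec"] = g.ec or ""
        row["taxon_id"] = g.taxon
        row["taxon_label"] = g.taxon_label or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- operations ------------------------------------------------------------------


def assign_best_ko(hits: Sequence[HitRecord], min_bitscore: float = 60.0) -> str | None:
    """KO of the maximum-bitscore functional hit, provided that bit score is
    *strictly* greater than ``min_bitscore``; ties broken by smaller
    e-value, then lexicographic subject id."""
    if not hits:
        return None
    best = min(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    if best.bitscore > min_bitscore:
        return best.ko
    return None


def ec_abundance(profiles: Sequence[GeneProfile]) -> pd.DataFrame:
    """EC x sample matrix: total gene abundance per enzyme and sample.

    Genes without an EC contribute nothing.
    """
    samples: list[str] = list(profiles[0].abundance) if profiles else []
    acc: dict[str, np.ndarray] = {}
    for g in profiles:
        if g.ec is None:
            continue
        vec = np.array([g.abundance[s] for s in samples], dtype=float)
        acc[g.ec] = acc.get(g.ec, np.zeros(len(samples))) + vec
    df = pd.DataFrame(acc, index=samples).T
    return df.sort_index()


def pathway_profile(ec_matrix: pd.DataFrame, pathway: PathwayMap) -> pd.DataFrame:
    """Restrict an EC matrix to a pathway's enzymes, ranked by mean abundance.

    ECs in the map but unobserved appear with zero abundance; rows are
    sorted by mean abundance descending.
    """
    present = [e for e in ec_matrix.index if e in pathway.ec_numbers]
    sub = ec_matrix.loc[present].copy()
    absent = sorted(pathway.ec_numbers - set(present))
    if absent:
        zeros = pd.DataFrame(0.0, index=absent, columns=ec_matrix.columns)
        sub = pd.concat([sub, zeros])
    order = sub.mean(axis=1).sort_values(ascending=False, kind="stable").index
    return sub.loc[order]


def display_log(x, pseudo: float = 1e-8):
    """Heatmap display transform log10(x + 1e-8); maps 0 to exactly -8."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("relative abundance must be non-negative")
    out = np.log10(arr + pseudo)
    return float(out) if np.isscalar(x) else out


def taxon_breakdown(
    profiles: Sequence[GeneProfile],
    sample: str | None = None,
    min_frac: float = 0.01,
) -> dict[str, float]:
    """Taxonomic composition of one enzyme's gene mass.

    Genes are grouped by their lowest-level taxon label; fractions are of
    the group's total mass (mean across samples unless ``sample`` names
    one); taxa below ``min_frac`` are pooled into ``"Others (<1%)"``.
    """
    if not profiles:
        raise ValueError("need at least one gene")
    masses: dict[str, float] = {}
    for g in profiles:
        label = g.taxon_label or g.taxon
        m = (
            g.abundance[sample]
            if sample is not None
            else float(np.mean(list(g.abundance.values())))
        )
        masses[label] = masses.get(label, 0.0) + m
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("zero total abundance mass for this enzyme")
    fracs = {t: m / total for t, m in masses.items()}
    out: dict[str, float] = {}
    pooled = 0.0
    for t, f in sorted(fracs.items(), key=lambda kv: -kv[1]):
        if f < min_frac:
            pooled += f
        else:
            out[t] = f
    if pooled > 0:
        out[OTHERS_LABEL] = pooled
    return out
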