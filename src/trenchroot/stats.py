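"""Validation and diversity statistics for root-distribution phenotypes.

Covers the downstream analyses applied to per-replicate Depth50/Width50
tables: Pearson validation of predicted vs. manually traced phenotypes,
broad-sense heritability H2 = V_G / V_P from a one-way random-effects
variance decomposition over accessions, a fixed-effects ANOVA for
acquisition-date effects, the Steel-Dwass all-pairs nonparametric
comparison between subspecies groups, and hierarchical clustering of
accessions on z-scored (Depth50, Width50) means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "PhenotypeTable",
    "HeritabilityResult",
    "pearson",
    "broad_sense_heritability",
    "oneway_anova",
    "steel_dwass",
    "cluster_accessions",
]

SUBSPECIES = ("japonica", "indica", "aus", "admixed")

#: Canonical PhenotypeTable columns.
COLUMNS = ["accession", "subspecies", "plot", "date", "depth50_cm", "width50_cm"]


@dataclass
class PhenotypeTable:
    """Per-replicate phenotype records, one row per trench image."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("accession", "depth50_cm", "width50_cm")
                   if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        vals = self.data[["depth50_cm", "width50_cm"]].to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("phenotype values must be finite and >= 0")

    @classmethod
    def from_csv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, comment="#"))

    def accession_means(self) -> pd.DataFrame:
        return self.data.groupby("accession")[["depth50_cm", "width50_cm"]].mean()


@dataclass
class HeritabilityResult:
    H2: float
    V_G: float
    V_P: float
    replicates_effective: float


def pearson(x, y) -> float:
    """Product-moment correlation; requires equal length >= 3 and
    non-degenerate variance on both sides."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


def _anova_mean_squares(groups: list[np.ndarray]) -> tuple[float, float]:
    """Between-group and within-group mean squares of a one-way layout."""
    k = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(n * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    big_n = n.sum()
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (big_n - k) if big_n > k else 0.0
    return ms_between, ms_within


def broad_sense_heritability(table: PhenotypeTable, trait: str) -> HeritabilityResult:
    """Broad-sense heritability H2 = V_G / V_P from replicated accessions.

    One-way random-effects decomposition over accessions:
    V_G = (MS_accession - MS_error) / r_bar with r_bar the harmonic mean
    of replicate counts, clipped at zero; V_P = V_G + MS_error (the
    variance of a single replicate observation).
    """
    if trait not in table.data.columns:
        raise ValueError(f"unknown trait {trait!r}")
    groups = [g.to_numpy(float) for _, g in table.data.groupby("accession")[trait]]
    if len(groups) < 2:
        raise ValueError("need at least 2 accessions")
    if max(len(g) for g in groups) < 2:
        raise ValueError("need replicates for at least one accession")
    ms_a, ms_e = _anova_mean_squares(groups)
    r_bar = sps.hmean([len(g) for g in groups])
    v_g = max((ms_a - ms_e) / r_bar, 0.0)
    v_p = v_g + ms_e
    if v_p <= 0:
        raise ValueError("zero phenotypic variance")
    return HeritabilityResult(v_g / v_p, v_g, v_p, float(r_bar))


def oneway_anova(groups: list) -> tuple[float, float]:
    """Fixed-effects one-way ANOVA: F with (k-1, N-k) df and its p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    res = sps.f_oneway(*groups)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # identical constant groups
        return 0.0, 1.0
    return f, p


def steel_dwass(groups: dict[str, np.ndarray] | dict) -> pd.DataFrame:
    """Steel-Dwass all-pairs nonparametric comparison.

    For each pair of groups the two samples alone are midranked, the
    rank sum of the first is standardized (tie-corrected variance), and
    sqrt(2) * |z| is referred to the studentized range distribution with
    k groups (infinite df).  At k = 2 this reduces to the two-sided
    normal-approximation Wilcoxon rank-sum test.
    """
    labels = list(groups)
    arrays = {lab: np.asarray(groups[lab], dtype=float) for lab in labels}
    if len(labels) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("need >= 2 groups with >= 2 values each")
    k = len(labels)
    rows = []
    for a, b in combinations(labels, 2):
        xa, xb = arrays[a], arrays[b]
        na, nb = len(xa), len(xb)
        big_n = na + nb
        ranks = sps.rankdata(np.concatenate([xa, xb]))
        w = ranks[:na].sum()
        expect = na * (big_n + 1) / 2.0
        var = na * nb / (big_n * (big_n - 1.0)) * np.sum((ranks - (big_n + 1) / 2.0) ** 2)
        if var <= 0:
            z = 0.0
        else:
            z = (w - expect) / np.sqrt(var)
        stat = abs(z) * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(stat, k, np.inf))
        rows.append({"group1": a, "group2": b, "statistic": float(stat),
                     "z": float(z), "p": min(p, 1.0)})
    return pd.DataFrame(rows)


def cluster_accessions(table: PhenotypeTable, k: int = 5,
                       method: str = "single") -> tuple[pd.Series, np.ndarray]:
    """Cluster accessions on z-scored mean (Depth50, Width50).

    Per-accession means are standardized to mean 0, variance 1 per
    trait, then agglomeratively clustered with nearest-neighbor (single)
    linkage on Euclidean distance and cut to ``k`` clusters.  Returns
    (labels indexed by accession, scipy linkage matrix).
    """
    means = table.accession_means()
    if k > len(means):
        raise ValueError(f"k={k} exceeds {len(means)} accessions")
    z = (means - means.mean()) / means.std(ddof=0)
    lk = linkage(z.to_numpy(), method=method, metric="euclidean")
    labels = fcluster(lk, t=k, criterion="maxclust")
    return pd.Series(labels, index=means.index, name="cluster"), lk
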