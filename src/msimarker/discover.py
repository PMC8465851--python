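"""Discriminative m/z feature discovery between two tissue groups.

Within one annotated wall layer, spectra of two cohort groups are compared
feature by feature: balanced random subsampling equalizes the observation
pools, the ROC area under the curve (computed through the Mann-Whitney rank
identity) quantifies separation, a Wilcoxon rank-sum test supplies the
p-value, and a point-biserial correlation between intensity and group
indicator acts as the peak correlation ratio.  Features with AUC >= 0.6 or
<= 0.4, p < 0.001 and |correlation| > 0.5 are flagged as candidate markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import PeakMatrix

__all__ = [
    "ComparisonSpec", "FeatureStats", "subsample_balanced",
    "roc_auc", "wilcoxon_ranksum", "correlation_ratio", "discover",
    "stats_frame",
]

AUC_LOW = 0.4
AUC_HIGH = 0.6
P_MAX = 1e-3
CORR_MIN = 0.5

# exact rank-sum enumeration is used up to this per-group size (no ties)
_EXACT_N = 12


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group comparison within one region of interest.

    ``n_subsample`` caps the number of spectra drawn per group (balanced,
    without replacement); 35,000 matches the scale used on full tissue
    sections and is truncated to the smaller group when data are fewer.
    """

    group_a: str
    group_b: str
    region: str
    n_subsample: int = 35_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("group_a and group_b must differ")
        if self.n_subsample < 1:
            raise ValueError("n_subsample must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.group_a} vs {self.group_b} ({self.region})"


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature discovery statistics for one comparison."""

    feature_mz: float
    auc: float
    p_value: float
    correlation_ratio: float
    candidate: bool
    direction: str  # "higher-in-a" | "higher-in-b" | "none"


def subsample_balanced(matrix: PeakMatrix, spec: ComparisonSpec) -> PeakMatrix:
    """Draw equally many spectra per group from one region, seeded.

    Each group contributes ``min(n_subsample, smaller group size)`` rows,
    uniformly without replacement.  Raises if a group is absent from the
    region.
    """
    region_mask = matrix.meta["region"].to_numpy() == spec.region
    idx_a = np.flatnonzero(region_mask & (matrix.meta["group"].to_numpy() == spec.group_a))
    idx_b = np.flatnonzero(region_mask & (matrix.meta["group"].to_numpy() == spec.group_b))
    for name, idx in ((spec.group_a, idx_a), (spec.group_b, idx_b)):
        if idx.size == 0:
            raise ValueError(f"group {name!r} has no spectra in region {spec.region!r}")
    n = min(spec.n_subsample, idx_a.size, idx_b.size)
    rng = np.random.default_rng(spec.seed)
    take_a = rng.choice(idx_a, size=n, replace=False)
    take_b = rng.choice(idx_b, size=n, replace=False)
    return matrix.subset_rows(np.concatenate([np.sort(take_a), np.sort(take_b)]))


def roc_auc(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """AUC = P(a > b) + 0.5 P(a = b), via the rank (Mann-Whitney) identity.

    Orientation: > 0.5 means the first group has the higher intensities.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _auc_columns(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Column-wise AUC for (n_a, p) vs (n_b, p) arrays."""
    ranks = sps.rankdata(np.vstack([xa, xb]), axis=0)
    u = ranks[: xa.shape[0]].sum(axis=0) - xa.shape[0] * (xa.shape[0] + 1) / 2.0
    return u / (xa.shape[0] * xb.shape[0])


def wilcoxon_ranksum(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when both samples have <= 12 observations and the
    pooled data are tie-free; otherwise the normal approximation with tie
    and continuity corrections.  Identical constant samples give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and a.size <= _EXACT_N and b.size <= _EXACT_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def _p_columns(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Column-wise two-sided rank-sum p-values, matching wilcoxon_ranksum."""
    n = xa.shape[0] + xb.shape[0]
    if n > 2 * _EXACT_N:
        with np.errstate(invalid="ignore"):
            res = sps.mannwhitneyu(xa, xb, alternative="two-sided",
                                   method="asymptotic", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        # all-constant columns: sd of U is 0 and scipy yields nan; no evidence
        p[np.isnan(p)] = 1.0
        return p
    return np.array([wilcoxon_ranksum(xa[:, j], xb[:, j]) for j in range(xa.shape[1])])


def correlation_ratio(feature_intensities: Sequence[float], labels: Sequence[int]) -> float:
    """Point-biserial Pearson correlation of intensity with the group-a flag.

    Returns 0 (with a warning) when either vector has zero variance.
    """
    x = np.asarray(feature_intensities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("intensities and labels must have the same length")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance in correlation_ratio input; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _corr_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def discover(matrix: PeakMatrix, spec: ComparisonSpec) -> list[FeatureStats]:
    """Score every feature of a peak matrix for one comparison.

    Applies balanced subsampling, then computes AUC, rank-sum p and
    correlation ratio per feature.  ``candidate`` is true iff
    (AUC >= 0.6 or AUC <= 0.4) and p < 0.001 and |correlation| > 0.5;
    ``direction`` reflects the AUC side.
    """
    sub = subsample_balanced(matrix, spec)
    is_a = sub.meta["group"].to_numpy() == spec.group_a
    xa = sub.intensity[is_a]
    xb = sub.intensity[~is_a]
    aucs = _auc_columns(xa, xb)
    ps = _p_columns(xa, xb)
    rs = _corr_columns(sub.intensity, is_a.astype(float))
    out = []
    for j, f in enumerate(sub.features):
        auc = float(aucs[j])
        direction = ("higher-in-a" if auc >= AUC_HIGH
                     else "higher-in-b" if auc <= AUC_LOW else "none")
        candidate = (direction != "none" and ps[j] < P_MAX and abs(rs[j]) > CORR_MIN)
        out.append(FeatureStats(f.center_mz, auc, float(ps[j]), float(rs[j]),
                                bool(candidate), direction))
    return out


def stats_frame(stats: Sequence[FeatureStats]) -> pd.DataFrame:
    """FeatureStats as a DataFrame, with an informational BH-adjusted column."""
    df = pd.DataFrame(
        {
            "feature_mz": [s.feature_mz for s in stats],
            "auc": [s.auc for s in stats],
            "p_value": [s.p_value for s in stats],
            "correlation_ratio": [s.correlation_ratio for s in stats],
            "candidate": [s.candidate for s in stats],
            "direction": [s.direction for s in stats],
        }
    )
    if len(df):
        df["p_bh"] = sps.false_discovery_control(df["p_value"], method="bh")
    return df
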