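"""Comparison statistics: Bland-Altman, orthogonal regression, angles, t-tests.

Bland-Altman agreement between two measurement series reports the mean of the
paired differences with its standard error, the limits of agreement (half
width, 1.96 times the SD of the differences) and relative measures expressed
as percentages of the grand mean of the pair averages.  Orthogonal (Deming,
error-variance ratio 1 — total least squares) regression gives slope and
intercept symmetric under axis swap, alongside Pearson's r.  Directional
agreement of 3-vectors is summarised by the distribution of pairwise angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "BAResult",
    "RegressionResult",
    "AngleResult",
    "bland_altman",
    "orthogonal_regression",
    "angle_distribution",
    "paired_ttest",
]


@dataclass(frozen=True)
class BAResult:
    mean_difference: float
    sem: float
    loa: float  # 1.96 * SD(differences), half width
    relative_mean_difference_pct: float
    median_relative_difference_pct: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mean_difference": self.mean_difference,
            "SEM": self.sem,
            "LoA": self.loa,
            "relative_mean_difference_pct": self.relative_mean_difference_pct,
            "median_relative_difference_pct": self.median_relative_difference_pct,
            "n": self.n,
        }


def bland_altman(x, y) -> BAResult:
    """Agreement of y against x; differences are d = y - x.

    Relative percentages are taken to the grand mean of the pair averages
    (x + y)/2 over all pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    sd = float(np.std(d, ddof=1))
    grand_mean = float(np.mean((x + y) / 2.0))
    if grand_mean == 0:
        rel = np.nan
        med_rel = np.nan
    else:
        rel = 100.0 * float(np.mean(d)) / grand_mean
        med_rel = 100.0 * float(np.median(d)) / grand_mean
    return BAResult(
        mean_difference=float(np.mean(d)),
        sem=sd / np.sqrt(n),
        loa=1.96 * sd,
        relative_mean_difference_pct=rel,
        median_relative_difference_pct=med_rel,
        n=n,
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.pearson_r,
            "n": self.n,
        }


def orthogonal_regression(x, y) -> RegressionResult:
    """Deming regression with error-variance ratio 1 (total least squares).

    Minimises the sum of squared orthogonal distances to the line; swapping
    x and y maps the slope to its reciprocal.  Pearson's r is computed on
    the raw pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 paired values")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx == 0 and syy == 0:
        raise ValueError("zero variance in both variables")
    if sxy == 0:
        # principal axis is one of the coordinate axes
        slope = 0.0 if sxx >= syy else np.inf
    else:
        slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x)) if np.isfinite(slope) else np.nan
    r = float(sstats.pearsonr(x, y)[0]) if sxx > 0 and syy > 0 else np.nan
    return RegressionResult(slope=float(slope), intercept=intercept, pearson_r=r, n=len(x))


@dataclass(frozen=True)
class AngleResult:
    angles_deg: np.ndarray  # per-pair angle in [0, 180]
    median_angle_deg: float
    n_excluded: int

    def as_dict(self) -> dict:
        return {
            "median_angle_deg": self.median_angle_deg,
            "n": int(len(self.angles_deg)),
            "n_excluded": self.n_excluded,
        }


def angle_distribution(a, b) -> AngleResult:
    """Angles (degrees) between paired 3-vectors; zero-magnitude pairs excluded."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError("vector arrays must have matching shapes")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    cosine = np.sum(a[ok] * b[ok], axis=1) / (na[ok] * nb[ok])
    angles = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    if angles.size == 0:
        raise ValueError("no nonzero vector pairs")
    return AngleResult(
        angles_deg=angles,
        median_angle_deg=float(np.median(angles)),
        n_excluded=int((~ok).sum()),
    )


def paired_ttest(d1, d2) -> tuple[float, float, bool]:
    """Two-sided paired t-test; returns (statistic, p, significant at 0.05).

    Identical samples give (0, 1, False) by convention; a nonzero constant
    difference (degenerate variance) is an error.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D arrays")
    if len(d1) < 2:
        raise ValueError("need at least 2 pairs")
    diff = d2 - d1
    if np.all(diff == 0):
        return 0.0, 1.0, False
    if np.std(diff, ddof=1) == 0:
        raise ValueError("degenerate variance: constant nonzero difference")
    t, p = sstats.ttest_rel(d2, d1)
    return float(t), float(p), bool(p < 0.05)
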