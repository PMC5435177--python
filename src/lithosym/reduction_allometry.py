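"""Reduction and size indices for shaped stone tools, plus the association
statistics used to relate them to symmetry and shape.

The index of invasiveness scores how far retouch scars invade each of 16
face segments (2 faces x 8 segments, each 0 / 0.5 / 1) and averages them:
0 is unretouched, 1 fully covered. Johnson's Thinning Index is plan-view
area over mass (mm^2/g) — thin, heavily worked pieces score high. Size is
the centroid size per view, or the geometric mean over the three views for
the whole artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError, UndefinedStatisticError
from .outlines import Contour, contour_metrics

__all__ = [
    "ZoneScores",
    "ReductionRecord",
    "AssociationResult",
    "invasiveness_index",
    "thinning_index",
    "artifact_size",
    "association",
]

_ALLOWED_SCORES = (0.0, 0.5, 1.0)


@dataclass
class ZoneScores:
    """2 faces x 8 segments of retouch-invasiveness scores in {0, 0.5, 1}."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 8):
            raise ParameterError(f"zone matrix must be 2x8, got {m.shape}")
        if not np.isin(m, _ALLOWED_SCORES).all():
            bad = m[~np.isin(m, _ALLOWED_SCORES)]
            raise ParameterError(f"zone scores must be 0, 0.5 or 1; found {sorted(set(bad.tolist()))}")
        self.matrix = m


@dataclass
class ReductionRecord:
    """Per-artifact reduction and size summary."""

    artifact_id: str
    invasiveness: float | None = None
    centroid_size_top: float | None = None
    centroid_size_lateral: float | None = None
    centroid_size_frontal: float | None = None
    geometric_mean_size: float | None = None
    plan_area: float | None = None
    mass: float | None = None
    jti: float | None = None


@dataclass
class AssociationResult:
    """One association or group-comparison statistic.

    ``kind`` names the statistic reported in ``statistic`` (r, t, W, R2);
    ``value`` is the headline effect quantity (correlation, mean
    difference, or R^2 for regressions). p-values are two-sided.
    """

    kind: str
    statistic: float
    p: float
    n: int
    df: float | None = None
    value: float | None = None
    extra: dict | None = None


def invasiveness_index(z) -> float:
    """Mean zone score over the 16 face segments; 0 unretouched, 1 covered."""
    if not isinstance(z, ZoneScores):
        z = ZoneScores(z)
    return float(z.matrix.sum() / 16.0)


def thinning_index(plan_area: float, mass: float) -> float:
    """Plan-view area (mm^2) divided by mass (g)."""
    if mass <= 0:
        raise ParameterError("mass must be positive")
    if plan_area < 0:
        raise ParameterError("plan area must be nonnegative")
    return float(plan_area / mass)


def artifact_size(views: dict, mode: str = "size") -> dict:
    """Per-view centroid size and whole-artifact geometric-mean size.

    ``views`` maps view names to contours. The whole-artifact value is the
    geometric mean over the three views of either the centroid sizes
    (``mode="size"``, default) or the outline areas (``mode="area"``); it
    is absent unless all three views are present.
    """
    if not views:
        raise ParameterError("at least one view is required")
    if mode not in ("size", "area"):
        raise ParameterError(f"unknown size mode {mode!r}")
    per_view = {}
    for name, c in views.items():
        m = contour_metrics(c) if isinstance(c, Contour) else contour_metrics(Contour("x", "top", c))
        per_view[name] = m["centroid_size"] if mode == "size" else m["area"]
    geo = None
    if all(v in per_view for v in ("top", "lateral", "frontal")):
        vals = np.array([per_view["top"], per_view["lateral"], per_view["frontal"]])
        geo = float(np.exp(np.mean(np.log(vals))))
    return {"per_view": per_view, "geometric_mean": geo, "mode": mode}


def _check_variance(*arrays):
    for a in arrays:
        if np.ptp(a) == 0:
            raise UndefinedStatisticError("zero variance in input vector")


def association(x, y, method: str = "pearson") -> AssociationResult:
    """Association between two vectors, or a two-group comparison.

    Paired methods (``pearson``, ``spearman``, ``ols``) require equal
    lengths; group methods (``student_t``, ``welch_t``, ``wilcoxon``)
    treat x and y as the two samples. The Wilcoxon test is the two-sample
    rank-sum, reported as the Mann-Whitney W of the first sample; Student's
    t is the pooled-variance test with df = n1 + n2 - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ParameterError("inputs must be 1-D vectors")
    paired = method in ("pearson", "spearman", "ols")
    if paired and len(x) != len(y):
        raise ParameterError(f"{method} requires equal-length vectors")
    if min(len(x), len(y)) < 3:
        raise ParameterError("need at least 3 observations per vector")

    if method == "pearson":
        _check_variance(x, y)
        r = float(stats.pearsonr(x, y).statistic)
        n = len(x)
        df = n - 2
        if abs(r) >= 1.0:
            t = np.inf * np.sign(r)
            p = 0.0
        else:
            t = r * np.sqrt(df / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), df)
        return AssociationResult("r", statistic=r, p=float(p), n=n, df=df,
                                 value=r, extra={"t": float(t)})
    if method == "spearman":
        _check_variance(x, y)
        res = stats.spearmanr(x, y)
        return AssociationResult("rho", statistic=float(res.statistic), p=float(res.pvalue),
                                 n=len(x), df=len(x) - 2, value=float(res.statistic))
    if method == "ols":
        _check_variance(x)
        fit = stats.linregress(x, y)
        n = len(x)
        r2 = float(fit.rvalue**2)
        return AssociationResult(
            "R2", statistic=r2, p=float(fit.pvalue), n=n, df=n - 2, value=r2,
            extra={"slope": float(fit.slope), "intercept": float(fit.intercept),
                   "slope_se": float(fit.stderr)},
        )
    if method in ("student_t", "welch_t"):
        equal_var = method == "student_t"
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            if np.mean(x) == np.mean(y):
                # identical constant groups: no evidence of difference
                return AssociationResult("t", statistic=0.0, p=1.0, n=len(x) + len(y),
                                         df=len(x) + len(y) - 2, value=0.0)
            raise UndefinedStatisticError("zero variance in both groups with unequal means")
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        df = len(x) + len(y) - 2 if equal_var else float(res.df)
        return AssociationResult("t", statistic=float(res.statistic), p=float(res.pvalue),
                                 n=len(x) + len(y), df=df,
                                 value=float(np.mean(x) - np.mean(y)))
    if method == "wilcoxon":
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        return AssociationResult("W", statistic=float(res.statistic), p=float(res.pvalue),
                                 n=len(x) + len(y), value=float(res.statistic))
    raise ParameterError(f"unknown association method {method!r}")
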