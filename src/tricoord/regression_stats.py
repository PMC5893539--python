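"""Log-scale pairwise regression of expression parameters and the
two-slope comparison test.

The discrepancy between transcriptome parameters is quantified by ordinary
least squares on log2 RPKM, e.g. ``log2(TA) = mu + beta * log2(RA) + eps``,
and a fitted replicate-vs-replicate regression serves as the noise
baseline.  Two slopes are compared via separate Student-t confidence
intervals (per-interval coverage 97.5%, a Bonferroni-style pair giving a
joint 5% level) and via the normal-approximation score

    t = (beta2_hat - beta1_hat) / sqrt(se2^2 + se1^2),

whose two-sided p-value is computed on the log scale so that values far
below 1e-300 remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_io import ExpressionProfile

__all__ = ["RegressionFit", "SlopeComparison", "fit_loglog", "slope_ci",
           "compare_slopes", "pairwise_panel"]


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit of log2(y) on log2(x)."""

    slope: float
    intercept: float
    slope_se: float
    df: int          # residual degrees of freedom, n - 2
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if self.df != self.n - 2 or self.df < 1:
            raise ValueError("df must equal n - 2 and be >= 1")
        if not self.slope_se >= 0:
            raise ValueError("slope_se must be non-negative")


@dataclass(frozen=True)
class SlopeComparison:
    """Result of comparing two regression slopes."""

    ci1: tuple[float, float]
    ci2: tuple[float, float]
    ci_level: float          # per-interval coverage, e.g. 0.975
    overlap: bool
    t_score: float
    log10_p: float           # log10 of the two-sided normal p-value


def fit_loglog(y, x) -> RegressionFit:
    """OLS of log2(y) on log2(x); pairs with a non-positive value are dropped.

    ``y`` is the response (first symbol in a panel name like ``ta_vs_ra``).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("x and y must be paired (same length)")
    ok = (x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 positive pairs, got {n}")
    res = stats.linregress(np.log2(x), np.log2(y))
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         slope_se=float(res.stderr), df=n - 2,
                         r_squared=float(res.rvalue ** 2), n=n)


def slope_ci(fit: RegressionFit, tail: float = 0.0125) -> tuple[float, float]:
    """Student-t confidence interval ``slope -/+ t_{tail, df} * slope_se``.

    ``tail`` is the one-sided tail probability; the default 0.0125 gives a
    97.5% interval, so a non-overlapping pair of such intervals implies a
    difference at the joint 5% level.
    """
    if not 0 < tail < 0.5:
        raise ValueError("tail must be in (0, 0.5)")
    t = stats.t.ppf(1.0 - tail, fit.df)
    half = t * fit.slope_se
    return (float(fit.slope - half), float(fit.slope + half))


def _log10_two_sided_normal_p(t_score: float) -> float:
    # logsf is evaluated asymptotically by scipy, so |t| ~ 40 (p ~ 1e-350)
    # stays finite instead of underflowing to 0.
    return float((math.log(2.0) + stats.norm.logsf(abs(t_score))) / math.log(10.0))


def compare_slopes(fit1: RegressionFit, fit2: RegressionFit,
                   tail: float = 0.0125) -> SlopeComparison:
    """Compare two slopes: CI overlap plus the normal-approximation score test.

    Swapping the arguments negates ``t_score`` and preserves the p-value and
    the overlap flag.
    """
    ci1 = slope_ci(fit1, tail)
    ci2 = slope_ci(fit2, tail)
    overlap = bool(ci1[0] <= ci2[1]) and bool(ci2[0] <= ci1[1])
    t_score = (fit2.slope - fit1.slope) / math.hypot(fit1.slope_se, fit2.slope_se)
    return SlopeComparison(ci1=ci1, ci2=ci2, ci_level=1.0 - 2.0 * tail,
                           overlap=overlap, t_score=float(t_score),
                           log10_p=_log10_two_sided_normal_p(t_score))


def pairwise_panel(profile: ExpressionProfile) -> dict[str, RegressionFit]:
    """The scatter-panel fits: TR ~ RA, TA ~ RA and, when two mRNA-abundance
    replicates exist, RA2 ~ RA1 as the experimental-noise baseline.

    Panel keys name the response first (``tr_vs_ra`` fits TR on RA).
    """
    v = profile.values
    panel = {
        "tr_vs_ra": fit_loglog(v["tr"], v["ra"]),
        "ta_vs_ra": fit_loglog(v["ta"], v["ra"]),
    }
    if profile.replicates is not None and "ra" in profile.replicates.columns.get_level_values(0):
        reps = sorted(profile.replicates["ra"].columns)
        if len(reps) >= 2:
            panel["ra2_vs_ra1"] = fit_loglog(profile.replicates[("ra", reps[1])],
                                             profile.replicates[("ra", reps[0])])
    return panel


def fit_to_dict(fit: RegressionFit) -> dict:
    return {"slope": fit.slope, "intercept": fit.intercept, "slope_se": fit.slope_se,
            "df": fit.df, "r_squared": fit.r_squared, "n": fit.n}


def comparison_to_dict(cmp: SlopeComparison) -> dict:
    return {"ci1": list(cmp.ci1), "ci2": list(cmp.ci2), "ci_level": cmp.ci_level,
            "overlap": cmp.overlap, "t_score": cmp.t_score, "log10_p": cmp.log10_p}
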