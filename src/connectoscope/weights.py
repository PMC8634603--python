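"""Distributional statistics of connection weights.

Interareal connection weights (FLN) are heterogeneous over several orders
of magnitude and close to log-normal: a maximum-likelihood Gaussian fit on
the log10 values summarizes the distribution.  Feedforward projections
(SLN > 0.5) are compared with feedback projections (SLN < 0.5) on the
log10 FLN scale with two-sample KS, t and F tests and the Hedges g
standardized mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "LogNormalFit",
    "FFFBComparison",
    "fit_log10_normal",
    "density_histogram",
    "hedges_g",
    "compare_ff_fb",
]


@dataclass
class LogNormalFit:
    """ML Gaussian parameters of log10-transformed weights."""

    mu_log10: float
    sigma_log10: float
    n_values: int
    span_orders: float  # max(log10) - min(log10)


def fit_log10_normal(fln_values) -> LogNormalFit:
    """Maximum-likelihood Gaussian fit on log10 of positive weights.

    Absent connections (zeros) must be filtered out first; a non-positive
    value raises.  The ML sigma uses the 1/n normalization.
    """
    v = np.asarray(fln_values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    if np.any(v <= 0):
        raise ValueError("non-positive values; filter absent connections first")
    lv = np.log10(v)
    return LogNormalFit(
        mu_log10=float(lv.mean()),
        sigma_log10=float(lv.std(ddof=0)),
        n_values=int(v.size),
        span_orders=float(lv.max() - lv.min()),
    )


def density_histogram(
    values, bin_size: float, n_total: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram: counts / (bin_size * n_total).

    Returns ``(bin_edges, heights)``.  Bins are anchored at integer
    multiples of ``bin_size`` counted from zero, starting at or below the
    data minimum, so histograms are reproducible regardless of sample.
    ``n_total`` defaults to the number of input values, in which case
    ``sum(height) * bin_size == 1``; pass a larger total to express the
    heights as a fraction of a wider population.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return np.array([]), np.array([])
    if n_total is None:
        n_total = v.size
    lo = math.floor(v.min() / bin_size)
    hi = math.floor(v.max() / bin_size) + 1
    edges = np.arange(lo, hi + 1) * bin_size
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts / (bin_size * n_total)


def hedges_g(x, y) -> float:
    """Hedges g: pooled-SD standardized mean difference, bias-corrected.

    g = J * (mean(x) - mean(y)) / s_pooled with the small-sample
    correction J = 1 - 3 / (4 df - 1), df = nx + ny - 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 members")
    df = nx + ny - 2
    s_pooled = math.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / df
    )
    if s_pooled == 0:
        return 0.0
    correction = 1.0 - 3.0 / (4.0 * df - 1.0)
    return correction * (x.mean() - y.mean()) / s_pooled


@dataclass
class FFFBComparison:
    """Feedforward vs feedback log10 FLN comparison."""

    mean_log10_ff: float
    mean_log10_fb: float
    n_ff: int
    n_fb: int
    ks_p: float
    t_p: float
    f_p: float
    hedges_g: float
    ks_statistic: float
    t_statistic: float
    f_statistic: float


def compare_ff_fb(fln_values, sln_values) -> FFFBComparison:
    """Compare FF (SLN > 0.5) and FB (SLN < 0.5) connection weights.

    Tests run on log10 FLN: two-sided two-sample KS, equal-variance t, and
    the variance-ratio F test (two-sided); effect size is Hedges g
    (FF minus FB).  Connections with SLN exactly 0.5 or undefined are left
    out of both groups.
    """
    fln = np.asarray(fln_values, dtype=float)
    sln = np.asarray(sln_values, dtype=float)
    if fln.shape != sln.shape:
        raise ValueError("fln and sln must be aligned")
    ok = np.isfinite(sln) & (fln > 0)
    ff = np.log10(fln[ok & (sln > 0.5)])
    fb = np.log10(fln[ok & (sln < 0.5)])
    if ff.size < 2 or fb.size < 2:
        raise ValueError("each of FF and FB needs at least 2 connections")
    ks = stats.ks_2samp(ff, fb, alternative="two-sided")
    tt = stats.ttest_ind(ff, fb, equal_var=True)
    f_stat = ff.var(ddof=1) / fb.var(ddof=1)
    fdist = stats.f(ff.size - 1, fb.size - 1)
    f_p = 2.0 * min(fdist.cdf(f_stat), fdist.sf(f_stat))
    return FFFBComparison(
        mean_log10_ff=float(ff.mean()),
        mean_log10_fb=float(fb.mean()),
        n_ff=int(ff.size),
        n_fb=int(fb.size),
        ks_p=float(ks.pvalue),
        t_p=float(tt.pvalue),
        f_p=float(min(f_p, 1.0)),
        hedges_g=float(hedges_g(ff, fb)),
        ks_statistic=float(ks.statistic),
        t_statistic=float(tt.statistic),
        f_statistic=float(f_stat),
    )
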