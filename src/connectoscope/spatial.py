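"""Spatial embedding: distance distributions, the exponential distance
rule (EDR), and its allometric scaling across species.

The EDR states that the probability of an axonal projection of length d
decays as ``p(d) = c * exp(-lambda * d)``.  It is fitted, as in the
connectomics literature, by histogramming per-neuron projection lengths
(counts divided by the total number of projections), then ordinary least
squares of log10(bar height) on the bin-centre distance:

    slope (log10 per mm)  ->  lambda = -slope * ln(10)   [1/mm]
    intercept (log10)     ->  c = 10 ** intercept

Across species the decay rate follows a power law in gray-matter volume;
the allometric fit is OLS of log10(lambda) on log10(volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "lambda_from_log10_slope",
    "prefactor_from_log10_intercept",
    "EDRModel",
    "EDRResults",
    "fit_edr",
    "fln_distance_profile",
    "compare_distance_distributions",
    "DistanceComparison",
    "AllometricModel",
    "AllometricResults",
    "fit_allometric",
]

_LN10 = math.log(10.0)


def lambda_from_log10_slope(slope_log10: float) -> float:
    """Convert a log10-per-mm histogram slope to the EDR decay rate.

    log10 p(d) = slope * d + intercept  is  p(d) = c e^{-lambda d} with
    lambda = -slope * ln(10).  A non-negative slope means no decay
    (lambda = 0).
    """
    return -slope_log10 * _LN10 if slope_log10 < 0 else 0.0


def prefactor_from_log10_intercept(intercept_log10: float) -> float:
    """c = 10 ** intercept of the log10 histogram fit."""
    return 10.0 ** intercept_log10


@dataclass
class EDRResults:
    """Exponential-distance-rule fit of a projection-length sample."""

    bin_size_mm: float
    slope_log10: float      # log10 height per mm
    intercept_log10: float
    lam: float              # decay rate, 1/mm
    c: float                # prefactor
    n_lengths: int
    n_bins: int
    bin_centers: np.ndarray
    heights: np.ndarray     # counts / total, per bin

    def predict(self, d) -> np.ndarray:
        """p(d) = c exp(-lambda d)."""
        return self.c * np.exp(-self.lam * np.asarray(d, dtype=float))

    def summary(self) -> str:
        return (
            "Exponential distance rule fit\n"
            f"  n lengths: {self.n_lengths}   bin size: {self.bin_size_mm} mm"
            f"   nonempty bins: {self.n_bins}\n"
            f"  log10 fit: slope {self.slope_log10:.4f} /mm, "
            f"intercept {self.intercept_log10:.4f}\n"
            f"  lambda = {self.lam:.4f} /mm   c = {self.c:.4f}"
        )

    def plot(self, ax=None):
        """Histogram bars (log scale) with the fitted exponential."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.bar(self.bin_centers, self.heights, width=self.bin_size_mm * 0.9)
        d = np.linspace(0, self.bin_centers.max(), 200)
        ax.plot(d, self.predict(d), "r-")
        ax.set_yscale("log")
        ax.set_xlabel("projection length (mm)")
        ax.set_ylabel("fraction of projections")
        return ax


class EDRModel:
    """Histogram-based EDR estimator for per-neuron projection lengths.

    The linear fit to the log10 bar heights is, by default, weighted by
    the square root of the bin counts — the delta-method precision of a
    log-transformed Poisson count — because on an exponential sample the
    sparse far bins otherwise drag the slope steep (the downward bias of
    log of a small count).  ``weighting='equal'`` reproduces a plain
    unweighted fit to the bars.
    """

    def __init__(
        self, lengths, bin_size_mm: float = 2.0, weighting: str = "counts"
    ):
        self.lengths = np.asarray(lengths, dtype=float)
        if self.lengths.size < 100:
            raise ValueError("need at least 100 projection lengths")
        if bin_size_mm <= 0:
            raise ValueError("bin size must be positive")
        if weighting not in ("counts", "equal"):
            raise ValueError("weighting must be 'counts' or 'equal'")
        self.bin_size = float(bin_size_mm)
        self.weighting = weighting

    def fit(self) -> EDRResults:
        v = self.lengths
        n_bins = int(math.floor(v.max() / self.bin_size)) + 1
        edges = np.arange(n_bins + 1) * self.bin_size
        counts, _ = np.histogram(v, bins=edges)
        heights = counts / v.size
        centers = (edges[:-1] + edges[1:]) / 2
        keep = counts > 0  # empty bins have no defined log height
        if keep.sum() < 3:
            raise ValueError("fewer than 3 nonempty bins")
        w = np.sqrt(counts[keep]) if self.weighting == "counts" else None
        slope, intercept = np.polyfit(
            centers[keep], np.log10(heights[keep]), 1, w=w
        )
        return EDRResults(
            bin_size_mm=self.bin_size,
            slope_log10=float(slope),
            intercept_log10=float(intercept),
            lam=lambda_from_log10_slope(float(slope)),
            c=prefactor_from_log10_intercept(float(intercept)),
            n_lengths=int(v.size),
            n_bins=int(keep.sum()),
            bin_centers=centers[keep],
            heights=heights[keep],
        )


def fit_edr(
    projection_lengths, bin_size: float = 2.0, weighting: str = "counts"
) -> EDRResults:
    """Fit the EDR to a sample of projection lengths (see :class:`EDRModel`)."""
    return EDRModel(projection_lengths, bin_size, weighting).fit()


def fln_distance_profile(
    fln_values,
    distances,
    window_points: int = 173,
    stride: int = 20,
) -> pd.DataFrame:
    """Sliding-window mean/SD of log10 FLN against interareal distance.

    Pairs (FLN > 0, finite distance) are sorted by distance; a window of
    ``window_points`` consecutive pairs advances by ``stride``.  Each row
    reports the window's mean distance and the mean and SD of its log10
    FLN values.  A window larger than the data collapses to one global
    window.
    """
    fln = np.asarray(fln_values, dtype=float)
    d = np.asarray(distances, dtype=float)
    ok = (fln > 0) & np.isfinite(d)
    fln, d = fln[ok], d[ok]
    if fln.size == 0:
        raise ValueError("no positive-FLN pairs with finite distance")
    order = np.argsort(d, kind="stable")
    lf = np.log10(fln[order])
    ds = d[order]
    n = ds.size
    w = min(window_points, n)
    starts = range(0, n - w + 1, max(1, stride))
    rows = [
        {
            "distance_mm": ds[i : i + w].mean(),
            "mean_log10_fln": lf[i : i + w].mean(),
            "sd_log10_fln": lf[i : i + w].std(),
            "n_points": w,
        }
        for i in starts
    ]
    return pd.DataFrame(rows)


@dataclass
class DistanceComparison:
    """Two-sample KS comparison of interareal distance distributions."""

    ks_statistic: float
    ks_p: float
    fit_all: tuple[float, float]      # Gaussian ML (mean, sd)
    fit_sampled: tuple[float, float]


def compare_distance_distributions(
    all_pairs, sampled_pairs
) -> DistanceComparison:
    """KS-compare distances among all areas vs the injected subset.

    Both samples also get maximum-likelihood Gaussian fits, matching how
    distance histograms are summarized.
    """
    x = np.asarray(all_pairs, dtype=float)
    y = np.asarray(sampled_pairs, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ks = stats.ks_2samp(x, y, alternative="two-sided")
    return DistanceComparison(
        ks_statistic=float(ks.statistic),
        ks_p=float(ks.pvalue),
        fit_all=(float(x.mean()), float(x.std())),
        fit_sampled=(float(y.mean()), float(y.std())),
    )


@dataclass
class AllometricResults:
    """Power law of the EDR decay rate against gray-matter volume."""

    species: pd.DataFrame
    slope: float        # d log10(lambda) / d log10(volume)
    intercept: float    # log10(lambda) at volume 1 mm^3
    r_squared: float

    def predict_lambda(self, gm_volume_mm3) -> np.ndarray:
        """lambda(V) = 10**intercept * V**slope."""
        v = np.asarray(gm_volume_mm3, dtype=float)
        if np.any(v <= 0):
            raise ValueError("volumes must be positive")
        return 10.0 ** self.intercept * v ** self.slope

    def summary(self) -> str:
        return (
            "Allometric scaling of the EDR decay rate\n"
            f"  species: {len(self.species)}\n"
            f"  log10(lambda) = {self.slope:.4f} log10(GM volume) "
            f"+ {self.intercept:.4f}   (R^2 = {self.r_squared:.4f})"
        )


class AllometricModel:
    """log-log OLS of decay rate on gray-matter volume across species.

    ``species_table`` needs columns ``name, lambda_mm, gm_volume_mm3``.
    """

    def __init__(self, species_table: pd.DataFrame):
        t = pd.DataFrame(species_table)
        required = {"name", "lambda_mm", "gm_volume_mm3"}
        if not required.issubset(t.columns):
            raise ValueError(f"species table needs columns {sorted(required)}")
        if len(t) < 2:
            raise ValueError("need at least 2 species")
        if (t["lambda_mm"] <= 0).any() or (t["gm_volume_mm3"] <= 0).any():
            raise ValueError("lambda and volume must be positive")
        self.table = t

    def fit(self) -> AllometricResults:
        x = np.log10(self.table["gm_volume_mm3"].to_numpy(dtype=float))
        y = np.log10(self.table["lambda_mm"].to_numpy(dtype=float))
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return AllometricResults(
            species=self.table.copy(),
            slope=float(slope),
            intercept=float(intercept),
            r_squared=r2,
        )


def fit_allometric(species_table) -> AllometricResults:
    """Fit the cross-species power law (see :class:`AllometricModel`)."""
    return AllometricModel(species_table).fit()
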