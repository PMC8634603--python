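"""Microstructural gradients along the hierarchy.

Spine counts on the basal dendritic tree of layer-3 pyramidal neurons are
available for groups of areas (a published spine count can cover several
parcellation areas).  The hierarchy index is normalized to its maximum,
averaged within each group, and correlated with spine count.  Spine count
is also related to neural density by a log-log power law, and to position
along the rostrocaudal axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_microstructure_table",
    "correlate_spine_hierarchy",
    "fit_density_powerlaw",
    "correlate_rostrocaudal",
    "CorrelationResult",
    "PowerLawFit",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass
class PowerLawFit:
    exponent: float
    intercept_log10: float
    n: int


def read_microstructure_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read the table: group, member_areas (';'-separated), spine_count,
    optional neural_density and rostrocaudal_mm."""
    t = pd.read_csv(path, delimiter=delimiter)
    required = {"group", "member_areas", "spine_count"}
    if not required.issubset(t.columns):
        raise ValueError(f"microstructure table needs columns {sorted(required)}")
    if (t["spine_count"] <= 0).any():
        raise ValueError("spine counts must be positive")
    t = t.copy()
    t["member_areas"] = t["member_areas"].map(
        lambda s: [a.strip() for a in str(s).split(";") if a.strip()]
    )
    if t["member_areas"].map(len).eq(0).any():
        raise ValueError("every group needs at least one member area")
    return t


def correlate_spine_hierarchy(
    table: pd.DataFrame,
    hierarchy: pd.Series,
    mode: str = "average_h",
) -> CorrelationResult:
    """Pearson correlation of spine count with group-averaged hierarchy.

    Hierarchy indices are first normalized to a maximum of 1.  With
    ``mode='average_h'`` (default) each group's hierarchy is the mean
    normalized index over its member areas; ``mode='duplicate'`` instead
    expands each group into one point per member area, duplicating the
    spine count.  Groups with no member matched in ``hierarchy`` are
    excluded with a warning.
    """
    if mode not in ("average_h", "duplicate"):
        raise ValueError("mode must be 'average_h' or 'duplicate'")
    h = hierarchy / hierarchy.max()
    xs, ys = [], []
    for row in table.itertuples():
        members = [a for a in row.member_areas if a in h.index]
        if not members:
            warnings.warn(f"group {row.group!r}: no member matched; excluded")
            continue
        if mode == "average_h":
            xs.append(float(h[members].mean()))
            ys.append(float(row.spine_count))
        else:
            for a in members:
                xs.append(float(h[a]))
                ys.append(float(row.spine_count))
    if len(xs) < 3:
        raise ValueError("need at least 3 matched groups")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationResult(r=float(r), p=float(p), n=len(xs))


def fit_density_powerlaw(spine_count, neural_density) -> PowerLawFit:
    """OLS of log10 spine count on log10 neural density.

    The exponent is the power-law slope (an inverse-cube relation gives
    exactly -3).
    """
    s = np.asarray(spine_count, dtype=float)
    d = np.asarray(neural_density, dtype=float)
    if s.size != d.size or s.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.any(s <= 0) or np.any(d <= 0):
        raise ValueError("all values must be positive")
    slope, intercept = np.polyfit(np.log10(d), np.log10(s), 1)
    return PowerLawFit(
        exponent=float(slope), intercept_log10=float(intercept), n=int(s.size)
    )


def correlate_rostrocaudal(table: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of spine count with rostrocaudal position."""
    if "rostrocaudal_mm" not in table.columns:
        raise ValueError("table has no rostrocaudal_mm column")
    t = table.dropna(subset=["rostrocaudal_mm"])
    if len(t) < 3:
        raise ValueError("need at least 3 rows with coordinates")
    r, p = stats.pearsonr(
        t["spine_count"].astype(float), t["rostrocaudal_mm"].astype(float)
    )
    return CorrelationResult(r=float(r), p=float(p), n=len(t))
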