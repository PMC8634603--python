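"""Laminar hierarchy estimation and the circular hierarchy-weight embedding.

The fraction of supragranular labeled neurons (SLN) of a projection
encodes its direction of information flow: feedforward projections
originate mainly in supragranular layers (SLN > 0.5), feedback projections
in infragranular layers (SLN < 0.5).  Assigning each area a scalar
hierarchy index h such that

    SLN(X <- Y) ~ logistic(h_X - h_Y)

turns the full set of per-injection SLN observations into a global
hierarchy.  The model is a beta regression: each observed SLN is
beta-distributed with mean ``logistic(h_target - h_source)`` and a single
global precision phi, maximized jointly over {h_i} and phi.  A linear
alternative (ordinary least squares on logit-transformed SLN) is provided
for comparison.  The gauge freedom (adding a constant to every h) is
removed by anchoring one reference area at 0; the reported indices are
then affinely rescaled to [0, 1].

The circular embedding places the areas on a disk: radius
``R_i = sqrt(1 - h_i)`` (high areas central) and angles chosen so that
angular separation is proportional to -log10 FLN, fitted by multi-restart
local optimization with the anchor area (V1 in the study) at angle 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.special import expit, logit

__all__ = [
    "HierarchyModel",
    "HierarchyResults",
    "fit_hierarchy_beta",
    "fit_hierarchy_linear",
    "classify_projections",
    "EmbeddingCoordinates",
    "circular_embedding",
]


def _smithson_verkuilen(y: np.ndarray) -> np.ndarray:
    """Nudge boundary observations off {0, 1} via (y(n-1)+1/2)/n.

    Only exact 0/1 values are transformed; interior values, where the beta
    likelihood is already finite, are left untouched.
    """
    n = y.size
    boundary = (y == 0.0) | (y == 1.0)
    return np.where(boundary, (y * (n - 1) + 0.5) / n, y)


@dataclass
class HierarchyResults:
    """Fitted hierarchy indices and diagnostics.

    Attributes
    ----------
    areas : list of str
        Area codes in fit order.
    h : Series
        Hierarchy indices affinely rescaled to [0, 1].
    h_raw : Series
        Unrescaled indices on the logit scale (anchor at 0); differences
        of these predict SLN through the logistic link.
    phi : float or nan
        Beta-regression precision (nan for the linear method).
    pred_obs_correlation : float
        Pearson correlation of predicted vs observed SLN.
    method : str
        "beta" or "linear".
    """

    areas: list[str]
    h: pd.Series
    h_raw: pd.Series
    phi: float
    pred_obs_correlation: float
    method: str
    anchor: str
    loglik: float
    n_obs: int
    converged: bool
    degenerate: bool = False
    components: list[list[str]] | None = None

    def predict(self, target, source) -> float:
        """Predicted SLN of the projection target <- source."""
        return float(expit(self.h_raw[target] - self.h_raw[source]))

    def summary(self) -> str:
        lines = [
            f"Hierarchy fit ({self.method} regression)",
            f"  areas: {len(self.areas)}   observations: {self.n_obs}",
            f"  anchor: {self.anchor} (h_raw = 0)",
            f"  precision phi: {self.phi:.4g}"
            if np.isfinite(self.phi)
            else "  precision phi: n/a (linear)",
            f"  corr(predicted, observed SLN): {self.pred_obs_correlation:.4f}",
            "",
            "  area        h (0-1)     h_raw",
        ]
        for a in self.h.sort_values(ascending=False).index:
            lines.append(f"  {a:<10}  {self.h[a]:8.4f}  {self.h_raw[a]:8.4f}")
        return "\n".join(lines)


class HierarchyModel:
    """Beta/linear regression of SLN on hierarchy differences.

    Parameters
    ----------
    observations : DataFrame or list of tuples
        Columns ``target, source, sln`` and optional ``weight`` — one row
        per existing projection per injection (per-injection SLN values
        enter the likelihood, not the across-injection means).  Weights
        default to 1; pass labeled-neuron counts for count weighting.
    anchor : str, optional
        Reference area fixed at h_raw = 0; defaults to the first target.
    """

    def __init__(self, observations, anchor: str | None = None):
        if not isinstance(observations, pd.DataFrame):
            observations = pd.DataFrame(
                observations, columns=["target", "source", "sln", "weight"][
                    : len(observations[0])
                ]
            )
        obs = observations.copy()
        if "weight" not in obs.columns:
            obs["weight"] = 1.0
        obs = obs[np.isfinite(obs["sln"])]
        if obs.empty:
            raise ValueError("no defined SLN observations")
        if ((obs["sln"] < 0) | (obs["sln"] > 1)).any():
            raise ValueError("SLN values must lie in [0, 1]")
        self.obs = obs.reset_index(drop=True)
        self.areas = sorted(set(obs["target"]) | set(obs["source"]))
        if anchor is None:
            anchor = str(obs["target"].iloc[0])
        if anchor not in self.areas:
            raise ValueError(f"anchor {anchor!r} not among observed areas")
        self.anchor = anchor
        self._check_connected()
        idx = {a: k for k, a in enumerate(self.areas)}
        self._t = self.obs["target"].map(idx).to_numpy()
        self._s = self.obs["source"].map(idx).to_numpy()
        self._w = self.obs["weight"].to_numpy(dtype=float)
        self._y = self.obs["sln"].to_numpy(dtype=float)

    def _check_connected(self) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.areas)
        g.add_edges_from(zip(self.obs["target"], self.obs["source"]))
        comps = [sorted(c) for c in nx.connected_components(g)]
        self.components = comps if len(comps) > 1 else None
        if self.components:
            warnings.warn(
                f"observation graph has {len(comps)} components; indices are "
                "only comparable within a component"
            )

    # -- beta likelihood ----------------------------------------------------

    def _unpack(self, params: np.ndarray) -> tuple[np.ndarray, float]:
        k = self.areas.index(self.anchor)
        h = np.insert(params[:-1], k, 0.0)
        return h, np.exp(params[-1])

    def _negloglik_grad(self, params: np.ndarray, y: np.ndarray):
        h, phi = self._unpack(params)
        eta = h[self._t] - h[self._s]
        mu = expit(eta)
        om = expit(-eta)  # 1 - mu without catastrophic cancellation
        a = mu * phi
        b = om * phi
        w = self._w
        ll = w * (
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
        dl_dmu = phi * (
            -special.digamma(a)
            + special.digamma(b)
            + np.log(y)
            - np.log1p(-y)
        )
        dl_deta = w * dl_dmu * mu * om
        n_areas = len(self.areas)
        grad_h = np.zeros(n_areas)
        np.add.at(grad_h, self._t, dl_deta)
        np.add.at(grad_h, self._s, -dl_deta)
        dl_dphi = w * (
            special.digamma(phi)
            - mu * special.digamma(a)
            - om * special.digamma(b)
            + mu * np.log(y)
            + om * np.log1p(-y)
        )
        k = self.areas.index(self.anchor)
        grad = np.concatenate(
            [np.delete(grad_h, k), [dl_dphi.sum() * phi]]
        )
        return -ll.sum(), -grad

    def _fit_beta(self) -> tuple[np.ndarray, float, float, bool]:
        y = _smithson_verkuilen(self._y)
        h0 = self._linear_solution(eps=1e-3)
        x0 = np.concatenate(
            [np.delete(h0, self.areas.index(self.anchor)), [np.log(5.0)]]
        )
        # bounds keep eta and phi where the beta likelihood is finite:
        # |h| <= 10 spans far more than any observable SLN contrast, and
        # log(phi) <= 12 (~1.6e5) is effectively a perfect-fit plateau
        bounds = [(-10.0, 10.0)] * (x0.size - 1) + [(-5.0, 12.0)]
        res = optimize.minimize(
            self._negloglik_grad,
            x0,
            args=(y,),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000},
        )
        h, phi = self._unpack(res.x)
        return h, phi, -res.fun, bool(res.success)

    # -- linear (logit-OLS) -------------------------------------------------

    def _linear_solution(self, eps: float = 1e-3) -> np.ndarray:
        y = logit(np.clip(self._y, eps, 1.0 - eps))
        n_areas = len(self.areas)
        k = self.areas.index(self.anchor)
        cols = [c for c in range(n_areas) if c != k]
        colmap = {c: j for j, c in enumerate(cols)}
        x = np.zeros((y.size, n_areas - 1))
        rows = np.arange(y.size)
        t_in = self._t != k
        s_in = self._s != k
        x[rows[t_in], [colmap[c] for c in self._t[t_in]]] += 1.0
        x[rows[s_in], [colmap[c] for c in self._s[s_in]]] -= 1.0
        sw = np.sqrt(self._w)
        beta, *_ = np.linalg.lstsq(x * sw[:, None], y * sw, rcond=None)
        return np.insert(beta, k, 0.0)

    # -- public fit ---------------------------------------------------------

    def fit(self, method: str = "beta") -> HierarchyResults:
        if method not in ("beta", "linear"):
            raise ValueError("method must be 'beta' or 'linear'")
        degenerate = bool(np.all(self._y == self._y[0]))
        if degenerate:
            warnings.warn("all SLN observations identical; flat hierarchy")
        if method == "beta":
            h_raw, phi, loglik, converged = self._fit_beta()
        else:
            h_raw = self._linear_solution()
            phi, loglik, converged = float("nan"), float("nan"), True
        pred = expit(h_raw[self._t] - h_raw[self._s])
        if np.std(pred) > 0 and np.std(self._y) > 0:
            corr = float(stats.pearsonr(pred, self._y)[0])
        else:
            corr = float("nan")
        span = h_raw.max() - h_raw.min()
        h_norm = (h_raw - h_raw.min()) / span if span > 0 else np.zeros_like(h_raw)
        return HierarchyResults(
            areas=self.areas,
            h=pd.Series(h_norm, index=self.areas),
            h_raw=pd.Series(h_raw, index=self.areas),
            phi=float(phi),
            pred_obs_correlation=corr,
            method=method,
            anchor=self.anchor,
            loglik=float(loglik),
            n_obs=int(self._y.size),
            converged=converged,
            degenerate=degenerate,
            components=self.components,
        )

    @classmethod
    def from_injections(
        cls,
        injections,
        anchor: str | None = None,
        count_weights: bool = False,
        agranular=None,
    ) -> "HierarchyModel":
        """Build per-injection SLN observations from injection records."""
        from .records import AGRANULAR_AREAS, compute_sln

        if agranular is None:
            agranular = AGRANULAR_AREAS
        rows = []
        for inj in injections:
            for src, (s, i) in inj.extrinsic_rows().items():
                sln = compute_sln(s, i, src, agranular)
                if sln is None:
                    continue
                rows.append(
                    {
                        "target": inj.target_area,
                        "source": src,
                        "sln": sln,
                        "weight": float(s + i) if count_weights else 1.0,
                    }
                )
        return cls(pd.DataFrame(rows), anchor=anchor)


def fit_hierarchy_beta(observations, anchor=None) -> HierarchyResults:
    """Beta-regression hierarchy fit (see :class:`HierarchyModel`)."""
    return HierarchyModel(observations, anchor=anchor).fit("beta")


def fit_hierarchy_linear(observations, anchor=None) -> HierarchyResults:
    """Logit-OLS hierarchy fit (see :class:`HierarchyModel`)."""
    return HierarchyModel(observations, anchor=anchor).fit("linear")


def classify_projections(sln):
    """FF (SLN > 0.5), FB (SLN < 0.5) or unclassified (exactly 0.5).

    Accepts a scalar or array; returns a string or object array.
    """
    arr = np.asarray(sln, dtype=float)
    out = np.where(arr > 0.5, "FF", np.where(arr < 0.5, "FB", "unclassified"))
    if arr.ndim == 0:
        return str(out)
    return out


# ---------------------------------------------------------------------------
# circular embedding
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingCoordinates:
    """Polar coordinates of the hierarchy-weight embedding."""

    areas: list[str]
    R: np.ndarray
    theta: np.ndarray  # radians in [0, 2 pi)
    r_scale: float
    objective_value: float
    anchor: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"area": self.areas, "R": self.R, "theta": self.theta}
        ).set_index("area")


def _circdist(delta: np.ndarray) -> np.ndarray:
    d = np.abs(delta) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def _embedding_objective(theta, ii, jj, y):
    c = _circdist(theta[ii] - theta[jj])
    denom = float(c @ c)
    r = max(float(y @ c) / denom, 0.0) if denom > 0 else 0.0
    resid = y - r * c
    return float(resid @ resid), r


def circular_embedding(
    h: pd.Series,
    fln: pd.DataFrame,
    anchor: str | None = None,
    seed: int = 0,
    n_restarts: int = 50,
) -> EmbeddingCoordinates:
    """Disk embedding: radius from hierarchy, angles from connection weight.

    ``R_i = sqrt(1 - h_i)`` puts the top of the hierarchy at the centre.
    The angles minimize

        sum over connected ordered pairs of
            (-log10 FLN_ij - r * circdist(theta_i, theta_j))^2

    jointly over theta and the scale r >= 0 (r is profiled out in closed
    form).  The anchor area is fixed at theta = 0 and the reflection
    ambiguity is resolved by requiring the resultant of the remaining
    angles to lie in the upper half-plane.  Multi-restart L-BFGS from
    seed-controlled random starts; best objective reported.
    """
    areas = list(h.index)
    n = len(areas)
    if n < 3:
        raise ValueError("need at least 3 areas")
    if anchor is None:
        anchor = areas[0]
    if anchor not in areas:
        raise ValueError(f"anchor {anchor!r} not among areas")
    a_idx = areas.index(anchor)
    f = fln.loc[areas, areas].to_numpy(dtype=float)
    np.fill_diagonal(f, 0.0)
    ii, jj = np.nonzero(f > 0)
    if ii.size == 0:
        raise ValueError("no positive FLN entries to embed")
    y = -np.log10(f[ii, jj])

    free = [k for k in range(n) if k != a_idx]

    def expand(x):
        theta = np.zeros(n)
        theta[free] = x
        return theta

    def fun(x):
        obj, _ = _embedding_objective(expand(x), ii, jj, y)
        return obj

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        x0 = rng.uniform(0.0, 2 * np.pi, size=n - 1)
        res = optimize.minimize(fun, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    theta = expand(best.x) % (2 * np.pi)
    obj, r = _embedding_objective(theta, ii, jj, y)
    # reflection convention: resultant of non-anchor angles in upper half-plane
    if np.sin(theta[free]).sum() < 0:
        theta = (-theta) % (2 * np.pi)
    hv = h.to_numpy(dtype=float)
    return EmbeddingCoordinates(
        areas=areas,
        R=np.sqrt(np.clip(1.0 - hv, 0.0, None)),
        theta=theta,
        r_scale=r,
        objective_value=obj,
        anchor=anchor,
    )
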