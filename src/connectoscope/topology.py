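"""Binary-graph analyses of the edge-complete network.

The weighted FLN matrix is binarized (connection present when FLN > 0) and
restricted to the square edge-complete subnetwork where all inputs and
outputs are known.  This module measures density, degree distributions,
dyad and triad motif composition against degree-preserving nulls, cliques
and the core-periphery partition, and the dependence of connection
probability on the functional similarity of area pairs.

Conventions
-----------
* A *clique* of size k requires all k(k-1) ordered edges: it is a clique of
  the mutual (reciprocal-edge) graph.
* The *core* is the union of the member sets of all maximum-size cliques;
  the remaining areas are the periphery.
* Similarity distance of a pair is one minus the cosine similarity of
  their binary in- (or out-) connectivity profiles, with the entries
  involving the pair itself removed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import networkx as nx
from scipy.special import expit

__all__ = [
    "density",
    "degree_sequences",
    "DegreeReport",
    "dyad_census",
    "triad_census",
    "degree_preserving_null",
    "motif_ratio",
    "MotifReport",
    "enumerate_cliques",
    "extract_core",
    "CliqueCoreReport",
    "similarity_distance",
    "ConnectionProbabilityModel",
    "ConnectionProbabilityResults",
    "fit_connection_probability",
    "TRIAD_CLASSES",
]

#: The 16 directed triad isomorphism classes in standard M-A-N notation.
TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)


def _as_adjacency(graph) -> np.ndarray:
    a = np.asarray(graph, dtype=bool)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    a = a.copy()
    np.fill_diagonal(a, False)
    return a


def _to_digraph(a: np.ndarray) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(a.shape[0]))
    g.add_edges_from(zip(*np.nonzero(a)))
    return g


def density(graph) -> float:
    """Directed density rho = M / (N (N-1)), diagonal excluded."""
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return a.sum() / (n * (n - 1))


@dataclass
class DegreeReport:
    in_degrees: np.ndarray
    out_degrees: np.ndarray
    bin_size: int
    in_fit: tuple[float, float]   # ML Gaussian (mean, sd) of in-degrees
    out_fit: tuple[float, float]


def degree_sequences(graph, bin_size: int = 5) -> DegreeReport:
    """In/out degree vectors with ML Gaussian fits.

    Degrees exclude self-connections.  The Gaussian is the maximum
    likelihood fit to the degree values themselves, which is the line
    drawn over the normalized binned densities (counts / (bin size * N)).
    """
    a = _as_adjacency(graph)
    k_in = a.sum(axis=0)
    k_out = a.sum(axis=1)
    fit = lambda k: (float(np.mean(k)), float(np.std(k)))  # noqa: E731
    return DegreeReport(k_in, k_out, bin_size, fit(k_in), fit(k_out))


def dyad_census(graph) -> tuple[float, float, float]:
    """(reciprocal, unidirectional, absent) fractions over unordered pairs."""
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    iu = np.triu_indices(n, k=1)
    fwd = a[iu]
    bwd = a.T[iu]
    n_pairs = len(fwd)
    mutual = int(np.sum(fwd & bwd))
    single = int(np.sum(fwd ^ bwd))
    absent = n_pairs - mutual - single
    return (mutual / n_pairs, single / n_pairs, absent / n_pairs)


def triad_census(graph) -> dict[str, int]:
    """Counts of all 16 directed 3-node isomorphism classes.

    Every unordered node triple falls in exactly one class, so the counts
    sum to C(n, 3).
    """
    a = _as_adjacency(graph)
    if a.shape[0] < 3:
        raise ValueError("need at least 3 nodes")
    census = nx.triadic_census(_to_digraph(a))
    return {cls: int(census[cls]) for cls in TRIAD_CLASSES}


def degree_preserving_null(
    graph,
    n_realizations: int = 100,
    seed: int = 0,
    swap_factor: int = 10,
) -> list[np.ndarray]:
    """Randomized ensemble preserving every in- and out-degree exactly.

    Classic checkerboard rewiring: repeatedly pick two edges (a,b), (c,d)
    and replace them with (a,d), (c,b) unless that would create a
    self-loop or duplicate an existing edge.  Each realization performs
    ``swap_factor * M`` successful swaps (a standard mixing heuristic).
    If no valid swap can be found the graph is non-rewirable; a warning is
    issued and unmodified copies are returned.
    """
    if n_realizations < 1:
        raise ValueError("need n_realizations >= 1")
    a = _as_adjacency(graph)
    n = a.shape[0]
    base_edges = list(zip(*np.nonzero(a)))
    m = len(base_edges)
    rng = np.random.default_rng(seed)
    out = []
    if m < 2:
        warnings.warn("graph has fewer than 2 edges; returning copies")
        return [a.copy() for _ in range(n_realizations)]
    for _ in range(n_realizations):
        edges = [tuple(e) for e in base_edges]
        edge_set = set(edges)
        target_swaps = swap_factor * m
        successes = 0
        tries = 0
        max_tries = 100 * target_swaps
        while successes < target_swaps and tries < max_tries:
            tries += 1
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            (u, v), (x, y) = edges[i], edges[j]
            if u == y or x == v:
                continue
            if (u, y) in edge_set or (x, v) in edge_set:
                continue
            edge_set.discard((u, v))
            edge_set.discard((x, y))
            edge_set.add((u, y))
            edge_set.add((x, v))
            edges[i] = (u, y)
            edges[j] = (x, v)
            successes += 1
        if successes == 0:
            warnings.warn("graph appears non-rewirable; returning copies")
        b = np.zeros_like(a)
        rows, cols = zip(*edges)
        b[list(rows), list(cols)] = True
        out.append(b)
    return out


@dataclass
class MotifReport:
    """Data-vs-null motif composition (2-node dyads and 3-node triads)."""

    dyad_fractions: tuple[float, float, float]
    dyad_null_mean: tuple[float, float, float]
    dyad_null_sd: tuple[float, float, float]
    dyad_ratio: tuple[float, float, float]  # data / null mean; NaN if null 0
    triad_counts: dict[str, int]
    triad_null_mean: dict[str, float]
    triad_null_sd: dict[str, float]
    triad_ratio: dict[str, float]


def motif_ratio(graph, ensemble: list[np.ndarray]) -> MotifReport:
    """Data motif counts relative to a null ensemble's mean, with SD.

    A class whose null mean is zero has an undefined ratio, reported as
    NaN.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    a = _as_adjacency(graph)
    dy = np.array(dyad_census(a))
    tri = triad_census(a)
    dy_null = np.array([dyad_census(b) for b in ensemble])
    tri_null = {cls: [] for cls in TRIAD_CLASSES}
    for b in ensemble:
        tc = triad_census(b)
        for cls in TRIAD_CLASSES:
            tri_null[cls].append(tc[cls])
    dy_mean = dy_null.mean(axis=0)
    dy_sd = dy_null.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dy_ratio = np.where(dy_mean > 0, dy / dy_mean, np.nan)
    tri_mean = {c: float(np.mean(v)) for c, v in tri_null.items()}
    tri_sd = {c: float(np.std(v)) for c, v in tri_null.items()}
    tri_ratio = {
        c: (tri[c] / tri_mean[c] if tri_mean[c] > 0 else float("nan"))
        for c in TRIAD_CLASSES
    }
    return MotifReport(
        dyad_fractions=tuple(dy),
        dyad_null_mean=tuple(dy_mean),
        dyad_null_sd=tuple(dy_sd),
        dyad_ratio=tuple(dy_ratio),
        triad_counts=tri,
        triad_null_mean=tri_mean,
        triad_null_sd=tri_sd,
        triad_ratio=tri_ratio,
    )


def _mutual_graph(a: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(a.shape[0]))
    mutual = a & a.T
    iu = np.triu_indices(a.shape[0], k=1)
    rows, cols = iu[0][mutual[iu]], iu[1][mutual[iu]]
    g.add_edges_from(zip(rows, cols))
    return g


@dataclass
class CliqueCoreReport:
    """Clique-size spectrum and core-periphery partition."""

    clique_counts: dict[int, int]
    clique_proportion: dict[int, float]  # count / C(n, k)
    max_clique_size: int
    core_members: list = field(default_factory=list)
    density_core: float = float("nan")
    density_periphery: float = float("nan")
    density_between: float = float("nan")


def enumerate_cliques(graph, max_cliques: int = 5_000_000) -> CliqueCoreReport:
    """Count cliques of every size k >= 2 (all ordered edges required).

    A size-k clique is a node subset whose induced directed subgraph has
    100% density, i.e. a clique of the mutual-edge graph.  The proportion
    divides the count by C(n, k), the maximum possible number of cliques
    of that size.  ``max_cliques`` bounds the enumeration on pathological
    dense inputs.
    """
    a = _as_adjacency(graph)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    g = _mutual_graph(a)
    counts: dict[int, int] = {}
    seen = 0
    for clique in nx.enumerate_all_cliques(g):
        k = len(clique)
        if k >= 2:
            counts[k] = counts.get(k, 0) + 1
            seen += 1
            if seen > max_cliques:
                raise RuntimeError(
                    "clique enumeration exceeded max_cliques; the mutual "
                    "graph is too dense for exhaustive counting"
                )
    max_size = max(counts) if counts else 1
    proportion = {k: c / math.comb(n, k) for k, c in counts.items()}
    return CliqueCoreReport(counts, proportion, max_size)


def extract_core(graph, labels: list | None = None) -> CliqueCoreReport:
    """Core-periphery partition from maximum cliques.

    The core is the union of the member sets of all maximum-size cliques;
    everything else is the periphery.  Directed densities are reported
    within the core, within the periphery, and between them (both
    directions pooled).
    """
    a = _as_adjacency(graph)
    n = a.shape[0]
    report = enumerate_cliques(a)
    g = _mutual_graph(a)
    maximal = list(nx.find_cliques(g))
    max_size = max((len(c) for c in maximal), default=1)
    core_idx = sorted({v for c in maximal if len(c) == max_size for v in c})
    peri_idx = [i for i in range(n) if i not in set(core_idx)]

    def _block_density(rows, cols, same: bool) -> float:
        if not rows or not cols:
            return float("nan")
        block = a[np.ix_(rows, cols)]
        total = len(rows) * len(cols) - (len(rows) if same else 0)
        return block.sum() / total if total else float("nan")

    report.max_clique_size = max_size
    report.core_members = (
        [labels[i] for i in core_idx] if labels is not None else core_idx
    )
    report.density_core = _block_density(core_idx, core_idx, same=True)
    report.density_periphery = _block_density(peri_idx, peri_idx, same=True)
    if core_idx and peri_idx:
        e_cp = a[np.ix_(core_idx, peri_idx)].sum()
        e_pc = a[np.ix_(peri_idx, core_idx)].sum()
        report.density_between = (e_cp + e_pc) / (
            2 * len(core_idx) * len(peri_idx)
        )
    return report


def similarity_distance(graph, mode: str = "in") -> np.ndarray:
    """Pairwise functional dissimilarity from shared inputs or outputs.

    distance(i, j) = 1 - cosine similarity of the binary in-profiles
    (``mode='in'``: who projects to each area) or out-profiles
    (``mode='out'``: whom each area projects to) of i and j, with the
    entries involving i and j themselves excluded.  Symmetric, in [0, 1];
    NaN where a profile is all-zero (undefined) and on the diagonal.
    """
    a = _as_adjacency(graph).astype(float)
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes")
    if mode not in ("in", "out"):
        raise ValueError("mode must be 'in' or 'out'")
    profiles = a.T if mode == "in" else a  # row i = profile of node i
    d = np.full((n, n), np.nan)
    for i, j in combinations(range(n), 2):
        mask = np.ones(n, dtype=bool)
        mask[[i, j]] = False
        x = profiles[i, mask]
        y = profiles[j, mask]
        nx_, ny_ = np.linalg.norm(x), np.linalg.norm(y)
        if nx_ == 0 or ny_ == 0:
            continue
        val = 1.0 - float(x @ y) / (nx_ * ny_)
        d[i, j] = d[j, i] = min(max(val, 0.0), 1.0)
    return d


@dataclass
class ConnectionProbabilityResults:
    """Fitted logistic decay of connection probability with similarity distance."""

    a: float
    b: float
    n_obs: int
    separated: bool
    converged: bool
    bin_centers: np.ndarray
    empirical_p: np.ndarray
    empirical_reciprocal: np.ndarray
    empirical_unidirectional: np.ndarray

    def predict(self, s) -> np.ndarray:
        """p(s) = 1 / (1 + exp(a + b s))."""
        return expit(-(self.a + self.b * np.asarray(s, dtype=float)))

    def predict_reciprocal(self, s) -> np.ndarray:
        """Reciprocal-pair probability under directional independence: p(s)^2."""
        p = self.predict(s)
        return p * p

    def predict_unidirectional(self, s) -> np.ndarray:
        """Unidirectional-pair probability: 2 p(s) (1 - p(s))."""
        p = self.predict(s)
        return 2.0 * p * (1.0 - p)


class ConnectionProbabilityModel:
    """Bernoulli ML model of directed connection presence vs similarity.

    Observations are all ordered pairs (i, j) with a defined pairwise
    similarity distance s; the outcome is the presence of the directed
    edge i -> j.  The model is logistic, p(s) = 1 / (1 + exp(a + b s)),
    fitted by maximum likelihood on the unbinned data.
    """

    def __init__(self, distances: np.ndarray, graph):
        self.s = np.asarray(distances, dtype=float)
        self.a = _as_adjacency(graph)
        if self.s.shape != self.a.shape:
            raise ValueError("distance matrix must match adjacency shape")

    def fit(self, bin_width: float = 0.05) -> ConnectionProbabilityResults:
        import statsmodels.api as sm

        n = self.a.shape[0]
        xs, ys = [], []
        pair_s, pair_kind = [], []  # per unordered pair, for binned curves
        for i, j in combinations(range(n), 2):
            sij = self.s[i, j]
            if not np.isfinite(sij):
                continue
            xs.extend([sij, sij])
            ys.extend([self.a[i, j], self.a[j, i]])
            pair_s.append(sij)
            both = self.a[i, j] and self.a[j, i]
            one = self.a[i, j] ^ self.a[j, i]
            pair_kind.append("r" if both else ("u" if one else "0"))
        if len(pair_s) < 10:
            raise ValueError("need at least 10 defined pairs")
        x = np.asarray(xs, dtype=float)
        y = np.asarray(ys, dtype=float)
        exog = sm.add_constant(x)
        separated = False
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if y.min() == y.max():
                # degenerate outcome: probability saturates at 0 or 1
                separated = True
                p_hat = min(max(y.mean(), 1e-6), 1 - 1e-6)
                params = np.array([np.log(p_hat / (1 - p_hat)), 0.0])
            else:
                try:
                    res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
                    params = res.params
                    converged = bool(res.mle_retvals.get("converged", True))
                except Exception:  # perfect separation or singular fit
                    separated = True
                    res = sm.GLM(
                        y, exog, family=sm.families.Binomial()
                    ).fit(maxiter=100)
                    params = res.params
        if np.max(np.abs(params)) > 50:
            separated = True
        # Logit fits p = expit(b0 + b1 s); the decay form uses a = -b0, b = -b1
        a_hat, b_hat = -params[0], -params[1]

        pair_s = np.asarray(pair_s)
        kinds = np.asarray(pair_kind)
        edges = np.arange(0.0, pair_s.max() + bin_width, bin_width)
        centers, p_emp, r_emp, u_emp = [], [], [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = (pair_s >= lo) & (pair_s < hi)
            if not m.any():
                continue
            centers.append((lo + hi) / 2)
            kb = kinds[m]
            n_pairs = kb.size
            n_r = np.sum(kb == "r")
            n_u = np.sum(kb == "u")
            p_emp.append((2 * n_r + n_u) / (2 * n_pairs))
            r_emp.append(n_r / n_pairs)
            u_emp.append(n_u / n_pairs)
        return ConnectionProbabilityResults(
            a=float(a_hat),
            b=float(b_hat),
            n_obs=int(y.size),
            separated=separated,
            converged=converged,
            bin_centers=np.asarray(centers),
            empirical_p=np.asarray(p_emp),
            empirical_reciprocal=np.asarray(r_emp),
            empirical_unidirectional=np.asarray(u_emp),
        )


def fit_connection_probability(
    distances: np.ndarray, graph
) -> ConnectionProbabilityResults:
    """Convenience wrapper: fit the logistic connection-probability decay."""
    return ConnectionProbabilityModel(distances, graph).fit()
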