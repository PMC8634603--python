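"""Synthetic connectome generator.

Generates injection datasets with the statistical structure the downstream
analyses assume, so every stage is testable without the atlas data:

* areas are points in a 3-D box, so interareal Euclidean distances are
  unimodal and approximately normal;
* the expected extrinsic weight of a source decays exponentially with its
  distance from the target (the exponential distance rule, decay rate
  ``lambda_true`` per mm) with multiplicative log-normal noise
  (``sigma_log10`` orders of magnitude), which together yield log-normally
  distributed FLN spanning several orders of magnitude;
* a fixed neuron budget is allocated multinomially over sources, so
  per-injection FLN normalization is exact by construction;
* the supragranular/infragranular split of each source's count is
  beta-binomial with mean ``logistic(h_target - h_source)`` (the logit-link
  hierarchy model) and concentration ``kappa``, giving SLN the
  overdispersion real laminar data show;
* per-neuron projection lengths are exponential(``lambda_true``) truncated
  at the maximum interareal distance.

All randomness flows from the single ``seed`` through a splittable
``numpy.random.SeedSequence``, and every output records that seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import distance_matrix as _euclidean_matrix
from scipy.special import expit

from .records import InjectionRecord, write_injections

__all__ = [
    "SyntheticGroundTruth",
    "generate_areas",
    "generate_ground_truth",
    "generate_injection",
    "generate_replicates",
    "generate_projection_lengths",
    "generate_dataset",
    "write_dataset",
    "read_ground_truth",
]


@dataclass
class SyntheticGroundTruth:
    """Latent quantities behind a synthetic connectome.

    Attributes
    ----------
    n_areas : int
        Number of cortical areas.
    positions : ndarray, (n_areas, 3)
        Area barycenters in mm.
    distances : ndarray, (n_areas, n_areas)
        Euclidean interareal distances in mm (symmetric, zero diagonal).
    h_true : ndarray
        True per-area hierarchy indices in [0, 1].
    lambda_true : float
        EDR decay rate in 1/mm.
    sigma_log10 : float
        SD of the between-connection multiplicative noise, log10 scale.
    kappa : float
        Beta-binomial concentration of the laminar split.
    neurons_per_injection : int
        Expected labeled-cell budget per injection.  The realized budget
        of each injection is log-normal with this mean and
        ``budget_sigma_log10`` orders of spread (tracer uptake varies
        strongly between injections), unless the spread is zero.
    budget_sigma_log10 : float
        SD, in log10 units, of the per-injection realized budget.
    seed : int
        Master seed; all randomness derives from it.
    """

    n_areas: int
    positions: np.ndarray = field(repr=False)
    distances: np.ndarray = field(repr=False)
    h_true: np.ndarray = field(repr=False)
    lambda_true: float = 0.3
    sigma_log10: float = 1.0
    kappa: float = 20.0
    neurons_per_injection: int = 10_000
    budget_sigma_log10: float = 0.5
    seed: int = 0

    @property
    def d_max(self) -> float:
        """Maximum pairwise distance; default truncation of length draws."""
        return float(self.distances.max())

    @property
    def area_names(self) -> list[str]:
        return [f"A{i:03d}" for i in range(self.n_areas)]

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k in ("positions", "distances", "h_true"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def _rng(seed: int, *branch: int) -> np.random.Generator:
    """Child generator for a named branch of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=branch))


def generate_areas(
    n_areas: int, box_extent_mm: float = 20.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter areas uniformly in a cube; return positions and distances.

    Pairwise Euclidean distances of uniform points in a box are unimodal
    and close to normal, matching the shape of measured interareal wiring
    distances.
    """
    if n_areas < 2:
        raise ValueError("need at least 2 areas")
    if box_extent_mm <= 0:
        raise ValueError("box extent must be positive")
    rng = _rng(seed, 0)
    positions = rng.uniform(0.0, box_extent_mm, size=(n_areas, 3))
    distances = _euclidean_matrix(positions, positions)
    return positions, distances


def generate_ground_truth(
    n_areas: int = 116,
    box_extent_mm: float = 20.0,
    lambda_true: float = 0.3,
    sigma_log10: float = 1.0,
    kappa: float = 20.0,
    neurons_per_injection: int = 10_000,
    budget_sigma_log10: float = 0.5,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Draw positions, distances and true hierarchy for a synthetic cortex."""
    if lambda_true < 0 or sigma_log10 < 0 or kappa <= 0:
        raise ValueError("rates and concentrations must be non-negative")
    if neurons_per_injection < 1:
        raise ValueError("neuron budget must be positive")
    positions, distances = generate_areas(n_areas, box_extent_mm, seed)
    h_true = _rng(seed, 1).uniform(0.0, 1.0, size=n_areas)
    return SyntheticGroundTruth(
        n_areas=n_areas,
        positions=positions,
        distances=distances,
        h_true=h_true,
        lambda_true=lambda_true,
        sigma_log10=sigma_log10,
        kappa=kappa,
        neurons_per_injection=neurons_per_injection,
        budget_sigma_log10=budget_sigma_log10,
        seed=seed,
    )


def expected_fln(
    gt: SyntheticGroundTruth, target_index: int
) -> np.ndarray:
    """Noise-free expected FLN row of a target: exp(-lambda d), normalized.

    This is the closed form the generator converges to as the neuron
    budget grows with ``sigma_log10 = 0``.
    """
    w = np.exp(-gt.lambda_true * gt.distances[target_index])
    w[target_index] = 0.0
    return w / w.sum()


def _injection_counts(
    gt: SyntheticGroundTruth,
    target_index: int,
    rng: np.random.Generator,
    extra_log10: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial source counts and beta-binomial supragranular counts."""
    n = gt.n_areas
    w = np.exp(-gt.lambda_true * gt.distances[target_index])
    eps = rng.normal(0.0, gt.sigma_log10, size=n) if gt.sigma_log10 > 0 else 0.0
    log10w = np.log10(w) + eps
    if extra_log10 is not None:
        log10w = log10w + extra_log10
    log10w[target_index] = -np.inf  # intrinsic cells not generated
    if not np.isfinite(log10w).any():
        raise ValueError("degenerate expected weights: all zero")
    log10w -= np.nanmax(log10w[np.isfinite(log10w)])
    p = np.power(10.0, log10w, where=np.isfinite(log10w), out=np.zeros(n))
    p /= p.sum()
    budget = gt.neurons_per_injection
    if gt.budget_sigma_log10 > 0:
        # log-normal realized budget with mean = neurons_per_injection
        s = gt.budget_sigma_log10
        mu10 = np.log10(budget) - s * s * np.log(10.0) / 2.0
        budget = max(1, int(round(10.0 ** rng.normal(mu10, s))))
    counts = rng.multinomial(budget, p)
    # laminar split: per-source probability drawn from a beta with mean
    # logistic(h_target - h_source) and concentration kappa
    mu = expit(gt.h_true[target_index] - gt.h_true)
    a = mu * gt.kappa
    b = (1.0 - mu) * gt.kappa
    supra = np.zeros(n, dtype=int)
    pos = counts > 0
    if pos.any():
        psup = rng.beta(a[pos], b[pos])
        supra[pos] = rng.binomial(counts[pos], psup)
    return counts, supra


def _record_from_counts(
    gt: SyntheticGroundTruth, target_index: int, injection_id: str,
    counts: np.ndarray, supra: np.ndarray,
) -> InjectionRecord:
    names = gt.area_names
    rows = {
        names[j]: (int(supra[j]), int(counts[j] - supra[j]))
        for j in np.flatnonzero(counts)
    }
    return InjectionRecord(
        injection_id=injection_id, target_area=names[target_index], rows=rows
    )


def generate_injection(
    target_index: int,
    gt: SyntheticGroundTruth,
    injection_seq: int = 0,
) -> InjectionRecord:
    """Simulate one tracer injection into ``target_index``.

    Expected extrinsic count of source j is proportional to
    ``exp(-lambda d_tj) * 10**eps`` with ``eps ~ N(0, sigma_log10)``;
    realized counts are multinomial with the fixed neuron budget, and the
    supragranular split is beta-binomial (see module docstring).
    """
    if not 0 <= target_index < gt.n_areas:
        raise IndexError("target index out of range")
    rng = _rng(gt.seed, 2, target_index, injection_seq)
    counts, supra = _injection_counts(gt, target_index, rng)
    return _record_from_counts(
        gt, target_index, f"inj-{target_index:03d}-{injection_seq:02d}",
        counts, supra,
    )


def generate_replicates(
    target_index: int,
    k: int,
    gt: SyntheticGroundTruth,
    jitter_log10: float = 0.0,
) -> list[InjectionRecord]:
    """k independent injections into one target, sharing the ground truth.

    ``jitter_log10`` adds an extra per-injection log10 perturbation of the
    expected weights, emulating the replicate-to-replicate variability of
    afferent connection patterns seen with repeated injections.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for r in range(k):
        rng = _rng(gt.seed, 2, target_index, r)
        extra = (
            rng.normal(0.0, jitter_log10, size=gt.n_areas)
            if jitter_log10 > 0
            else None
        )
        counts, supra = _injection_counts(gt, target_index, rng, extra)
        out.append(
            _record_from_counts(
                gt, target_index, f"inj-{target_index:03d}-{r:02d}",
                counts, supra,
            )
        )
    return out


def generate_projection_lengths(
    gt: SyntheticGroundTruth,
    n_neurons: int,
    d_max: float | None = None,
) -> np.ndarray:
    """i.i.d. per-neuron projection lengths, exponential truncated at d_max.

    Drawn by inverse-CDF from exponential(``lambda_true``) truncated to
    [0, d_max]; ``d_max`` defaults to the maximum pairwise distance.
    """
    if n_neurons < 1:
        raise ValueError("need n_neurons >= 1")
    lam = gt.lambda_true
    if lam <= 0:
        raise ValueError("lambda_true must be positive to draw lengths")
    dmax = gt.d_max if d_max is None else d_max
    rng = _rng(gt.seed, 3)
    u = rng.uniform(size=n_neurons)
    mass = -np.expm1(-lam * dmax)  # 1 - exp(-lam dmax)
    return -np.log1p(-u * mass) / lam


def generate_dataset(
    gt: SyntheticGroundTruth,
    targets: list[int] | None = None,
    replicates: int = 1,
    jitter_log10: float = 0.0,
    n_lengths: int = 100_000,
) -> tuple[list[InjectionRecord], np.ndarray]:
    """Injections for each requested target plus a projection-length sample."""
    idx = list(range(gt.n_areas)) if targets is None else list(targets)
    injections: list[InjectionRecord] = []
    for t in idx:
        injections.extend(generate_replicates(t, replicates, gt, jitter_log10))
    lengths = generate_projection_lengths(gt, n_lengths)
    return injections, lengths


def write_dataset(
    gt: SyntheticGroundTruth,
    injections: list[InjectionRecord],
    lengths: np.ndarray,
    out_dir,
) -> dict[str, Path]:
    """Write injections, distances, lengths and a ground-truth sidecar.

    The sidecar (JSON) carries positions, true hierarchy, the true decay
    rate and all noise parameters, so recovery tests can compare fitted
    values against truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "injections": out / "injections.csv",
        "lengths": out / "lengths.csv",
        "distances": out / "distances.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_injections(injections, paths["injections"])
    import pandas as pd

    pd.DataFrame({"length_mm": lengths}).to_csv(paths["lengths"], index=False)
    pd.DataFrame(
        gt.distances, index=gt.area_names, columns=gt.area_names
    ).to_csv(paths["distances"])
    paths["ground_truth"].write_text(json.dumps(gt.to_jsonable()))
    return paths


def read_ground_truth(path) -> SyntheticGroundTruth:
    d = json.loads(Path(path).read_text())
    for k in ("positions", "distances", "h_true"):
        d[k] = np.asarray(d[k])
    return SyntheticGroundTruth(**d)
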