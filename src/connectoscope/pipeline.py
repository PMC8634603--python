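"""End-to-end analysis pipeline.

Orchestrates the full chain — injection tables to FLN/SLN matrices, weight
statistics, binary-graph topology with degree-preserving nulls, the
beta-regression hierarchy with its circular embedding, distance/EDR
analyses, optional microstructure correlations, and (when a synthetic
ground-truth sidecar is present) a parameter-recovery report — and writes
one JSON report per stage plus a provenance block (input hashes, seeds,
versions).  All randomness derives from the configured seed, so repeated
runs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .records import (
    build_edge_complete,
    build_matrices,
    read_injections,
)
from .synthetic import read_ground_truth
from .weights import compare_ff_fb, density_histogram, fit_log10_normal
from .topology import (
    degree_preserving_null,
    degree_sequences,
    density,
    dyad_census,
    extract_core,
    fit_connection_probability,
    motif_ratio,
    similarity_distance,
)
from .hierarchy import HierarchyModel, circular_embedding
from .spatial import (
    compare_distance_distributions,
    fit_edr,
    fln_distance_profile,
)
from .microstructure import (
    correlate_rostrocaudal,
    correlate_spine_hierarchy,
    fit_density_powerlaw,
    read_microstructure_table,
)
from .spatial import fit_allometric

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Inputs, seeds and binning of a full pipeline run.

    Bin sizes follow the conventions of the analyses: 0.5 on log10 FLN,
    0.05 on SLN, 2 mm on distances, 5 on degrees.
    """

    injections: str
    out_dir: str
    lengths: str | None = None
    distances: str | None = None
    species: str | None = None
    microstructure: str | None = None
    ground_truth: str | None = None
    parcellation: list[str] | None = None
    anchor: str | None = None
    seed: int = 0
    null_realizations: int = 100
    embedding_restarts: int = 50
    bin_log10_fln: float = 0.5
    bin_sln: float = 0.05
    bin_distance_mm: float = 2.0
    bin_degree: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _dump(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=default))


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; return the report bundle and write it to out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    rng_seed = int(config.seed)

    def stage(name):
        def deco(fn):
            try:
                bundle[name] = fn()
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            _dump(bundle[name], out / f"{name}.json")
            return bundle[name]

        return deco

    injections = read_injections(config.injections)
    distances_df = (
        pd.read_csv(config.distances, index_col=0)
        if config.distances
        else None
    )
    if config.parcellation is not None:
        sources = list(config.parcellation)
    elif distances_df is not None:
        sources = list(distances_df.columns)
    else:
        sources = sorted(
            {inj.target_area for inj in injections}
            | {a for inj in injections for a in inj.rows}
        )

    matrices = build_matrices(injections, sources)
    edge_complete = build_edge_complete(matrices)
    adj = edge_complete.adjacency
    fln_csv = out / "fln_mean.csv"
    matrices.fln_mean.to_csv(fln_csv)
    matrices.sln_wmean.to_csv(out / "sln_wmean.csv")

    @stage("matrices")
    def _matrices():
        return {
            "n_targets": len(matrices.targets),
            "n_sources": len(matrices.sources),
            "n_possible_connections": matrices.n_possible_connections,
            "coverage_percent": matrices.coverage_percent,
            "n_present": int(matrices.presence.to_numpy().sum()),
            "n_injections": matrices.n_injections,
        }

    @stage("weights")
    def _weights():
        fln = matrices.fln_mean.to_numpy().ravel()
        fln = fln[fln > 0]
        fit = fit_log10_normal(fln)
        edges, heights = density_histogram(np.log10(fln), config.bin_log10_fln)
        sln_flat = matrices.sln_wmean.to_numpy().ravel()
        fln_flat = matrices.fln_mean.to_numpy().ravel()
        report = {
            "lognormal_fit": asdict(fit),
            "histogram": {"edges": edges, "heights": heights},
        }
        try:
            report["ff_fb"] = asdict(compare_ff_fb(fln_flat, sln_flat))
        except ValueError as exc:
            report["ff_fb"] = {"skipped": str(exc)}
        return report

    @stage("topology")
    def _topology():
        deg = degree_sequences(adj, config.bin_degree)
        ensemble = degree_preserving_null(
            adj, config.null_realizations, seed=rng_seed
        )
        motifs = motif_ratio(adj, ensemble)
        core = extract_core(adj, labels=edge_complete.areas)
        report = {
            "density": density(adj),
            "dyad_fractions": dyad_census(adj),
            "in_degree_fit": deg.in_fit,
            "out_degree_fit": deg.out_fit,
            "motifs": asdict(motifs),
            "cliques": {
                "counts": {str(k): v for k, v in core.clique_counts.items()},
                "proportions": {
                    str(k): v for k, v in core.clique_proportion.items()
                },
                "max_size": core.max_clique_size,
            },
            "core": {
                "members": core.core_members,
                "density_core": core.density_core,
                "density_periphery": core.density_periphery,
                "density_between": core.density_between,
            },
        }
        for mode in ("in", "out"):
            try:
                sim = similarity_distance(adj, mode)
                cp = fit_connection_probability(sim, adj)
                report[f"similarity_{mode}"] = {
                    "a": cp.a,
                    "b": cp.b,
                    "separated": cp.separated,
                    "bin_centers": cp.bin_centers,
                    "empirical_p": cp.empirical_p,
                }
            except ValueError as exc:
                report[f"similarity_{mode}"] = {"skipped": str(exc)}
        return report

    model = HierarchyModel.from_injections(injections, anchor=config.anchor)
    hier = model.fit("beta")

    @stage("hierarchy")
    def _hierarchy():
        emb = None
        emb_areas = [a for a in edge_complete.areas if a in hier.h.index]
        if len(emb_areas) >= 3:
            emb = circular_embedding(
                hier.h[emb_areas],
                edge_complete.fln.loc[emb_areas, emb_areas],
                anchor=hier.anchor if hier.anchor in emb_areas else emb_areas[0],
                seed=rng_seed,
                n_restarts=config.embedding_restarts,
            )
        report = {
            "h": hier.h,
            "h_raw": hier.h_raw,
            "phi": hier.phi,
            "pred_obs_correlation": hier.pred_obs_correlation,
            "anchor": hier.anchor,
            "converged": hier.converged,
        }
        if emb is not None:
            emb.to_frame().to_csv(out / "embedding.csv")
            report["embedding"] = {
                "r_scale": emb.r_scale,
                "objective_value": emb.objective_value,
                "anchor": emb.anchor,
            }
        return report

    @stage("spatial")
    def _spatial():
        report = {}
        if config.lengths:
            lengths = pd.read_csv(config.lengths)["length_mm"].to_numpy()
            edr = fit_edr(lengths, config.bin_distance_mm)
            report["edr"] = {
                "slope_log10": edr.slope_log10,
                "intercept_log10": edr.intercept_log10,
                "lambda": edr.lam,
                "c": edr.c,
                "n_lengths": edr.n_lengths,
            }
        if distances_df is not None:
            d = distances_df.to_numpy(dtype=float)
            iu = np.triu_indices(d.shape[0], k=1)
            all_pairs = d[iu]
            tmask = [
                list(distances_df.index).index(t) for t in matrices.targets
            ]
            sub = []
            for ti in tmask:
                for sj in range(d.shape[0]):
                    if sj != ti:
                        sub.append(d[ti, sj])
            cmp = compare_distance_distributions(all_pairs, sub)
            report["distance_comparison"] = asdict(cmp)
            fln_pairs, dist_pairs = [], []
            didx = {a: k for k, a in enumerate(distances_df.index)}
            for t in matrices.targets:
                for s in matrices.sources:
                    if s in didx and t != s:
                        v = matrices.fln_mean.loc[t, s]
                        if v > 0:
                            fln_pairs.append(v)
                            dist_pairs.append(d[didx[t], didx[s]])
            profile = fln_distance_profile(fln_pairs, dist_pairs)
            profile.to_csv(out / "fln_distance_profile.csv", index=False)
            report["fln_distance_profile_rows"] = len(profile)
        if config.species:
            fit = fit_allometric(pd.read_csv(config.species))
            report["allometric"] = {
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
            }
        return report

    if config.microstructure:

        @stage("microstructure")
        def _micro():
            table = read_microstructure_table(config.microstructure)
            report = {
                "spine_hierarchy": asdict(
                    correlate_spine_hierarchy(table, hier.h)
                )
            }
            if "neural_density" in table.columns and table[
                "neural_density"
            ].notna().all():
                report["density_powerlaw"] = asdict(
                    fit_density_powerlaw(
                        table["spine_count"], table["neural_density"]
                    )
                )
            if "rostrocaudal_mm" in table.columns:
                try:
                    report["rostrocaudal"] = asdict(
                        correlate_rostrocaudal(table)
                    )
                except ValueError as exc:
                    report["rostrocaudal"] = {"skipped": str(exc)}
            return report

    if config.ground_truth:

        @stage("recovery")
        def _recovery():
            from scipy.stats import spearmanr

            gt = read_ground_truth(config.ground_truth)
            report = {"lambda_true": gt.lambda_true, "seed": gt.seed}
            if "edr" in bundle.get("spatial", {}):
                lam_hat = bundle["spatial"]["edr"]["lambda"]
                report["lambda_hat"] = lam_hat
                report["lambda_rel_error"] = (
                    abs(lam_hat - gt.lambda_true) / gt.lambda_true
                )
            names = gt.area_names
            common = [a for a in names if a in hier.h.index]
            h_true = pd.Series(gt.h_true, index=names)[common]
            rho = spearmanr(h_true, hier.h[common]).statistic
            report["hierarchy_spearman"] = float(rho)
            return report

    bundle["provenance"] = {
        "seed": rng_seed,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, list)
        },
        "inputs_sha256": {
            k: _sha256(p)
            for k, p in {
                "injections": config.injections,
                "lengths": config.lengths,
                "distances": config.distances,
                "species": config.species,
                "microstructure": config.microstructure,
                "ground_truth": config.ground_truth,
            }.items()
            if p
        },
        "versions": {
            "connectoscope": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    _dump(bundle["provenance"], out / "provenance.json")
    return bundle
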