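"""Raw injection records and connectome matrices.

A retrograde tracer injected into a *target* area labels the cell bodies of
neurons that project to it.  Labeled cells are counted per *source* area and
split by laminar compartment (supragranular = above the centre of layer 4,
infragranular = below).  Two per-connection statistics derive from these
counts:

* FLN (fraction of extrinsic labeled neurons): labeled neurons in a source
  area divided by all labeled neurons extrinsic to the injected area.  The
  connection weight from source to target; per injection the extrinsic FLN
  values sum to one.
* SLN (fraction of supragranular labeled neurons): supragranular count
  divided by the total count in the source area.  SLN > 0.5 marks a
  feedforward projection, SLN < 0.5 a feedback projection.  SLN is undefined
  for agranular sources, where no layer-4 boundary exists.

Injections targeting the same area are aggregated: FLN by arithmetic mean
(a connection absent in one replicate contributes 0), SLN by a labeled-
neuron-count weighted mean, equal to the pooled supra/total fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AGRANULAR_AREAS",
    "TRACERS",
    "InjectionRecord",
    "ConnectomeMatrices",
    "EdgeCompleteNetwork",
    "NoExtrinsicLabelError",
    "SchemaError",
    "compute_fln",
    "compute_sln",
    "aggregate_fln",
    "aggregate_sln",
    "build_matrices",
    "build_edge_complete",
    "read_injections",
    "write_injections",
    "read_matrix",
    "write_matrix",
]

#: Areas with no identifiable layer 4; SLN is undefined for these sources.
AGRANULAR_AREAS = frozenset({"APir", "Pir", "Ent", "A29a-c"})

#: Retrograde tracer codes accepted in injection tables.
TRACERS = ("DY", "FR", "FB", "FE", "CTBgr", "CTBr")


class NoExtrinsicLabelError(ValueError):
    """Raised when an injection labels no neuron outside its own area."""


class SchemaError(ValueError):
    """Raised on malformed injection tables or unknown area codes."""


@dataclass
class InjectionRecord:
    """Labeled-cell counts of one retrograde tracer injection.

    Parameters
    ----------
    injection_id : str
        Unique identifier of the injection.
    target_area : str
        Area code of the injected (target) area.
    rows : dict
        Mapping ``source_area -> (supra_count, infra_count)``.  A row for
        ``target_area`` itself is allowed; it is flagged intrinsic and
        excluded from all FLN computations.
    tracer : str, optional
        One of :data:`TRACERS`.
    projection_lengths : ndarray, optional
        Per-neuron projection lengths in mm.
    """

    injection_id: str
    target_area: str
    rows: dict[str, tuple[int, int]]
    tracer: str | None = None
    projection_lengths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tracer is not None and self.tracer not in TRACERS:
            raise SchemaError(f"unknown tracer {self.tracer!r}")
        for area, (supra, infra) in self.rows.items():
            if supra != int(supra) or infra != int(infra):
                raise SchemaError(f"non-integer count for source {area!r}")
            if supra < 0 or infra < 0:
                raise SchemaError(f"negative count for source {area!r}")
            if supra + infra < 1:
                raise SchemaError(f"empty row for source {area!r}")

    @property
    def has_intrinsic(self) -> bool:
        return self.target_area in self.rows

    def extrinsic_rows(self) -> dict[str, tuple[int, int]]:
        """Rows excluding the intrinsic (target-area) row."""
        return {a: c for a, c in self.rows.items() if a != self.target_area}

    def total_extrinsic(self) -> int:
        return sum(s + i for s, i in self.extrinsic_rows().values())


def compute_fln(
    injection: InjectionRecord, parcellation: list[str] | None = None
) -> dict[str, float]:
    """Per-source FLN of one injection.

    FLN(X<-Y) = labeled neurons in Y / total extrinsic labeled neurons,
    excluding the intrinsic (target-area) cells from numerator and
    denominator.  Values are in (0, 1] and sum to 1.

    Raises
    ------
    NoExtrinsicLabelError
        If the injection labels no extrinsic neuron.
    SchemaError
        If ``parcellation`` is given and a source code is not in it.
    """
    if parcellation is not None:
        known = set(parcellation)
        for area in injection.rows:
            if area not in known:
                raise SchemaError(f"unknown area code {area!r}")
    rows = injection.extrinsic_rows()
    total = sum(s + i for s, i in rows.values())
    if total == 0:
        raise NoExtrinsicLabelError(
            f"injection {injection.injection_id!r}: no extrinsic label"
        )
    return {area: (s + i) / total for area, (s, i) in rows.items()}


def compute_sln(
    supra_count: int,
    infra_count: int,
    source_area: str | None = None,
    agranular: frozenset[str] = AGRANULAR_AREAS,
) -> float | None:
    """SLN = supra / (supra + infra), or ``None`` where undefined.

    SLN has no meaning for agranular sources (no layer-4 boundary to split
    supra from infra); for those the undefined marker ``None`` is returned
    rather than a number.
    """
    if source_area is not None and source_area in agranular:
        return None
    total = supra_count + infra_count
    if total < 1:
        raise ValueError("SLN requires at least one labeled neuron")
    return supra_count / total


def aggregate_fln(injections: list[InjectionRecord]) -> dict[str, float]:
    """Arithmetic mean FLN row across replicate injections in one target.

    A connection absent in an injection contributes FLN = 0 for that
    injection, so the averaged row still sums to 1.
    """
    if not injections:
        raise ValueError("need at least one injection")
    target = injections[0].target_area
    if any(inj.target_area != target for inj in injections):
        raise ValueError("mixed target areas in aggregate_fln")
    per_inj = [compute_fln(inj) for inj in injections]
    sources = sorted({a for fln in per_inj for a in fln})
    k = len(per_inj)
    return {a: sum(fln.get(a, 0.0) for fln in per_inj) / k for a in sources}


def aggregate_sln(
    injections: list[InjectionRecord],
    source: str,
    agranular: frozenset[str] = AGRANULAR_AREAS,
) -> float | None:
    """Labeled-neuron-count weighted mean SLN for one connection.

    Each injection's SLN is weighted by its total labeled-neuron count in
    the source, which makes the weighted mean equal the pooled
    supra / (supra + infra) over all injections revealing the connection.
    Returns ``None`` if no injection reveals the connection or the source
    is agranular.
    """
    if source in agranular:
        return None
    supra_tot = 0
    total = 0
    for inj in injections:
        if source in inj.rows and source != inj.target_area:
            s, i = inj.rows[source]
            supra_tot += s
            total += s + i
    if total == 0:
        return None
    return supra_tot / total


@dataclass
class ConnectomeMatrices:
    """Target x source FLN and SLN matrices aggregated across injections.

    Attributes
    ----------
    fln_mean : DataFrame
        Arithmetic-mean FLN, rows = targets, columns = sources.  0 encodes
        an absent connection; the intrinsic entry is fixed at exactly 0.
    sln_wmean : DataFrame
        Pooled-count weighted-mean SLN; NaN where the connection is absent,
        intrinsic, or the source is agranular.
    presence : DataFrame
        Boolean mask, ``fln_mean > 0``.
    n_injections : Series
        Number of injections per target area.
    """

    fln_mean: pd.DataFrame
    sln_wmean: pd.DataFrame
    presence: pd.DataFrame
    n_injections: pd.Series

    @property
    def targets(self) -> list[str]:
        return list(self.fln_mean.index)

    @property
    def sources(self) -> list[str]:
        return list(self.fln_mean.columns)

    @property
    def n_possible_connections(self) -> int:
        """Number of (target, source) slots in the matrix."""
        return self.fln_mean.shape[0] * self.fln_mean.shape[1]

    @property
    def coverage_percent(self) -> float:
        """Injected targets as a percentage of the parcellation."""
        return 100.0 * len(self.targets) / len(self.sources)


def build_matrices(
    injections: list[InjectionRecord],
    sources: list[str],
    agranular: frozenset[str] = AGRANULAR_AREAS,
) -> ConnectomeMatrices:
    """Aggregate a set of injections into :class:`ConnectomeMatrices`.

    ``sources`` is the full parcellation (user-supplied, case-sensitive);
    every area code appearing in the injections must be listed in it.
    Targets are the distinct injected areas, in first-appearance order.
    """
    if not injections:
        raise ValueError("no injections")
    known = set(sources)
    targets: list[str] = []
    by_target: dict[str, list[InjectionRecord]] = {}
    for inj in injections:
        if inj.target_area not in known:
            raise SchemaError(f"target {inj.target_area!r} not in parcellation")
        for area in inj.rows:
            if area not in known:
                raise SchemaError(f"source {area!r} not in parcellation")
        if inj.target_area not in by_target:
            targets.append(inj.target_area)
        by_target.setdefault(inj.target_area, []).append(inj)

    fln = pd.DataFrame(0.0, index=targets, columns=sources)
    sln = pd.DataFrame(np.nan, index=targets, columns=sources)
    n_inj = pd.Series({t: len(by_target[t]) for t in targets}, dtype=int)
    for t in targets:
        row = aggregate_fln(by_target[t])
        for a, v in row.items():
            fln.loc[t, a] = v
        for a in row:
            s = aggregate_sln(by_target[t], a, agranular=agranular)
            if s is not None:
                sln.loc[t, a] = s
        fln.loc[t, t] = 0.0  # intrinsic entry fixed at exactly 0
        sln.loc[t, t] = np.nan
    presence = fln > 0
    return ConnectomeMatrices(fln, sln, presence, n_inj)


@dataclass
class EdgeCompleteNetwork:
    """Square subnetwork over injected targets: all inputs and outputs known."""

    fln: pd.DataFrame
    sln: pd.DataFrame
    adjacency: np.ndarray  # boolean, zero diagonal
    areas: list[str]


def build_edge_complete(matrices: ConnectomeMatrices) -> EdgeCompleteNetwork:
    """Restrict the rectangular matrices to the square over injected targets.

    The diagonal (intrinsic entries) is excluded from all downstream
    statistics: it stays 0 in FLN and False in the adjacency.
    """
    targets = matrices.targets
    missing = [t for t in targets if t not in matrices.fln_mean.columns]
    if missing:
        raise ValueError(f"targets missing from source list: {missing}")
    fln = matrices.fln_mean.loc[targets, targets].copy()
    sln = matrices.sln_wmean.loc[targets, targets].copy()
    adj = (fln.to_numpy() > 0).astype(bool)
    np.fill_diagonal(adj, False)
    return EdgeCompleteNetwork(fln, sln, adj, list(targets))


# ---------------------------------------------------------------------------
# delimited-text interfaces
# ---------------------------------------------------------------------------

INJECTION_COLUMNS = [
    "injection_id",
    "target_area",
    "source_area",
    "supra_count",
    "infra_count",
]


def read_injections(
    path,
    lengths_path=None,
    delimiter: str = ",",
) -> list[InjectionRecord]:
    """Read an injection table (and optional per-neuron lengths file).

    The table has columns ``injection_id,target_area,source_area,
    supra_count,infra_count`` plus an optional ``tracer`` column; the
    lengths file has ``injection_id,source_area,length_mm``.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    miss = [c for c in INJECTION_COLUMNS if c not in df.columns]
    if miss:
        raise SchemaError(f"injection table missing columns {miss}")
    lengths: dict[str, list[float]] = {}
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, delimiter=delimiter)
        for inj_id, grp in ldf.groupby("injection_id", sort=False):
            lengths[str(inj_id)] = grp["length_mm"].to_list()
    records = []
    for inj_id, grp in df.groupby("injection_id", sort=False):
        targets = grp["target_area"].unique()
        if len(targets) != 1:
            raise SchemaError(f"injection {inj_id!r} lists multiple targets")
        if grp["source_area"].duplicated().any():
            raise SchemaError(f"injection {inj_id!r} has duplicate source rows")
        rows = {
            str(r.source_area): (int(r.supra_count), int(r.infra_count))
            for r in grp.itertuples()
        }
        tracer = None
        if "tracer" in grp.columns:
            tr = grp["tracer"].dropna().unique()
            tracer = str(tr[0]) if len(tr) else None
        plen = lengths.get(str(inj_id))
        records.append(
            InjectionRecord(
                injection_id=str(inj_id),
                target_area=str(targets[0]),
                rows=rows,
                tracer=tracer,
                projection_lengths=None if plen is None else np.asarray(plen),
            )
        )
    return records


def write_injections(
    injections: list[InjectionRecord],
    path,
    lengths_path=None,
    delimiter: str = ",",
) -> None:
    """Write injections in the delimited format read by :func:`read_injections`."""
    recs = []
    has_tracer = any(inj.tracer is not None for inj in injections)
    for inj in injections:
        for area, (s, i) in inj.rows.items():
            row = {
                "injection_id": inj.injection_id,
                "target_area": inj.target_area,
                "source_area": area,
                "supra_count": s,
                "infra_count": i,
            }
            if has_tracer:
                row["tracer"] = inj.tracer
            recs.append(row)
    pd.DataFrame(recs).to_csv(path, sep=delimiter, index=False)
    if lengths_path is not None:
        lrecs = []
        for inj in injections:
            if inj.projection_lengths is None:
                continue
            for length in inj.projection_lengths:
                lrecs.append(
                    {
                        "injection_id": inj.injection_id,
                        "source_area": "",
                        "length_mm": float(length),
                    }
                )
        pd.DataFrame(
            lrecs, columns=["injection_id", "source_area", "length_mm"]
        ).to_csv(lengths_path, sep=delimiter, index=False)


def write_matrix(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a matrix: first row source codes, first column target codes.

    Undefined entries (NaN, e.g. SLN of agranular sources) become empty
    fields.
    """
    df.to_csv(path, sep=delimiter)


def read_matrix(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (empty fields -> NaN)."""
    return pd.read_csv(path, sep=delimiter, index_col=0)
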