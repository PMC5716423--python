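"""Domain types and file I/O for planned arcs, delivery records and error logs.

The normative on-disk formats are small CSV/TSV dialects with ``# key=value``
metadata headers.  Floats are serialized with :func:`repr` so that a
write -> read round trip is bit-identical.

Leaf/jaw positions are millimetres at the isocenter plane, angles are
degrees, meterset is MU.  The 80-element leaf vectors are ordered
``[A01..A40, B01..B40]``; the jaw vector is ``[X1, X2, Y1, Y2]``.
Bank A positions never exceed their opposing bank B positions (a closed
pair has zero gap).
"""

from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError

__all__ = [
    "MachineGeometry",
    "ControlPoint",
    "ArcPlan",
    "DeliverySnapshot",
    "DeliveryRecord",
    "ToleranceConfig",
    "ErrorLog",
    "read_plan",
    "write_plan",
    "read_record",
    "write_record",
    "write_error_log",
    "read_error_log",
]

N_LEAF_PAIRS = 40
N_LEAVES = 2 * N_LEAF_PAIRS
N_JAWS = 4
_DOSE_RATES = (500.0, 250.0, 125.0, 63.0, 37.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MachineGeometry:
    """Static description of the MLC/jaw hardware.

    Parameters
    ----------
    n_leaf_pairs
        Number of opposing leaf pairs (80 leaves total for the default 40).
    leaf_width_iso_cm
        Projected leaf width at isocenter, in cm.
    leaf_pair_y_edges_mm
        ``n_leaf_pairs + 1`` strictly increasing transverse boundary
        coordinates of the leaf pairs, in mm at isocenter.
    dose_rates
        Nominal discrete dose rates in MU/min.
    max_leaf_speed
        Maximum leaf travel per degree of gantry rotation, mm/deg.
    """

    n_leaf_pairs: int = N_LEAF_PAIRS
    leaf_width_iso_cm: float = 1.0
    leaf_pair_y_edges_mm: np.ndarray = field(
        default_factory=lambda: np.arange(-200.0, 201.0, 10.0)
    )
    dose_rates: tuple[float, ...] = _DOSE_RATES
    max_leaf_speed: float = 4.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.leaf_pair_y_edges_mm, dtype=float)
        object.__setattr__(self, "leaf_pair_y_edges_mm", edges)
        if edges.shape != (self.n_leaf_pairs + 1,):
            raise ValidationError(
                f"expected {self.n_leaf_pairs + 1} leaf pair edges, got {edges.size}"
            )
        if not np.all(np.diff(edges) > 0):
            raise ValidationError("leaf_pair_y_edges_mm must be strictly increasing")
        if any(r <= 0 for r in self.dose_rates):
            raise ValidationError("dose rates must all be positive")


@dataclass
class ControlPoint:
    """One planned machine state along an arc."""

    index: int
    cumulative_mu: float
    gantry_deg: float
    bank_a: np.ndarray  # (40,) mm
    bank_b: np.ndarray  # (40,) mm
    jaws: np.ndarray  # (4,) mm: X1, X2, Y1, Y2

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        self.jaws = np.asarray(self.jaws, dtype=float)

    def validate(self) -> None:
        if self.bank_a.shape != (N_LEAF_PAIRS,) or self.bank_b.shape != (N_LEAF_PAIRS,):
            raise ValidationError(
                f"control point {self.index}: expected {N_LEAF_PAIRS} leaves per bank"
            )
        if self.jaws.shape != (N_JAWS,):
            raise ValidationError(f"control point {self.index}: expected {N_JAWS} jaws")
        if self.cumulative_mu < 0:
            raise ValidationError(f"control point {self.index}: negative cumulative MU")
        if not 0.0 <= self.gantry_deg < 360.0:
            raise ValidationError(
                f"control point {self.index}: gantry {self.gantry_deg} not in [0, 360)"
            )
        if np.any(self.bank_a > self.bank_b + 1e-9):
            raise ValidationError(
                f"control point {self.index}: opposing leaves overlap (bank A > bank B)"
            )
        if self.jaws[0] > self.jaws[1] or self.jaws[2] > self.jaws[3]:
            raise ValidationError(f"control point {self.index}: jaw pair crossed")

    @property
    def leaves(self) -> np.ndarray:
        """All 80 leaf positions, ``[A01..A40, B01..B40]``."""
        return np.concatenate([self.bank_a, self.bank_b])


@dataclass
class ArcPlan:
    """An ordered sequence of control points defining a planned arc."""

    patient_id: str
    field_id: str
    control_points: list[ControlPoint]
    collimator_deg: float = 45.0
    rotation_sense: int = -1

    def validate(self) -> None:
        if len(self.control_points) < 2:
            raise ValidationError("an arc plan needs at least 2 control points")
        if self.rotation_sense not in (-1, 1):
            raise ValidationError("rotation_sense must be +1 or -1")
        for cp in self.control_points:
            cp.validate()
        mu = self.mu
        if np.any(np.diff(mu) < 0):
            k = int(np.argmax(np.diff(mu) < 0))
            raise ValidationError(
                f"cumulative_mu decreases between control points {k} and {k + 1}"
            )
        # unwrap raises TrajectoryError on a step inconsistent with the sense
        from .trajectory_core import unwrap_gantry

        unwrap_gantry(self.gantry, self.rotation_sense)

    # -- vectorized views -------------------------------------------------
    @property
    def mu(self) -> np.ndarray:
        return np.array([cp.cumulative_mu for cp in self.control_points])

    @property
    def gantry(self) -> np.ndarray:
        return np.array([cp.gantry_deg for cp in self.control_points])

    @property
    def leaves(self) -> np.ndarray:
        """(n_cp, 80) leaf positions."""
        return np.array([cp.leaves for cp in self.control_points])

    @property
    def jaw_array(self) -> np.ndarray:
        """(n_cp, 4) jaw positions."""
        return np.array([cp.jaws for cp in self.control_points])


@dataclass
class DeliverySnapshot:
    """Machine-reported state captured at one control point boundary."""

    boundary_index: int
    cumulative_mu: float
    gantry_deg: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    jaws: np.ndarray
    timestamp: str | None = None

    def __post_init__(self) -> None:
        self.bank_a = np.asarray(self.bank_a, dtype=float)
        self.bank_b = np.asarray(self.bank_b, dtype=float)
        self.jaws = np.asarray(self.jaws, dtype=float)

    def validate(self) -> None:
        if self.bank_a.shape != (N_LEAF_PAIRS,) or self.bank_b.shape != (N_LEAF_PAIRS,):
            raise ValidationError(
                f"snapshot {self.boundary_index}: expected {N_LEAF_PAIRS} leaves per bank"
            )
        if self.jaws.shape != (N_JAWS,):
            raise ValidationError(f"snapshot {self.boundary_index}: expected {N_JAWS} jaws")

    @property
    def leaves(self) -> np.ndarray:
        return np.concatenate([self.bank_a, self.bank_b])


@dataclass
class DeliveryRecord:
    """All reported snapshots for one delivered fraction of one field."""

    patient_id: str
    field_id: str
    fraction_date: str
    snapshots: list[DeliverySnapshot]

    def validate(self) -> None:
        if not self.snapshots:
            raise ValidationError("delivery record has no snapshots")
        for s in self.snapshots:
            s.validate()
        mu = self.mu
        if np.any(np.diff(mu) < 0):
            k = int(np.argmax(np.diff(mu) < 0))
            raise ValidationError(
                f"reported cumulative_mu decreases between snapshots {k} and {k + 1}"
            )

    @property
    def mu(self) -> np.ndarray:
        return np.array([s.cumulative_mu for s in self.snapshots])

    @property
    def gantry(self) -> np.ndarray:
        return np.array([s.gantry_deg for s in self.snapshots])

    @property
    def leaves(self) -> np.ndarray:
        return np.array([s.leaves for s in self.snapshots])

    @property
    def jaw_array(self) -> np.ndarray:
        return np.array([s.jaws for s in self.snapshots])


@dataclass(frozen=True)
class ToleranceConfig:
    """Headline tolerances and the sweep levels used for tabulation."""

    mlc_mm: float = 3.0
    gantry_deg: float = 2.0
    jaw_mm: float = 3.0
    sweep: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0)

    def __post_init__(self) -> None:
        vals = (self.mlc_mm, self.gantry_deg, self.jaw_mm, *self.sweep)
        if any(v <= 0 for v in vals):
            raise ValidationError("tolerances must all be positive")


@dataclass
class ErrorLog:
    """Signed per-parameter position errors for one delivered fraction.

    All ``*_errors`` arrays are reported minus planned.  ``leaf_excluded``
    flags leaves whose pair is fully shielded by the planned Y jaws; their
    errors are retained, never dropped.
    """

    patient_id: str
    field_id: str
    fraction_date: str
    boundary_index: np.ndarray  # (n,)
    leaf_planned: np.ndarray  # (n, 80) mm
    leaf_reported: np.ndarray  # (n, 80) mm
    leaf_errors: np.ndarray  # (n, 80) mm
    leaf_excluded: np.ndarray  # (n, 80) bool
    gantry_planned: np.ndarray  # (n,) deg
    gantry_reported: np.ndarray  # (n,) deg
    gantry_errors: np.ndarray  # (n,) deg, shortest signed difference
    jaw_planned: np.ndarray  # (n, 4) mm
    jaw_reported: np.ndarray  # (n, 4) mm
    jaw_errors: np.ndarray  # (n, 4) mm

    def validate(self) -> None:
        n = self.boundary_index.shape[0]
        shapes = {
            "leaf_planned": (n, N_LEAVES),
            "leaf_reported": (n, N_LEAVES),
            "leaf_errors": (n, N_LEAVES),
            "leaf_excluded": (n, N_LEAVES),
            "gantry_planned": (n,),
            "gantry_reported": (n,),
            "gantry_errors": (n,),
            "jaw_planned": (n, N_JAWS),
            "jaw_reported": (n, N_JAWS),
            "jaw_errors": (n, N_JAWS),
        }
        for name, shape in shapes.items():
            if getattr(self, name).shape != shape:
                raise ValidationError(f"error log field {name} has wrong shape")

    @property
    def n_snapshots(self) -> int:
        return int(self.boundary_index.shape[0])


# ---------------------------------------------------------------------------
# CSV dialect helpers
# ---------------------------------------------------------------------------

PLAN_MAGIC = "# arcverify-plan v1; units=mm,deg,MU"
RECORD_MAGIC = "# arcverify-record v1; units=mm,deg,MU"
ERRORLOG_MAGIC = "# arcverify-errorlog v1; units=mm,deg,MU"

_LEAF_COLS = [f"a{i:02d}" for i in range(1, 41)] + [f"b{i:02d}" for i in range(1, 41)]
_CP_COLS = ["index", "cumulative_mu", "gantry_deg"] + _LEAF_COLS + ["x1", "x2", "y1", "y2"]


def _fmt(x: float) -> str:
    return repr(float(x))


def _split_header(lines: list[str], path: str) -> tuple[dict[str, str], list[str]]:
    """Separate ``# key=value`` metadata from data lines."""
    meta: dict[str, str] = {}
    data: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.rstrip("\n")
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("# ").strip()
            if "=" in body and ";" not in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        data.append(stripped)
    if not data:
        raise FormatError(f"{path}: no data rows")
    return meta, data


def _parse_cp_rows(data: list[str], path: str) -> list[dict[str, float]]:
    reader = csv.reader(io.StringIO("\n".join(data)))
    header = next(reader)
    header = [h.strip() for h in header]
    if header != _CP_COLS:
        missing = [c for c in _CP_COLS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing columns {missing[:5]}")
        raise FormatError(f"{path}: column order does not match the v1 dialect")
    rows = []
    for lineno, row in enumerate(reader, start=2):
        if len(row) != len(_CP_COLS):
            raise FormatError(
                f"{path}: data row {lineno} has {len(row)} fields, expected {len(_CP_COLS)}"
            )
        try:
            rows.append({c: float(v) for c, v in zip(_CP_COLS, row)})
        except ValueError as exc:
            raise FormatError(f"{path}: data row {lineno}: {exc}") from exc
    return rows


def _row_values(index: int, mu: float, gantry: float, bank_a: np.ndarray,
                bank_b: np.ndarray, jaws: np.ndarray) -> list[str]:
    return (
        [str(index), _fmt(mu), _fmt(gantry)]
        + [_fmt(v) for v in bank_a]
        + [_fmt(v) for v in bank_b]
        + [_fmt(v) for v in jaws]
    )


# ---------------------------------------------------------------------------
# plan I/O
# ---------------------------------------------------------------------------


def read_plan(path: str | Path, geometry: MachineGeometry | None = None) -> ArcPlan:
    """Read an arc plan from its CSV dialect and validate all invariants.

    ``rotation_sense`` is inferred from the unwrapped gantry sequence when
    the metadata line is absent.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# arcverify-plan v1"):
        raise FormatError(f"{path}: missing plan dialect magic line")
    meta, data = _split_header(lines, str(path))
    rows = _parse_cp_rows(data, str(path))
    cps = [
        ControlPoint(
            index=int(r["index"]),
            cumulative_mu=r["cumulative_mu"],
            gantry_deg=r["gantry_deg"],
            bank_a=np.array([r[c] for c in _LEAF_COLS[:40]]),
            bank_b=np.array([r[c] for c in _LEAF_COLS[40:]]),
            jaws=np.array([r["x1"], r["x2"], r["y1"], r["y2"]]),
        )
        for r in rows
    ]
    sense = meta.get("rotation_sense")
    if sense is None:
        sense_val = _infer_sense([cp.gantry_deg for cp in cps])
    else:
        sense_val = int(sense)
    plan = ArcPlan(
        patient_id=meta.get("patient_id", ""),
        field_id=meta.get("field_id", ""),
        collimator_deg=float(meta.get("collimator_deg", 45.0)),
        rotation_sense=sense_val,
        control_points=cps,
    )
    plan.validate()
    return plan


def _infer_sense(angles: Sequence[float]) -> int:
    """Infer rotation sense from the first non-zero wrapped gantry step."""
    for a, b in zip(angles, angles[1:]):
        d = (b - a) % 360.0
        if d == 0.0:
            continue
        return 1 if d < 180.0 else -1
    return -1


def write_plan(plan: ArcPlan, path: str | Path) -> None:
    path = Path(path)
    out = [PLAN_MAGIC]
    out.append(f"# patient_id={plan.patient_id}")
    out.append(f"# field_id={plan.field_id}")
    out.append(f"# collimator_deg={_fmt(plan.collimator_deg)}")
    out.append(f"# rotation_sense={plan.rotation_sense}")
    out.append(",".join(_CP_COLS))
    for cp in plan.control_points:
        out.append(",".join(_row_values(cp.index, cp.cumulative_mu, cp.gantry_deg,
                                        cp.bank_a, cp.bank_b, cp.jaws)))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------


def read_record(path: str | Path, geometry: MachineGeometry | None = None) -> DeliveryRecord:
    """Read a delivery record from its CSV dialect and validate it."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# arcverify-record v1"):
        raise FormatError(f"{path}: missing record dialect magic line")
    meta, data = _split_header(lines, str(path))
    rows = _parse_cp_rows(data, str(path))
    snaps = [
        DeliverySnapshot(
            boundary_index=int(r["index"]),
            cumulative_mu=r["cumulative_mu"],
            gantry_deg=r["gantry_deg"],
            bank_a=np.array([r[c] for c in _LEAF_COLS[:40]]),
            bank_b=np.array([r[c] for c in _LEAF_COLS[40:]]),
            jaws=np.array([r["x1"], r["x2"], r["y1"], r["y2"]]),
        )
        for r in rows
    ]
    record = DeliveryRecord(
        patient_id=meta.get("patient_id", ""),
        field_id=meta.get("field_id", ""),
        fraction_date=meta.get("fraction_date", ""),
        snapshots=snaps,
    )
    record.validate()
    return record


def write_record(record: DeliveryRecord, path: str | Path) -> None:
    path = Path(path)
    out = [RECORD_MAGIC]
    out.append(f"# patient_id={record.patient_id}")
    out.append(f"# field_id={record.field_id}")
    out.append(f"# fraction_date={record.fraction_date}")
    out.append(",".join(_CP_COLS))
    for s in record.snapshots:
        out.append(",".join(_row_values(s.boundary_index, s.cumulative_mu, s.gantry_deg,
                                        s.bank_a, s.bank_b, s.jaws)))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# error log I/O (TSV, one row per snapshot x parameter)
# ---------------------------------------------------------------------------

_LOG_COLS = ["boundary_index", "param_kind", "param_id", "planned", "reported",
             "error", "excluded"]
_LEAF_IDS = [f"A{i:02d}" for i in range(1, 41)] + [f"B{i:02d}" for i in range(1, 41)]
_JAW_IDS = ["X1", "X2", "Y1", "Y2"]


def write_error_log(log: ErrorLog, path: str | Path) -> None:
    """Write a per-fraction error log as TSV.

    Each snapshot contributes 80 leaf rows, 4 jaw rows and 1 gantry row.
    Jaw-blocked leaves carry ``excluded=1`` but are serialized, not dropped.
    """
    log.validate()
    path = Path(path)
    out = [ERRORLOG_MAGIC]
    out.append(f"# patient_id={log.patient_id}")
    out.append(f"# field_id={log.field_id}")
    out.append(f"# fraction_date={log.fraction_date}")
    out.append("\t".join(_LOG_COLS))
    for k in range(log.n_snapshots):
        b = int(log.boundary_index[k])
        for j in range(N_LEAVES):
            out.append("\t".join([
                str(b), "leaf", _LEAF_IDS[j],
                _fmt(log.leaf_planned[k, j]), _fmt(log.leaf_reported[k, j]),
                _fmt(log.leaf_errors[k, j]), str(int(log.leaf_excluded[k, j])),
            ]))
        for j in range(N_JAWS):
            out.append("\t".join([
                str(b), "jaw", _JAW_IDS[j],
                _fmt(log.jaw_planned[k, j]), _fmt(log.jaw_reported[k, j]),
                _fmt(log.jaw_errors[k, j]), "0",
            ]))
        out.append("\t".join([
            str(b), "gantry", "G",
            _fmt(log.gantry_planned[k]), _fmt(log.gantry_reported[k]),
            _fmt(log.gantry_errors[k]), "0",
        ]))
    path.write_text("\n".join(out) + "\n")


def read_error_log(path: str | Path) -> ErrorLog:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# arcverify-errorlog v1"):
        raise FormatError(f"{path}: missing error-log dialect magic line")
    meta, data = _split_header(lines, str(path))
    header = data[0].split("\t")
    if header != _LOG_COLS:
        raise FormatError(f"{path}: error-log columns do not match the v1 dialect")

    by_snapshot: dict[int, dict[str, dict[str, tuple[float, float, float, int]]]] = {}
    order: list[int] = []
    for lineno, line in enumerate(data[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(_LOG_COLS):
            raise FormatError(f"{path}: row {lineno} has {len(parts)} fields")
        b = int(parts[0])
        kind, pid = parts[1], parts[2]
        try:
            planned, reported, error = (float(parts[3]), float(parts[4]), float(parts[5]))
            excluded = int(parts[6])
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: {exc}") from exc
        if b not in by_snapshot:
            by_snapshot[b] = {"leaf": {}, "jaw": {}, "gantry": {}}
            order.append(b)
        if kind not in ("leaf", "jaw", "gantry"):
            raise FormatError(f"{path}: row {lineno}: unknown param_kind {kind!r}")
        by_snapshot[b][kind][pid] = (planned, reported, error, excluded)

    n = len(order)
    leaf_p = np.empty((n, N_LEAVES))
    leaf_r = np.empty((n, N_LEAVES))
    leaf_e = np.empty((n, N_LEAVES))
    leaf_x = np.empty((n, N_LEAVES), dtype=bool)
    jaw_p = np.empty((n, N_JAWS))
    jaw_r = np.empty((n, N_JAWS))
    jaw_e = np.empty((n, N_JAWS))
    g_p = np.empty(n)
    g_r = np.empty(n)
    g_e = np.empty(n)
    for k, b in enumerate(order):
        snap = by_snapshot[b]
        if set(snap["leaf"]) != set(_LEAF_IDS):
            raise FormatError(f"{path}: snapshot {b} does not carry all 80 leaves")
        if set(snap["jaw"]) != set(_JAW_IDS) or set(snap["gantry"]) != {"G"}:
            raise FormatError(f"{path}: snapshot {b} missing jaw or gantry rows")
        for j, pid in enumerate(_LEAF_IDS):
            leaf_p[k, j], leaf_r[k, j], leaf_e[k, j], x = snap["leaf"][pid]
            leaf_x[k, j] = bool(x)
        for j, pid in enumerate(_JAW_IDS):
            jaw_p[k, j], jaw_r[k, j], jaw_e[k, j], _ = snap["jaw"][pid]
        g_p[k], g_r[k], g_e[k], _ = snap["gantry"]["G"]

    log = ErrorLog(
        patient_id=meta.get("patient_id", ""),
        field_id=meta.get("field_id", ""),
        fraction_date=meta.get("fraction_date", ""),
        boundary_index=np.array(order, dtype=int),
        leaf_planned=leaf_p, leaf_reported=leaf_r, leaf_errors=leaf_e,
        leaf_excluded=leaf_x,
        gantry_planned=g_p, gantry_reported=g_r, gantry_errors=g_e,
        jaw_planned=jaw_p, jaw_reported=jaw_r, jaw_errors=jaw_e,
    )
    log.validate()
    return log


def logs_equal(a: ErrorLog, b: ErrorLog) -> bool:
    """Exact (bitwise) equality of two error logs."""
    for f in dataclasses.fields(ErrorLog):
        va, vb = getattr(a, f.name), getattr(b, f.name)
        if isinstance(va, np.ndarray):
            if va.shape != vb.shape or not np.array_equal(va, vb):
                return False
        elif va != vb:
            return False
    return True
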