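"""Planned-trajectory reconstruction and per-snapshot error computation.

The planned machine state at an arbitrary cumulative-MU value is obtained by
linear interpolation between the bracketing control point pair, with the
gantry handled on an unwrapped (cumulative) angle axis so arcs crossing the
0/360 boundary interpolate correctly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import PairingError, RangeError, TrajectoryError
from .records_io import (
    ArcPlan,
    DeliveryRecord,
    ErrorLog,
    MachineGeometry,
)

__all__ = [
    "PlannedState",
    "unwrap_gantry",
    "interpolate_plan",
    "leaf_blocked",
    "blocked_pairs",
    "angular_error",
    "compute_errors",
    "sample_plan_as_record",
]


@dataclass
class PlannedState:
    """Interpolated planned machine state at one cumulative-MU value."""

    cumulative_mu: float
    gantry_deg: float
    gantry_unwrapped_deg: float
    bank_a: np.ndarray
    bank_b: np.ndarray
    jaws: np.ndarray
    segment_index: int
    clamped: bool = False

    @property
    def leaves(self) -> np.ndarray:
        return np.concatenate([self.bank_a, self.bank_b])


def unwrap_gantry(angles: np.ndarray, rotation_sense: int) -> np.ndarray:
    """Unwrap raw gantry angles in [0, 360) onto a cumulative signed axis.

    The first output equals the first input; every subsequent step is the
    wrapped difference resolved along ``rotation_sense``.  Steps of less than
    180 degrees against the sense are tolerated (jitter); a step of exactly
    180 degrees is ambiguous and raises :class:`TrajectoryError`.
    """
    angles = np.asarray(angles, dtype=float)
    if rotation_sense not in (-1, 1):
        raise TrajectoryError("rotation_sense must be +1 or -1")
    if angles.size == 0:
        return angles.copy()
    deltas_along = (rotation_sense * np.diff(angles)) % 360.0
    if np.any(deltas_along == 180.0):
        k = int(np.argmax(deltas_along == 180.0))
        raise TrajectoryError(
            f"ambiguous 180 degree gantry step between samples {k} and {k + 1}"
        )
    steps = np.where(deltas_along < 180.0, deltas_along, deltas_along - 360.0)
    out = np.empty_like(angles)
    out[0] = angles[0]
    out[1:] = angles[0] + rotation_sense * np.cumsum(steps)
    # snap to the exact input angle plus an integer number of turns so the
    # unwrapped axis stays congruent to the raw angles despite cumsum rounding
    out = angles + 360.0 * np.round((out - angles) / 360.0)
    return out


def angular_error(reported_deg: float, planned_deg: float) -> float:
    """Signed shortest angular difference reported - planned, in (-180, 180].

    The antipodal tie is resolved to +180.
    """
    d = (float(reported_deg) - float(planned_deg)) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


def _bracket(mu_axis: np.ndarray, mu: float) -> tuple[int, float]:
    """Return (segment index k, interpolation weight t) for a bracketed mu.

    Zero-length segments resolve to the earlier control point (t = 0); a mu
    equal to a control point's value reproduces that control point exactly.
    """
    n = mu_axis.size
    k = int(np.searchsorted(mu_axis, mu, side="right")) - 1
    k = min(max(k, 0), n - 2)
    span = mu_axis[k + 1] - mu_axis[k]
    if span == 0.0:
        return k, 0.0
    t = (mu - mu_axis[k]) / span
    return k, float(min(max(t, 0.0), 1.0))


def interpolate_plan(plan: ArcPlan, mu: float, clamp: bool = False) -> PlannedState:
    """Reconstruct the planned state at ``mu`` by control-point interpolation.

    With bracketing control points k and k+1 and
    ``t = (mu - mu_k) / (mu_{k+1} - mu_k)``, every leaf, jaw and the
    unwrapped gantry equal ``(1 - t) * value_k + t * value_{k+1}``.

    Parameters
    ----------
    plan
        A validated arc plan.
    mu
        Cumulative monitor units, inside the plan's MU range unless
        ``clamp`` is set.
    clamp
        Map out-of-range ``mu`` to the nearest endpoint and flag the
        returned state as clamped instead of raising.
    """
    mu_axis = plan.mu
    clamped = False
    if mu < mu_axis[0] or mu > mu_axis[-1]:
        if not clamp:
            raise RangeError(
                f"mu={mu} outside plan range [{mu_axis[0]}, {mu_axis[-1]}]"
            )
        mu = float(min(max(mu, mu_axis[0]), mu_axis[-1]))
        clamped = True
    k, t = _bracket(mu_axis, mu)
    unwrapped = unwrap_gantry(plan.gantry, plan.rotation_sense)
    cp0, cp1 = plan.control_points[k], plan.control_points[k + 1]
    w0, w1 = 1.0 - t, t
    bank_a = w0 * cp0.bank_a + w1 * cp1.bank_a
    bank_b = w0 * cp0.bank_b + w1 * cp1.bank_b
    jaws = w0 * cp0.jaws + w1 * cp1.jaws
    g_unwrapped = w0 * unwrapped[k] + w1 * unwrapped[k + 1]
    # at an exact control point, return its stored raw angle bit-for-bit
    if t == 0.0:
        g_deg = cp0.gantry_deg
    elif t == 1.0:
        g_deg = cp1.gantry_deg
    else:
        g_deg = g_unwrapped % 360.0
    return PlannedState(
        cumulative_mu=mu,
        gantry_deg=g_deg,
        gantry_unwrapped_deg=float(g_unwrapped),
        bank_a=bank_a,
        bank_b=bank_b,
        jaws=jaws,
        segment_index=k,
        clamped=clamped,
    )


def leaf_blocked(pair_index: int, jaws: np.ndarray, geometry: MachineGeometry) -> bool:
    """Whether leaf pair ``pair_index`` (0-based) is fully shielded by the Y jaws.

    A pair is blocked iff its transverse extent ``[edge_i, edge_{i+1}]`` has
    zero-length intersection with the open Y-jaw interval ``(Y1, Y2)``; a
    touching boundary counts as blocked.
    """
    edges = geometry.leaf_pair_y_edges_mm
    lo, hi = edges[pair_index], edges[pair_index + 1]
    y1, y2 = float(jaws[2]), float(jaws[3])
    return bool(min(hi, y2) - max(lo, y1) <= 0.0)


def blocked_pairs(jaws: np.ndarray, geometry: MachineGeometry) -> np.ndarray:
    """Vectorized :func:`leaf_blocked` over all pairs; returns (n_pairs,) bools."""
    edges = geometry.leaf_pair_y_edges_mm
    lo, hi = edges[:-1], edges[1:]
    y1, y2 = float(jaws[2]), float(jaws[3])
    return np.minimum(hi, y2) - np.maximum(lo, y1) <= 0.0


def compute_errors(
    plan: ArcPlan,
    record: DeliveryRecord,
    geometry: MachineGeometry | None = None,
) -> ErrorLog:
    """Compare every reported snapshot against the MU-interpolated plan.

    For each snapshot the planned state is reconstructed at the snapshot's
    reported cumulative MU; leaf and jaw errors are reported minus planned
    in mm, the gantry error is the signed shortest angular difference in
    degrees.  Leaves whose pair is shielded by the planned (interpolated)
    jaws are flagged excluded; their errors are retained.

    Raises
    ------
    PairingError
        If plan and record carry different patient or field identifiers.
    """
    if geometry is None:
        geometry = MachineGeometry()
    if (plan.patient_id, plan.field_id) != (record.patient_id, record.field_id):
        raise PairingError(
            f"plan {plan.patient_id}/{plan.field_id} does not match "
            f"record {record.patient_id}/{record.field_id}"
        )
    n = len(record.snapshots)
    n_pairs = geometry.n_leaf_pairs
    n_leaves = 2 * n_pairs
    leaf_planned = np.empty((n, n_leaves))
    leaf_excluded = np.empty((n, n_leaves), dtype=bool)
    gantry_planned = np.empty(n)
    jaw_planned = np.empty((n, 4))
    mu_axis = plan.mu
    n_clamped = 0
    for k, snap in enumerate(record.snapshots):
        if snap.cumulative_mu < mu_axis[0] or snap.cumulative_mu > mu_axis[-1]:
            n_clamped += 1
        state = interpolate_plan(plan, snap.cumulative_mu, clamp=True)
        leaf_planned[k] = state.leaves
        gantry_planned[k] = state.gantry_deg
        jaw_planned[k] = state.jaws
        pair_blocked = blocked_pairs(state.jaws, geometry)
        leaf_excluded[k] = np.concatenate([pair_blocked, pair_blocked])
    if n_clamped:
        warnings.warn(
            f"{n_clamped} snapshot(s) reported cumulative MU outside the plan "
            "range; clamped to the nearest endpoint",
            stacklevel=2,
        )
    leaf_reported = record.leaves
    jaw_reported = record.jaw_array
    gantry_reported = record.gantry
    gantry_errors = np.array(
        [angular_error(r, p) for r, p in zip(gantry_reported, gantry_planned)]
    )
    log = ErrorLog(
        patient_id=record.patient_id,
        field_id=record.field_id,
        fraction_date=record.fraction_date,
        boundary_index=np.array([s.boundary_index for s in record.snapshots], dtype=int),
        leaf_planned=leaf_planned,
        leaf_reported=leaf_reported,
        leaf_errors=leaf_reported - leaf_planned,
        leaf_excluded=leaf_excluded,
        gantry_planned=gantry_planned,
        gantry_reported=gantry_reported,
        gantry_errors=gantry_errors,
        jaw_planned=jaw_planned,
        jaw_reported=jaw_reported,
        jaw_errors=jaw_reported - jaw_planned,
    )
    log.validate()
    return log


def sample_plan_as_record(plan: ArcPlan, fraction_date: str = "1970-01-01") -> DeliveryRecord:
    """Build the ideal delivery record: one snapshot per control point, no error."""
    from .records_io import DeliverySnapshot

    snaps = [
        DeliverySnapshot(
            boundary_index=cp.index,
            cumulative_mu=cp.cumulative_mu,
            gantry_deg=cp.gantry_deg,
            bank_a=cp.bank_a.copy(),
            bank_b=cp.bank_b.copy(),
            jaws=cp.jaws.copy(),
        )
        for cp in plan.control_points
    ]
    return DeliveryRecord(
        patient_id=plan.patient_id,
        field_id=plan.field_id,
        fraction_date=fraction_date,
        snapshots=snaps,
    )
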