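"""Synthetic VMAT arc plans and simulated deliveries.

The generator produces single (or dual) arcs with the clinic-style
geometry: gantry starting at 175 deg rotating counter-clockwise to 185 deg
at ~4 deg control-point spacing, 40 leaf pairs of 1 cm width, and
per-segment leaf motion bounded by 4 mm per gantry degree.  Leaf sequences
are smoothly varying random apertures (a seeded random walk on each pair's
center and width) whose step sizes are scaled by a ``complexity`` knob and
clipped so the speed bound holds by construction.

The delivery simulator adds a speed-proportional lag (each leaf reported
behind its planned position by ``lag_coeff`` times its planned mm/deg speed
in the preceding segment), a constant bias, Gaussian noise on every
parameter, and optional MU-sampling jitter.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, ValidationError
from .records_io import (
    ArcPlan,
    ControlPoint,
    DeliveryRecord,
    DeliverySnapshot,
    MachineGeometry,
)
from .trajectory_core import interpolate_plan, unwrap_gantry

__all__ = [
    "PlanGeneratorConfig",
    "ErrorModel",
    "CohortFraction",
    "generate_plan",
    "generate_arcs",
    "simulate_delivery",
    "generate_cohort",
]


@dataclass(frozen=True)
class PlanGeneratorConfig:
    """Knobs for the synthetic arc generator.

    ``complexity`` in [0, 1] scales the requested leaf motion: 0 yields a
    static aperture, 1 yields motion regularly saturating the speed bound.
    """

    n_arcs: int = 1
    arc_start_deg: float = 175.0
    arc_stop_deg: float = 185.0
    rotation_sense: int = -1
    gantry_spacing_deg: float = 4.0
    total_mu: float = 400.0
    max_leaf_speed: float = 4.0
    complexity: float = 0.5
    n_active_pairs: int = 15
    center_pair: int = 20
    aperture_center_sd_mm: float = 10.0
    aperture_width_min_mm: float = 40.0
    aperture_width_max_mm: float = 80.0
    max_delivery_time_s: float = 90.0  # metadata only
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_mu <= 0:
            raise ConfigurationError("total_mu must be positive")
        if self.n_arcs not in (1, 2):
            raise ConfigurationError("n_arcs must be 1 or 2")
        if self.rotation_sense not in (-1, 1):
            raise ConfigurationError("rotation_sense must be +1 or -1")
        if self.gantry_spacing_deg <= 0:
            raise ConfigurationError("gantry_spacing_deg must be positive")
        if self.complexity < 0:
            raise ConfigurationError("complexity must be non-negative")


@dataclass(frozen=True)
class ErrorModel:
    """Parameters of the simulated delivery-error process.

    ``lag_coeff`` is mm of leaf lag per (mm/deg) of planned leaf speed — the
    angle-domain analogue of a control-system sampling latency.
    """

    lag_coeff: float = 0.0
    leaf_noise_sd: float = 0.0
    gantry_noise_sd: float = 0.0
    jaw_noise_sd: float = 0.0
    mu_jitter_sd: float = 0.0
    leaf_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sds = (self.leaf_noise_sd, self.gantry_noise_sd, self.jaw_noise_sd,
               self.mu_jitter_sd)
        if any(s < 0 for s in sds):
            raise ValidationError("noise standard deviations must be >= 0")


def _arc_span_deg(config: PlanGeneratorConfig) -> float:
    """Unwrapped gantry travel from start to stop along the rotation sense."""
    return (config.rotation_sense * (config.arc_stop_deg - config.arc_start_deg)) % 360.0


def generate_plan(
    config: PlanGeneratorConfig,
    geometry: MachineGeometry | None = None,
    patient_id: str = "SYN001",
    field_id: str = "A1",
) -> ArcPlan:
    """Generate one validated synthetic arc plan (the first arc of ``config``).

    Control points sit at the configured spacing along the arc (the spacing
    is stretched slightly so it divides the span into a whole number of
    segments); cumulative MU is apportioned uniformly per segment.
    Deterministic for a fixed seed.
    """
    if geometry is None:
        geometry = MachineGeometry()
    rng = np.random.default_rng(config.seed)
    span = _arc_span_deg(config)
    n_seg = max(1, int(round(span / config.gantry_spacing_deg)))
    n_cp = n_seg + 1
    d_theta = span / n_seg
    unwrapped = config.arc_start_deg + config.rotation_sense * d_theta * np.arange(n_cp)
    gantry = unwrapped % 360.0
    mu = np.linspace(0.0, config.total_mu, n_cp)

    n_pairs = geometry.n_leaf_pairs
    first = max(0, config.center_pair - config.n_active_pairs // 2)
    last = min(n_pairs, first + config.n_active_pairs)  # exclusive
    active = np.zeros(n_pairs, dtype=bool)
    active[first:last] = True

    # per-pair aperture walks; step limits chosen so |d(bank)| <= speed bound
    limit = config.max_leaf_speed * d_theta
    c_scale = min(config.complexity, 1.0) * 0.6 * limit
    w_scale = min(config.complexity, 1.0) * 0.8 * limit
    centers = np.zeros((n_cp, n_pairs))
    widths = np.zeros((n_cp, n_pairs))
    centers[0, active] = rng.normal(0.0, config.aperture_center_sd_mm, active.sum())
    widths[0, active] = rng.uniform(
        config.aperture_width_min_mm, config.aperture_width_max_mm, active.sum()
    )
    for k in range(1, n_cp):
        dc = np.clip(rng.uniform(-c_scale, c_scale, n_pairs), -0.6 * limit, 0.6 * limit)
        dw = np.clip(rng.uniform(-w_scale, w_scale, n_pairs), -0.8 * limit, 0.8 * limit)
        centers[k] = centers[k - 1] + np.where(active, dc, 0.0)
        widths[k] = np.where(active, np.maximum(widths[k - 1] + dw, 2.0), 0.0)
    bank_a = centers - widths / 2.0
    bank_b = centers + widths / 2.0

    edges = geometry.leaf_pair_y_edges_mm
    y1 = edges[first] if active.any() else -10.0
    y2 = edges[last] if active.any() else 10.0
    x1 = float(bank_a.min()) - 5.0
    x2 = float(bank_b.max()) + 5.0
    jaws = np.array([x1, x2, y1, y2])

    cps = [
        ControlPoint(
            index=k,
            cumulative_mu=float(mu[k]),
            gantry_deg=float(gantry[k]),
            bank_a=bank_a[k].copy(),
            bank_b=bank_b[k].copy(),
            jaws=jaws.copy(),
        )
        for k in range(n_cp)
    ]
    plan = ArcPlan(
        patient_id=patient_id,
        field_id=field_id,
        control_points=cps,
        rotation_sense=config.rotation_sense,
    )
    plan.validate()
    return plan


def generate_arcs(
    config: PlanGeneratorConfig,
    geometry: MachineGeometry | None = None,
    patient_id: str = "SYN001",
) -> list[ArcPlan]:
    """Generate ``config.n_arcs`` plans; the second arc returns clockwise."""
    arcs = [generate_plan(config, geometry, patient_id, field_id="A1")]
    if config.n_arcs == 2:
        back = replace(
            config,
            arc_start_deg=config.arc_stop_deg,
            arc_stop_deg=config.arc_start_deg,
            rotation_sense=-config.rotation_sense,
            seed=config.seed + 1,
        )
        arcs.append(generate_plan(back, geometry, patient_id, field_id="A2"))
    return arcs


def _planned_leaf_speeds(plan: ArcPlan) -> np.ndarray:
    """Signed planned leaf speed (mm/deg) in the segment preceding each CP.

    Row 0 (no preceding segment) is zero; zero-gantry-travel segments
    contribute zero speed.
    """
    unwrapped = unwrap_gantry(plan.gantry, plan.rotation_sense)
    d_gantry = np.abs(np.diff(unwrapped))
    d_leaf = np.diff(plan.leaves, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        seg_speed = np.where(d_gantry[:, None] > 0, d_leaf / d_gantry[:, None], 0.0)
    speeds = np.zeros_like(plan.leaves)
    speeds[1:] = seg_speed
    return speeds


def simulate_delivery(
    plan: ArcPlan,
    model: ErrorModel,
    fraction_date: str = "1970-01-01",
) -> DeliveryRecord:
    """Simulate the machine-reported record for one delivered fraction.

    One snapshot per control point boundary.  The reported cumulative MU is
    the planned MU plus Gaussian jitter (clipped to the plan range and made
    non-decreasing); each reported leaf is the planned leaf at the jittered
    MU, minus ``lag_coeff`` times its signed planned speed in the preceding
    segment, plus bias and noise.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(model.seed)
    mu = plan.mu
    n = mu.size
    n_leaves = plan.leaves.shape[1]

    mu_rep = mu + rng.normal(0.0, model.mu_jitter_sd, n) if model.mu_jitter_sd else mu.copy()
    mu_rep = np.clip(mu_rep, mu[0], mu[-1])
    mu_rep = np.maximum.accumulate(mu_rep)

    leaf_noise = rng.normal(0.0, model.leaf_noise_sd, (n, n_leaves))
    gantry_noise = rng.normal(0.0, model.gantry_noise_sd, n)
    jaw_noise = rng.normal(0.0, model.jaw_noise_sd, (n, 4))
    speeds = _planned_leaf_speeds(plan)

    snaps: list[DeliverySnapshot] = []
    for k in range(n):
        state = interpolate_plan(plan, float(mu_rep[k]), clamp=True)
        leaves = (
            state.leaves
            - model.lag_coeff * speeds[k]
            + model.leaf_bias
            + leaf_noise[k]
        )
        gantry = (state.gantry_deg + gantry_noise[k]) % 360.0
        snaps.append(
            DeliverySnapshot(
                boundary_index=k,
                cumulative_mu=float(mu_rep[k]),
                gantry_deg=float(gantry),
                bank_a=leaves[: n_leaves // 2],
                bank_b=leaves[n_leaves // 2 :],
                jaws=state.jaws + jaw_noise[k],
            )
        )
    record = DeliveryRecord(
        patient_id=plan.patient_id,
        field_id=plan.field_id,
        fraction_date=fraction_date,
        snapshots=snaps,
    )
    record.validate()
    return record


@dataclass
class CohortFraction:
    """One simulated (plan, record) pair, keyed by patient and date."""

    patient_id: str
    fraction_date: str
    complexity: float
    plan: ArcPlan
    record: DeliveryRecord

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.fraction_date)


def generate_cohort(
    n_patients: int,
    site_mix: dict[float, float],
    fractions_per_patient: int,
    model: ErrorModel,
    seed: int = 0,
    base_config: PlanGeneratorConfig | None = None,
    geometry: MachineGeometry | None = None,
) -> list[CohortFraction]:
    """Generate a reproducible multi-patient, multi-fraction cohort.

    ``site_mix`` maps a complexity level to the proportion of patients at
    that level (proportions must sum to 1); patient counts are apportioned
    by largest remainder.  Each patient gets one plan and
    ``fractions_per_patient`` simulated records on consecutive dates.
    """
    if n_patients < 1 or fractions_per_patient < 1:
        raise ConfigurationError("need at least one patient and one fraction")
    total = sum(site_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"site_mix proportions sum to {total}, expected 1")
    if base_config is None:
        base_config = PlanGeneratorConfig()

    levels = sorted(site_mix)
    exact = {c: site_mix[c] * n_patients for c in levels}
    counts = {c: int(np.floor(exact[c])) for c in levels}
    for c in sorted(levels, key=lambda c: exact[c] - counts[c], reverse=True):
        if sum(counts.values()) >= n_patients:
            break
        counts[c] += 1

    ss = np.random.SeedSequence(seed)
    base_date = datetime.date(2026, 1, 5)
    out: list[CohortFraction] = []
    p = 0
    for complexity in levels:
        for _ in range(counts[complexity]):
            p += 1
            pid = f"P{p:03d}"
            plan_seed, *frac_seeds = [
                int(s.generate_state(1)[0]) for s in ss.spawn(1 + fractions_per_patient)
            ]
            config = replace(base_config, complexity=complexity, seed=plan_seed)
            plan = generate_plan(config, geometry, patient_id=pid)
            for f in range(fractions_per_patient):
                date = (base_date + datetime.timedelta(days=f)).isoformat()
                frac_model = replace(model, seed=frac_seeds[f])
                record = simulate_delivery(plan, frac_model, fraction_date=date)
                out.append(
                    CohortFraction(
                        patient_id=pid,
                        fraction_date=date,
                        complexity=complexity,
                        plan=plan,
                        record=record,
                    )
                )
    return out
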