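"""Summary statistics over error logs and planned leaf motion.

Conventions (fixed here, used consistently everywhere):

* percent-within comparisons are inclusive, ``|error| <= tolerance``;
* the fractional-movement threshold is strict, speed ``> 1`` mm/deg;
* per-leaf RMS uses only non-excluded samples, with NaN marking a leaf
  excluded at every snapshot;
* histogram bins are symmetric about zero with zero at a bin center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateSegmentError,
    PairingError,
    UndefinedCorrelationError,
    UndefinedMetricError,
)
from .records_io import ArcPlan, ErrorLog, ToleranceConfig
from .trajectory_core import unwrap_gantry

__all__ = [
    "FractionSummary",
    "PlanMotionSummary",
    "Histogram",
    "percent_within",
    "summarize_fraction",
    "plan_motion_summary",
    "aggregate_history",
    "pearson_r",
    "speed_error_relation",
    "METRIC_KEYS",
]

#: metric name -> (parameter kind, tolerance) for the three headline metrics
METRIC_KEYS = {
    "P3mm_mlc": ("mlc", 3.0),
    "P2deg_gantry": ("gantry", 2.0),
    "P3mm_jaw": ("jaw", 3.0),
}


@dataclass
class Histogram:
    """Binned error counts; ``edges`` has one more entry than ``counts``."""

    edges: np.ndarray
    counts: np.ndarray

    def to_dict(self) -> dict:
        return {"edges": self.edges.tolist(), "counts": self.counts.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Histogram":
        return cls(edges=np.asarray(d["edges"], dtype=float),
                   counts=np.asarray(d["counts"], dtype=int))


def _zero_centered_hist(values: np.ndarray, bin_width: float) -> Histogram:
    """Histogram with zero at a bin center and all values covered."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        edges = np.array([-bin_width / 2, bin_width / 2])
        return Histogram(edges=edges, counts=np.zeros(1, dtype=int))
    reach = float(np.max(np.abs(values)))
    # bin centers at 0, ±w, ±2w, ...; outermost edge must strictly cover reach
    k = int(np.floor(reach / bin_width + 0.5)) + 1
    edges = (np.arange(-k, k + 1) + 0.5) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return Histogram(edges=edges, counts=counts.astype(int))


def percent_within(
    errors: np.ndarray,
    tolerance: float,
    excluded: np.ndarray | None = None,
) -> float:
    """Percentage of included samples with ``|error| <= tolerance``.

    Raises :class:`UndefinedMetricError` when no sample is included.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    if excluded is None:
        included = errors
    else:
        excluded = np.asarray(excluded, dtype=bool).ravel()
        included = errors[~excluded]
    if included.size == 0:
        raise UndefinedMetricError("percent_within has zero included samples")
    return 100.0 * float(np.count_nonzero(np.abs(included) <= tolerance)) / included.size


@dataclass
class FractionSummary:
    """Per-fraction aggregate: tolerance table, per-leaf RMS, histograms."""

    patient_id: str
    field_id: str
    fraction_date: str
    p_within: dict[tuple[str, float], float]
    rms_per_leaf: np.ndarray  # (80,) mm, NaN if a leaf is always excluded
    histograms: dict[str, Histogram]  # keys: leaf, gantry, jaw
    n_included_leaf: int
    n_excluded_leaf: int
    n_gantry: int
    n_jaw: int

    def metric(self, name: str) -> float:
        """Look up a named metric such as ``P3mm_mlc``."""
        if name not in METRIC_KEYS:
            raise KeyError(name)
        return self.p_within[METRIC_KEYS[name]]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "field_id": self.field_id,
            "fraction_date": self.fraction_date,
            "p_within": [
                {"kind": kind, "tolerance": tol, "percent": pct}
                for (kind, tol), pct in sorted(self.p_within.items())
            ],
            "rms_per_leaf": [None if np.isnan(v) else v for v in self.rms_per_leaf],
            "histograms": {k: h.to_dict() for k, h in self.histograms.items()},
            "n_included_leaf": self.n_included_leaf,
            "n_excluded_leaf": self.n_excluded_leaf,
            "n_gantry": self.n_gantry,
            "n_jaw": self.n_jaw,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FractionSummary":
        return cls(
            patient_id=d["patient_id"],
            field_id=d["field_id"],
            fraction_date=d["fraction_date"],
            p_within={
                (e["kind"], float(e["tolerance"])): float(e["percent"])
                for e in d["p_within"]
            },
            rms_per_leaf=np.array(
                [np.nan if v is None else float(v) for v in d["rms_per_leaf"]]
            ),
            histograms={k: Histogram.from_dict(h) for k, h in d["histograms"].items()},
            n_included_leaf=int(d["n_included_leaf"]),
            n_excluded_leaf=int(d["n_excluded_leaf"]),
            n_gantry=int(d["n_gantry"]),
            n_jaw=int(d["n_jaw"]),
        )


def summarize_fraction(
    log: ErrorLog,
    config: ToleranceConfig | None = None,
    bin_width_mm: float = 0.5,
    bin_width_deg: float = 0.5,
) -> FractionSummary:
    """Aggregate one error log into its fraction summary.

    The percent-within table covers the sweep levels for all three parameter
    kinds plus the headline tolerances; per-leaf RMS is taken over included
    samples only.
    """
    if config is None:
        config = ToleranceConfig()
    log.validate()
    excl = log.leaf_excluded
    leaf_included = log.leaf_errors[~excl]
    gantry = log.gantry_errors
    jaws = log.jaw_errors.ravel()

    levels = {
        "mlc": sorted({*config.sweep, config.mlc_mm}),
        "gantry": sorted({*config.sweep, config.gantry_deg}),
        "jaw": sorted({*config.sweep, config.jaw_mm}),
    }
    p_within: dict[tuple[str, float], float] = {}
    for tol in levels["mlc"]:
        p_within[("mlc", float(tol))] = percent_within(log.leaf_errors, tol, excl)
    for tol in levels["gantry"]:
        p_within[("gantry", float(tol))] = percent_within(gantry, tol)
    for tol in levels["jaw"]:
        p_within[("jaw", float(tol))] = percent_within(jaws, tol)

    n_leaves = log.leaf_errors.shape[1]
    rms = np.full(n_leaves, np.nan)
    for j in range(n_leaves):
        sel = ~excl[:, j]
        if np.any(sel):
            rms[j] = float(np.sqrt(np.mean(log.leaf_errors[sel, j] ** 2)))

    return FractionSummary(
        patient_id=log.patient_id,
        field_id=log.field_id,
        fraction_date=log.fraction_date,
        p_within=p_within,
        rms_per_leaf=rms,
        histograms={
            "leaf": _zero_centered_hist(leaf_included, bin_width_mm),
            "gantry": _zero_centered_hist(gantry, bin_width_deg),
            "jaw": _zero_centered_hist(jaws, bin_width_mm),
        },
        n_included_leaf=int(leaf_included.size),
        n_excluded_leaf=int(np.count_nonzero(excl)),
        n_gantry=int(gantry.size),
        n_jaw=int(jaws.size),
    )


@dataclass
class PlanMotionSummary:
    """Planned leaf-speed statistics for one plan (all 80 leaves)."""

    patient_id: str
    field_id: str
    leaf_speeds: np.ndarray  # (n_segments, 80) mm/deg, non-negative
    frac_gt_1mm_per_deg: float  # % of movements with speed strictly > 1
    speed_histogram: Histogram = field(default=None)  # type: ignore[assignment]

    @property
    def mean_speed(self) -> float:
        return float(np.mean(self.leaf_speeds))


def plan_motion_summary(plan: ArcPlan, bin_width: float = 0.25) -> PlanMotionSummary:
    """Per-segment per-leaf planned speeds in mm of travel per gantry degree.

    Raises :class:`DegenerateSegmentError` if any segment has zero gantry
    travel (speed undefined there).
    """
    unwrapped = unwrap_gantry(plan.gantry, plan.rotation_sense)
    d_gantry = np.abs(np.diff(unwrapped))
    if np.any(d_gantry == 0.0):
        k = int(np.argmax(d_gantry == 0.0))
        raise DegenerateSegmentError(
            f"segment {k} (control points {k}-{k + 1}) has zero gantry travel"
        )
    d_leaf = np.abs(np.diff(plan.leaves, axis=0))
    speeds = d_leaf / d_gantry[:, None]
    frac = 100.0 * float(np.count_nonzero(speeds > 1.0)) / speeds.size
    edges = np.arange(0.0, max(float(speeds.max()), bin_width) + bin_width, bin_width)
    counts, _ = np.histogram(speeds, bins=edges)
    return PlanMotionSummary(
        patient_id=plan.patient_id,
        field_id=plan.field_id,
        leaf_speeds=speeds,
        frac_gt_1mm_per_deg=frac,
        speed_histogram=Histogram(edges=edges, counts=counts.astype(int)),
    )


def _sd(values: np.ndarray) -> float:
    """Sample standard deviation (ddof=1); zero for a single value."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def aggregate_history(summaries: list[FractionSummary]) -> dict:
    """Aggregate per-fraction summaries into a multi-fraction trend table.

    Returns, per headline metric: the date-ordered series, overall mean and
    SD, per-patient mean/SD/2SD across that patient's fractions, and the
    average over patients of the per-patient SDs.
    """
    if not summaries:
        raise UndefinedMetricError("aggregate_history needs at least one summary")
    ordered = sorted(summaries, key=lambda s: (s.fraction_date, s.patient_id, s.field_id))
    out: dict = {"n_fractions": len(ordered), "metrics": {}}
    for name in METRIC_KEYS:
        values = np.array([s.metric(name) for s in ordered])
        per_patient: dict[str, dict] = {}
        for pid in sorted({s.patient_id for s in ordered}):
            pvals = np.array([s.metric(name) for s in ordered if s.patient_id == pid])
            sd = _sd(pvals)
            per_patient[pid] = {
                "n": int(pvals.size),
                "mean": float(np.mean(pvals)),
                "sd": sd,
                "sd2": 2.0 * sd,
            }
        out["metrics"][name] = {
            "series": [
                {"patient_id": s.patient_id, "field_id": s.field_id,
                 "fraction_date": s.fraction_date, "value": s.metric(name)}
                for s in ordered
            ],
            "mean": float(np.mean(values)),
            "sd": _sd(values),
            "per_patient": per_patient,
            "mean_per_patient_sd": float(
                np.mean([p["sd"] for p in per_patient.values()])
            ),
        }
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient.

    Raises :class:`UndefinedCorrelationError` for unequal lengths, fewer
    than 3 points, or a constant series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise UndefinedCorrelationError("series must be 1-D and of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)


def speed_error_relation(
    plan_summaries: dict[tuple, PlanMotionSummary],
    fraction_summaries: dict[tuple, FractionSummary],
    metric: str = "P3mm_mlc",
) -> list[tuple[float, float]]:
    """Pair per-fraction planned-motion and delivered-accuracy statistics.

    Returns ``(frac_gt_1mm_per_deg, metric)`` pairs in the key order of
    ``plan_summaries``; raises :class:`PairingError` on key mismatch.
    """
    if set(plan_summaries) != set(fraction_summaries):
        missing = set(plan_summaries) ^ set(fraction_summaries)
        raise PairingError(f"unmatched fraction keys: {sorted(missing)[:5]}")
    return [
        (plan_summaries[k].frac_gt_1mm_per_deg, fraction_summaries[k].metric(metric))
        for k in plan_summaries
    ]
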