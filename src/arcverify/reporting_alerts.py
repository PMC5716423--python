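"""Report rendering, declarative alert rules and pluggable notification sinks.

Reports are versioned JSON documents (``schema: arcverify-report/1``);
figures are an optional matplotlib rendering step.  Alerting is declarative:
rules compare a named summary metric against a threshold, either per
fraction or over a trailing window of a patient's fractions, and fire
:class:`AlertEvent` objects that are handed to a sink.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .metrics import METRIC_KEYS, FractionSummary
from .records_io import ErrorLog

__all__ = [
    "AlertRule",
    "AlertEvent",
    "evaluate_alerts",
    "render_fraction_report",
    "render_history_report",
    "notify",
    "NotificationSink",
    "FileSink",
    "ListSink",
]

REPORT_SCHEMA = "arcverify-report/1"


@dataclass(frozen=True)
class AlertRule:
    """Threshold rule over a summary metric.

    ``scope`` is ``"fraction"`` (each fraction checked individually) or
    ``"window"`` (trailing mean over ``window`` consecutive fractions of the
    same patient, ordered by date).
    """

    metric: str
    comparator: str  # "below" | "above"
    threshold: float
    scope: str = "fraction"
    window: int = 1

    def __post_init__(self) -> None:
        if self.comparator not in ("below", "above"):
            raise ConfigurationError(f"unknown comparator {self.comparator!r}")
        if self.scope not in ("fraction", "window"):
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.scope == "window" and self.window < 1:
            raise ConfigurationError("window must be >= 1")
        if not np.isfinite(self.threshold):
            raise ConfigurationError("threshold must be finite")

    def violated_by(self, value: float) -> bool:
        return value < self.threshold if self.comparator == "below" else value > self.threshold


@dataclass
class AlertEvent:
    """One rule violation on one fraction (or window ending at that fraction)."""

    rule: AlertRule
    patient_id: str
    fraction_date: str
    observed: float
    message: str


def _rule_key(rule: AlertRule) -> tuple:
    return (rule.metric, rule.comparator, rule.threshold, rule.scope, rule.window)


def evaluate_alerts(
    summaries: list[FractionSummary], rules: list[AlertRule]
) -> list[AlertEvent]:
    """Evaluate every rule against every fraction (or trailing window).

    Events are ordered by fraction date, then patient, then rule.  A rule
    naming a metric outside the known set raises
    :class:`ConfigurationError`.
    """
    for rule in rules:
        if rule.metric not in METRIC_KEYS:
            raise ConfigurationError(
                f"alert rule references unknown metric {rule.metric!r}; "
                f"known: {sorted(METRIC_KEYS)}"
            )
    events: list[AlertEvent] = []
    ordered = sorted(summaries, key=lambda s: (s.fraction_date, s.patient_id, s.field_id))
    for rule in rules:
        if rule.scope == "fraction":
            for s in ordered:
                value = s.metric(rule.metric)
                if rule.violated_by(value):
                    events.append(_make_event(rule, s.patient_id, s.fraction_date, value))
        else:
            for pid in sorted({s.patient_id for s in ordered}):
                series = [s for s in ordered if s.patient_id == pid]
                for end in range(rule.window - 1, len(series)):
                    win = series[end - rule.window + 1 : end + 1]
                    mean = float(np.mean([s.metric(rule.metric) for s in win]))
                    if rule.violated_by(mean):
                        events.append(
                            _make_event(rule, pid, series[end].fraction_date, mean)
                        )
    events.sort(key=lambda e: (e.fraction_date, e.patient_id, _rule_key(e.rule)))
    return events


def _make_event(rule: AlertRule, patient_id: str, date: str, observed: float) -> AlertEvent:
    scope_txt = (
        "fraction" if rule.scope == "fraction" else f"trailing {rule.window}-fraction mean"
    )
    msg = (
        f"[arcverify] {rule.metric} {scope_txt} = {observed:.2f} is "
        f"{rule.comparator} threshold {rule.threshold:g} "
        f"(patient {patient_id}, fraction {date})"
    )
    return AlertEvent(rule=rule, patient_id=patient_id, fraction_date=date,
                      observed=observed, message=msg)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_fraction_report(summary: FractionSummary, log: ErrorLog | None = None) -> dict:
    """Render one fraction's summary as a versioned JSON-ready document.

    All numeric content round-trips losslessly: ``FractionSummary.from_dict``
    on the ``summary`` section reproduces the input field-for-field.
    """
    doc = {
        "schema": REPORT_SCHEMA,
        "kind": "fraction",
        "patient_id": summary.patient_id,
        "field_id": summary.field_id,
        "fraction_date": summary.fraction_date,
        "headline": {name: summary.metric(name) for name in METRIC_KEYS},
        "tolerance_sweep": _sweep_table(summary),
        "summary": summary.to_dict(),
    }
    if log is not None:
        doc["n_snapshots"] = log.n_snapshots
    return doc


def _sweep_table(summary: FractionSummary) -> dict:
    """Tolerance-sweep rows per parameter kind, columns in increasing level."""
    table: dict[str, dict[str, float]] = {}
    for (kind, tol), pct in sorted(summary.p_within.items()):
        table.setdefault(kind, {})[f"{tol:g}"] = pct
    return table


def render_history_report(trend: dict, annotations: list[dict] | None = None) -> dict:
    """Render an aggregate trend table as a versioned JSON-ready document.

    ``annotations`` are optional dated events (e.g. machine calibration
    adjustments) carried through for chart annotation.
    """
    if not trend.get("metrics"):
        raise ConfigurationError("history report needs a non-empty trend table")
    return {
        "schema": REPORT_SCHEMA,
        "kind": "history",
        "n_fractions": trend["n_fractions"],
        "metrics": trend["metrics"],
        "annotations": annotations or [],
    }


def save_report(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def render_fraction_figures(summary: FractionSummary, path: str | Path) -> None:
    """Four-panel per-fraction figure: three error histograms + per-leaf RMS."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    panels = [("leaf", "MLC leaf error (mm)"), ("gantry", "Gantry error (deg)"),
              ("jaw", "Jaw error (mm)")]
    for ax, (key, label) in zip(axes.ravel(), panels):
        h = summary.histograms[key]
        ax.stairs(h.counts, h.edges, fill=True)
        ax.set_xlabel(label)
        ax.set_ylabel("count")
    ax = axes.ravel()[3]
    rms = summary.rms_per_leaf
    ax.bar(np.arange(1, rms.size + 1), np.nan_to_num(rms, nan=0.0), width=1.0)
    ax.set_xlabel("leaf number")
    ax.set_ylabel("RMS error (mm)")
    fig.suptitle(
        f"{summary.patient_id} / {summary.field_id} — {summary.fraction_date}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_history_figures(trend: dict, path: str | Path) -> None:
    """Three-panel historical chart, one panel per headline metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = trend["metrics"]
    fig, axes = plt.subplots(len(metrics), 1, figsize=(9, 3 * len(metrics)),
                             sharex=True, squeeze=False)
    for ax, (name, data) in zip(axes.ravel(), metrics.items()):
        values = [p["value"] for p in data["series"]]
        ax.plot(range(len(values)), values, "o", ms=3)
        ax.axhline(data["mean"], ls="--", lw=1)
        ax.set_ylabel(f"{name} (%)")
        ax.set_title(f"mean {data['mean']:.1f} ± {data['sd']:.1f}")
    axes.ravel()[-1].set_xlabel("fraction (date order)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# notification sinks
# ---------------------------------------------------------------------------


class NotificationSink:
    """Interface for notification transports; ``send`` raises on failure."""

    def send(self, message: dict) -> None:  # pragma: no cover - interface
        raise NotImplementedError


class FileSink(NotificationSink):
    """Writes one JSON message file per event into a directory."""

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self._n = 0

    def send(self, message: dict) -> None:
        self._n += 1
        path = self.directory / f"alert-{self._n:04d}.json"
        path.write_text(json.dumps(message, indent=1, sort_keys=True) + "\n")


class ListSink(NotificationSink):
    """In-memory sink for tests."""

    def __init__(self, fail: bool = False):
        self.messages: list[dict] = []
        self.fail = fail

    def send(self, message: dict) -> None:
        if self.fail:
            raise IOError("sink unavailable")
        self.messages.append(message)


def notify(events: list[AlertEvent], sink: NotificationSink) -> dict:
    """Serialize each event to one message and hand it to the sink.

    Returns ``{"delivered": [...], "undelivered": [...]}``; a sink failure
    moves the event (and all information needed to resend it) to the
    undelivered queue — no event is ever lost.
    """
    delivered: list[dict] = []
    undelivered: list[dict] = []
    for event in events:
        message = {
            "metric": event.rule.metric,
            "comparator": event.rule.comparator,
            "threshold": event.rule.threshold,
            "scope": event.rule.scope,
            "window": event.rule.window,
            "patient_id": event.patient_id,
            "fraction_date": event.fraction_date,
            "observed": event.observed,
            "message": event.message,
        }
        try:
            sink.send(message)
        except Exception as exc:  # noqa: BLE001 - any transport failure retained
            undelivered.append({"message": message, "error": str(exc)})
        else:
            delivered.append(message)
    return {"delivered": delivered, "undelivered": undelivered}
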