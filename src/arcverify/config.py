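"""YAML/JSON run configuration: tolerances, histogram bins, alert rules, sink."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .records_io import ToleranceConfig
from .reporting_alerts import AlertRule

__all__ = ["VerifyConfig", "load_config"]


@dataclass
class VerifyConfig:
    tolerances: ToleranceConfig = field(default_factory=ToleranceConfig)
    leaf_bin_mm: float = 0.5
    gantry_bin_deg: float = 0.5
    rules: list[AlertRule] = field(default_factory=list)
    sink_dir: str | None = None


def load_config(path: str | Path) -> VerifyConfig:
    """Load a config file (YAML, which subsumes JSON)."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return VerifyConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    tol_raw = raw.get("tolerances", {})
    try:
        tolerances = ToleranceConfig(
            mlc_mm=float(tol_raw.get("mlc_mm", 3.0)),
            gantry_deg=float(tol_raw.get("gantry_deg", 2.0)),
            jaw_mm=float(tol_raw.get("jaw_mm", 3.0)),
            sweep=tuple(float(v) for v in tol_raw.get("sweep", (1, 2, 3, 5))),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"{path}: bad tolerances section: {exc}") from exc
    hist = raw.get("histogram", {})
    rules = []
    for r in raw.get("alerts", []):
        try:
            rules.append(
                AlertRule(
                    metric=r["metric"],
                    comparator=r["comparator"],
                    threshold=float(r["threshold"]),
                    scope=r.get("scope", "fraction"),
                    window=int(r.get("window", 1)),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: alert rule missing key {exc}") from exc
    sink = raw.get("sink", {})
    return VerifyConfig(
        tolerances=tolerances,
        leaf_bin_mm=float(hist.get("leaf_bin_mm", 0.5)),
        gantry_bin_deg=float(hist.get("gantry_bin_deg", 0.5)),
        rules=rules,
        sink_dir=sink.get("path"),
    )
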