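# arcverify

Automated daily delivery verification for VMAT (volumetric-modulated arc
therapy). `arcverify` compares the machine-reported delivery snapshots of a
fraction against the planned arc — reconstructing the planned state at each
snapshot's cumulative monitor units by linear interpolation between control
points — and reports MLC leaf, gantry and jaw position-error statistics,
historical trends, and threshold alerts. A synthetic plan generator and
delivery simulator stand in for a clinical record-and-verify database, so
every stage is testable without patient data.

## What it computes

- **Planned-state interpolation**: leaves, jaws and (unwrapped) gantry at
  any cumulative-MU value, correct across the 0/360° gantry boundary.
- **Error logs**: signed reported−planned errors per snapshot for all
  80 leaves, 4 jaws and the gantry; leaves fully shielded by the planned
  Y jaws are flagged excluded but retained.
- **Fraction summaries**: percent-within-tolerance (inclusive, with the
  1/2/3/5 sweep and headline 3 mm MLC / 2° gantry / 3 mm jaw metrics),
  per-leaf RMS over included samples, zero-centered error histograms.
- **Plan motion**: per-segment leaf speeds in mm per gantry degree and the
  percentage of movements exceeding 1 mm/deg (a plan-complexity proxy).
- **Trends**: per-patient multi-fraction mean/SD/2SD, overall mean ± SD,
  Pearson correlation between error series.
- **Alerts**: declarative rules (per-fraction or trailing-window mean) over
  summary metrics, delivered through a pluggable notification sink.
- **Simulator**: arcs starting at 175° rotating counter-clockwise to 185°
  at ~4° control-point spacing, leaf motion bounded at 4 mm/deg, and a
  delivery-error model with speed-proportional lag, bias and Gaussian noise.

## CLI

```sh
# write a synthetic cohort of plan/record CSV files
arcverify simulate --out sim/ --patients 2 --fractions 3 --seed 1

# verify one fraction: error log + JSON report (+ optional figures);
# exits non-zero iff an alert fired (scheduler-friendly)
arcverify verify --plan sim/plan_P001.csv --record sim/record_P001_2026-01-05.csv \
    --config config.yaml --out out/

# aggregate a directory of error logs into a historical trend report
arcverify trend --logs out/ --out trend/ --figures

# re-render the report for a stored error log
arcverify report --log out/errors_P001_A1_2026-01-05.tsv --out rep/
```

Example `config.yaml`:

```yaml
tolerances: {mlc_mm: 3, gantry_deg: 2, jaw_mm: 3, sweep: [1, 2, 3, 5]}
histogram: {leaf_bin_mm: 0.5, gantry_bin_deg: 0.5}
alerts:
  - {metric: P3mm_mlc, comparator: below, threshold: 85}
  - {metric: P3mm_mlc, comparator: below, threshold: 90, scope: window, window: 5}
```

## File formats

- **Plan / record (CSV)**: `# arcverify-plan v1` / `# arcverify-record v1`
  magic line, `# key=value` metadata, then one row per control point or
  snapshot: `index, cumulative_mu, gantry_deg, a01..a40, b01..b40,
  x1, x2, y1, y2` (mm at isocenter, degrees, MU). Floats are serialized
  with full precision so write→read round trips are bit-identical.
- **Error log (TSV)**: one row per (snapshot, parameter):
  `boundary_index, param_kind{leaf|jaw|gantry}, param_id, planned,
  reported, error, excluded{0|1}`.
- **Reports**: JSON with `schema: arcverify-report/1`.

## Package layout

| module | contents |
| --- | --- |
| `arcverify.records_io` | domain types, CSV/TSV dialects, validation |
| `arcverify.trajectory_core` | gantry unwrapping, MU interpolation, error computation, jaw-blocked leaf exclusion |
| `arcverify.metrics` | percent-within, per-leaf RMS, histograms, leaf speeds, trends, correlation |
| `arcverify.reporting_alerts` | JSON reports, figures, alert rules, notification sinks |
| `arcverify.synthetic_delivery` | plan generator, delivery-error simulator, cohorts |
| `arcverify.dicom_io` | optional DICOM RT Plan ingestion |
| `arcverify.cli` | `arcverify` command group |
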