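import numpy as np
import pytest

from arcverify import (
    DegenerateSegmentError,
    ErrorModel,
    PairingError,
    PlanGeneratorConfig,
    ToleranceConfig,
    UndefinedCorrelationError,
    UndefinedMetricError,
    compute_errors,
    generate_plan,
    pearson_r,
    percent_within,
    plan_motion_summary,
    sample_plan_as_record,
    simulate_delivery,
    speed_error_relation,
    summarize_fraction,
)
from arcverify.metrics import aggregate_history

from .conftest import make_cp, make_plan


class TestPercentWithin:
    def test_inclusive_boundary(self):
        assert percent_within(np.array([0.5, 2.9, 3.0, 3.1, -4.0]), 3.0) == 60.0

    def test_all_zero(self):
        assert percent_within(np.zeros(10), 0.1) == 100.0

    def test_all_excluded_raises(self):
        with pytest.raises(UndefinedMetricError):
            percent_within(np.array([5.0, -5.0]), 3.0, excluded=np.array([True, True]))

    def test_exclusion_mask_applied(self):
        errors = np.array([0.0, 10.0, 10.0, 0.0])
        excluded = np.array([False, True, True, False])
        assert percent_within(errors, 3.0, excluded) == 100.0

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(2)
        errors = rng.normal(0, 2, 500)
        values = [percent_within(errors, t) for t in (1, 2, 3, 5)]
        assert values == sorted(values)


class TestSummarizeFraction:
    def test_identity_log(self):
        plan = make_plan([make_cp(0, 0.0, 175.0), make_cp(1, 100.0, 171.0)])
        log = compute_errors(plan, sample_plan_as_record(plan))
        s = summarize_fraction(log)
        assert all(v == 100.0 for v in s.p_within.values())
        np.testing.assert_array_equal(s.rms_per_leaf, np.zeros(80))
        assert s.n_excluded_leaf == 0

    def test_constant_error(self):
        plan = make_plan([make_cp(0, 0.0, 175.0), make_cp(1, 100.0, 171.0)])
        rec = sample_plan_as_record(plan)
        for snap in rec.snapshots:
            snap.bank_a = snap.bank_a + 2.0
            snap.bank_b = snap.bank_b + 2.0
        s = summarize_fraction(compute_errors(plan, rec))
        np.testing.assert_allclose(s.rms_per_leaf, 2.0)
        assert s.p_within[("mlc", 1.0)] == 0.0
        assert s.p_within[("mlc", 3.0)] == 100.0

    def test_gaussian_coverage(self):
        # P3mm -> 100*(2*Phi(2)-1) for sigma = 1.5 mm pure noise
        plan = generate_plan(PlanGeneratorConfig(seed=8))
        logs = [
            compute_errors(plan, simulate_delivery(plan, ErrorModel(leaf_noise_sd=1.5, seed=s)))
            for s in range(4)
        ]
        n = sum(int((~l.leaf_excluded).sum()) for l in logs)
        assert n >= 10_000
        hits = sum(
            int(np.count_nonzero(np.abs(l.leaf_errors[~l.leaf_excluded]) <= 3.0))
            for l in logs
        )
        p3 = 100.0 * hits / n
        expected = 95.44997361036416
        se = 100.0 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert abs(p3 - expected) <= 3 * se
        # and summarize_fraction agrees with the brute-force count per log
        s0 = summarize_fraction(logs[0])
        excl = logs[0].leaf_excluded
        brute = 100.0 * np.count_nonzero(
            np.abs(logs[0].leaf_errors[~excl]) <= 3.0) / (~excl).sum()
        assert s0.p_within[("mlc", 3.0)] == pytest.approx(brute, abs=1e-12)

    def test_histogram_conservation(self):
        plan = generate_plan(PlanGeneratorConfig(seed=9))
        rec = simulate_delivery(plan, ErrorModel(leaf_noise_sd=1.0, gantry_noise_sd=0.4,
                                                 jaw_noise_sd=0.4, seed=10))
        log = compute_errors(plan, rec)
        s = summarize_fraction(log)
        assert s.histograms["leaf"].counts.sum() == s.n_included_leaf
        assert s.histograms["gantry"].counts.sum() == s.n_gantry
        assert s.histograms["jaw"].counts.sum() == s.n_jaw

    def test_rms_lower_bound(self):
        plan = generate_plan(PlanGeneratorConfig(seed=12))
        rec = simulate_delivery(plan, ErrorModel(leaf_noise_sd=0.8, leaf_bias=0.5, seed=13))
        log = compute_errors(plan, rec)
        s = summarize_fraction(log)
        for j in range(80):
            sel = ~log.leaf_excluded[:, j]
            if sel.any():
                assert s.rms_per_leaf[j] >= abs(log.leaf_errors[sel, j].mean()) - 1e-12

    def test_fully_excluded_leaf_has_nan_rms(self):
        jaws = np.array([-100.0, 100.0, -20.0, 20.0])
        plan = make_plan([make_cp(0, 0.0, 175.0, jaws=jaws),
                          make_cp(1, 100.0, 171.0, jaws=jaws)])
        log = compute_errors(plan, sample_plan_as_record(plan))
        s = summarize_fraction(log)
        assert np.isnan(s.rms_per_leaf[0])  # pair 0 shielded throughout
        assert s.rms_per_leaf[18] == 0.0

    def test_sweep_includes_headline_levels(self):
        plan = make_plan([make_cp(0, 0.0, 175.0), make_cp(1, 100.0, 171.0)])
        log = compute_errors(plan, sample_plan_as_record(plan))
        s = summarize_fraction(log, ToleranceConfig())
        for kind, tol in [("mlc", 3.0), ("gantry", 2.0), ("jaw", 3.0)]:
            assert (kind, tol) in s.p_within
        for kind in ("mlc", "gantry", "jaw"):
            for tol in (1.0, 2.0, 3.0, 5.0):
                assert (kind, tol) in s.p_within


class TestPlanMotionSummary:
    def test_single_moving_leaf(self):
        a0 = np.full(40, -10.0)
        a1 = a0.copy()
        a1[5] = -18.0  # 8 mm over a 4 degree segment
        plan = make_plan([make_cp(0, 0.0, 175.0, bank_a=a0),
                          make_cp(1, 100.0, 171.0, bank_a=a1)])
        pm = plan_motion_summary(plan)
        assert pm.leaf_speeds[0, 5] == pytest.approx(2.0)
        assert pm.frac_gt_1mm_per_deg == pytest.approx(100.0 / 80.0)

    def test_static_plan(self):
        plan = make_plan([make_cp(0, 0.0, 175.0), make_cp(1, 100.0, 171.0)])
        pm = plan_motion_summary(plan)
        assert np.all(pm.leaf_speeds == 0.0)
        assert pm.frac_gt_1mm_per_deg == 0.0

    def test_strict_threshold(self):
        a0 = np.full(40, 0.0)
        a1 = np.full(40, -4.0)  # exactly 1 mm/deg over 4 degrees
        plan = make_plan([make_cp(0, 0.0, 175.0, bank_a=a0),
                          make_cp(1, 100.0, 171.0, bank_a=a1)])
        pm = plan_motion_summary(plan)
        assert pm.frac_gt_1mm_per_deg == 0.0  # strictly greater than 1 required

    def test_generator_respects_speed_bound(self):
        for seed in range(5):
            plan = generate_plan(PlanGeneratorConfig(seed=seed, complexity=1.0))
            pm = plan_motion_summary(plan)
            assert pm.leaf_speeds.max() <= 4.0 + 1e-9

    def test_degenerate_segment_raises(self):
        plan = make_plan([make_cp(0, 0.0, 175.0), make_cp(1, 50.0, 175.0),
                          make_cp(2, 100.0, 171.0)])
        with pytest.raises(DegenerateSegmentError, match="segment 0"):
            plan_motion_summary(plan)

    def test_speed_histogram_conserves(self):
        plan = generate_plan(PlanGeneratorConfig(seed=4, complexity=0.7))
        pm = plan_motion_summary(plan)
        assert pm.speed_histogram.counts.sum() == pm.leaf_speeds.size


def _summary(patient, date, p3):
    """Minimal FractionSummary carrying the three headline metrics."""
    from arcverify.metrics import FractionSummary, Histogram

    h = Histogram(edges=np.array([-0.25, 0.25]), counts=np.array([1]))
    return FractionSummary(
        patient_id=patient, field_id="A1", fraction_date=date,
        p_within={("mlc", 3.0): p3, ("gantry", 2.0): 99.0, ("jaw", 3.0): 99.9},
        rms_per_leaf=np.zeros(80),
        histograms={"leaf": h, "gantry": h, "jaw": h},
        n_included_leaf=1, n_excluded_leaf=0, n_gantry=1, n_jaw=1,
    )


class TestAggregateHistory:
    def test_single_fraction(self):
        out = aggregate_history([_summary("P1", "2026-01-01", 92.0)])
        m = out["metrics"]["P3mm_mlc"]
        assert m["mean"] == 92.0
        assert m["sd"] == 0.0

    def test_two_patient_sds(self):
        summaries = [
            _summary("P1", "2026-01-01", 90.0), _summary("P1", "2026-01-02", 94.0),
            _summary("P2", "2026-01-01", 80.0), _summary("P2", "2026-01-02", 88.0),
        ]
        m = aggregate_history(summaries)["metrics"]["P3mm_mlc"]
        assert m["per_patient"]["P1"]["sd"] == pytest.approx(2.8284271247461903)
        assert m["per_patient"]["P2"]["sd"] == pytest.approx(5.656854249492381)
        assert m["mean_per_patient_sd"] == pytest.approx(4.242640687119286)
        assert m["per_patient"]["P1"]["sd2"] == pytest.approx(2 * 2.8284271247461903)

    def test_order_invariance(self):
        summaries = [
            _summary("P1", "2026-01-03", 91.0), _summary("P2", "2026-01-01", 85.0),
            _summary("P1", "2026-01-02", 93.0),
        ]
        a = aggregate_history(summaries)
        b = aggregate_history(list(reversed(summaries)))
        assert a == b

    def test_empty_raises(self):
        with pytest.raises(UndefinedMetricError):
            aggregate_history([])


class TestPearsonR:
    def test_perfect_positive(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_perfect_negative(self):
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_direct_formula_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_series_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_too_short_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 2], [3, 4])


class TestSpeedErrorRelation:
    def _pm(self, frac):
        from arcverify.metrics import PlanMotionSummary

        return PlanMotionSummary(patient_id="P", field_id="A1",
                                 leaf_speeds=np.zeros((1, 80)),
                                 frac_gt_1mm_per_deg=frac)

    def test_pairs_in_key_order(self):
        pms = {(f"P{i}", "d"): self._pm(float(i)) for i in range(3)}
        fss = {(f"P{i}", "d"): _summary(f"P{i}", "d", 90.0 - i) for i in range(3)}
        pairs = speed_error_relation(pms, fss)
        assert pairs == [(0.0, 90.0), (1.0, 89.0), (2.0, 88.0)]

    def test_missing_key_raises(self):
        pms = {("P1", "d"): self._pm(0.0), ("P2", "d"): self._pm(1.0)}
        fss = {("P1", "d"): _summary("P1", "d", 90.0)}
        with pytest.raises(PairingError):
            speed_error_relation(pms, fss)
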