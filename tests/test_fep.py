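"""Tests for free-energy estimators, convergence diagnostics, and the DBC."""

import numpy as np
import pytest

from lipidflux.constants import rt_kcal
from lipidflux.errors import DataError, ParameterError
from lipidflux.fep import (
    DbcReference,
    DeltaGEstimate,
    FepSeries,
    FepWindow,
    accumulate,
    aggregate_replicas,
    bar_estimate,
    dbc,
    dbc_wall,
    exp_estimate,
    half_split,
    hysteresis,
    make_lambda_schedule,
    statistical_inefficiency,
)
from lipidflux.synth import FepScenario, gen_fep_dataset
from lipidflux.synth.geometry import random_rotation


def _window(fwd, bwd, la=0.0, lb=1.0, temperature=303.15):
    return FepWindow(la, lb, np.asarray(fwd, float), np.asarray(bwd, float),
                     temperature=temperature)


class TestExpEstimate:
    def test_constant_work_identity(self):
        w = _window([3.0] * 10, [-3.0] * 10)
        assert exp_estimate(w, "forward").value == pytest.approx(3.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        # forward work ~ N(dG + sigma^2/2RT, sigma^2) -> EXP estimate -> dG
        rng = np.random.default_rng(8)
        rt = rt_kcal(303.15)
        sigma = 0.5
        work = rng.normal(2.0 + sigma**2 / (2 * rt), sigma, 200_000)
        est = exp_estimate(_window(work, [0.0]), "forward")
        assert est.value == pytest.approx(2.0, abs=0.02)

    def test_backward_is_negated_forward_on_mirrored_samples(self):
        rng = np.random.default_rng(3)
        samples = rng.normal(1.0, 0.8, 500)
        fwd = exp_estimate(_window(samples, samples), "forward")
        bwd = exp_estimate(_window(samples, samples), "backward")
        assert bwd.value == pytest.approx(-fwd.value, abs=1e-12)

    def test_empty_direction_rejected(self):
        with pytest.raises(DataError):
            exp_estimate(_window([], [1.0]), "forward")

    def test_no_overflow_for_large_work(self):
        est = exp_estimate(_window([-5000.0, -5001.0], [0.0]), "forward")
        assert np.isfinite(est.value)


class TestBarEstimate:
    def test_single_sample_midpoint(self):
        est = bar_estimate(_window([3.0], [1.0]))
        assert est.value == pytest.approx(1.0, abs=1e-7)

    def test_symmetric_samples_give_zero(self):
        rng = np.random.default_rng(5)
        samples = rng.normal(0.5, 1.0, 400)
        est = bar_estimate(_window(samples, samples))
        assert est.value == pytest.approx(0.0, abs=1e-7)

    def test_crooks_gaussian_ground_truth(self):
        sc = FepScenario(true_dg_per_window=[2.0], work_sd=1.0,
                         samples_per_window=5000, seed=17)
        series = gen_fep_dataset(sc)
        est = bar_estimate(series.windows[0])
        assert abs(est.value - 2.0) <= 3 * est.stat_error

    def test_bar_between_exp_estimates(self):
        # pinned by the two one-sided estimators up to their statistical error
        # (strict sample-wise bracketing is not a theorem)
        for seed in range(5):
            sc = FepScenario(true_dg_per_window=[1.0], work_sd=0.4,
                             samples_per_window=2000, seed=seed)
            w = gen_fep_dataset(sc).windows[0]
            bar = bar_estimate(w).value
            f = exp_estimate(w, "forward")
            b = exp_estimate(w, "backward")
            slack = 2 * max(f.stat_error, b.stat_error)
            assert min(f.value, b.value) - slack <= bar <= max(f.value, b.value) + slack

    def test_reversed_window_negates_bar(self):
        sc = FepScenario(true_dg_per_window=[1.3], work_sd=1.0,
                         samples_per_window=800, seed=2)
        w = gen_fep_dataset(sc).windows[0]
        assert bar_estimate(w.reversed()).value == pytest.approx(
            -bar_estimate(w).value, abs=1e-7
        )

    def test_poor_overlap_flagged_not_fatal(self):
        est = bar_estimate(_window([100.0, 101.0], [-100.0, -101.0]))
        assert est.overlap_warning
        assert est.stat_error >= rt_kcal(303.15)
        assert np.isfinite(est.value)

    def test_exp_and_bar_agree_in_high_overlap_limit(self):
        # sigma much smaller than RT: all estimators coincide
        sc = FepScenario(true_dg_per_window=[0.7], work_sd=0.05,
                         samples_per_window=3000, seed=6)
        w = gen_fep_dataset(sc).windows[0]
        bar = bar_estimate(w)
        f = exp_estimate(w, "forward")
        assert abs(bar.value - f.value) <= 3 * max(f.stat_error, 1e-4)


class TestAccumulate:
    def test_two_window_telescoping(self):
        sc = FepScenario(true_dg_per_window=[1.0, -1.0], work_sd=0.3,
                         samples_per_window=3000, seed=9)
        total, lambdas, profile = accumulate(gen_fep_dataset(sc))
        assert total.value == pytest.approx(0.0, abs=3 * max(total.stat_error, 0.01))
        assert profile[0] == 0.0
        np.testing.assert_allclose(lambdas, [0.0, 0.5, 1.0])

    def test_profile_matches_cumulative_truth(self):
        truth = np.linspace(-1, 1, 10)
        sc = FepScenario(true_dg_per_window=list(truth), work_sd=0.8,
                         samples_per_window=2000, seed=13)
        total, lambdas, profile = accumulate(gen_fep_dataset(sc))
        expected = np.concatenate([[0.0], np.cumsum(truth)])
        np.testing.assert_allclose(profile, expected, atol=3 * total.stat_error + 0.05)

    def test_single_window_equals_its_bar(self):
        sc = FepScenario(true_dg_per_window=[0.4], work_sd=0.5,
                         samples_per_window=1000, seed=1)
        series = gen_fep_dataset(sc)
        total, _, _ = accumulate(series, decorrelate=False)
        assert total.value == pytest.approx(
            bar_estimate(series.windows[0]).value, abs=1e-12
        )

    def test_gap_in_coverage_rejected(self):
        windows = [_window([1.0] * 4, [-1.0] * 4, 0.0, 0.4),
                   _window([1.0] * 4, [-1.0] * 4, 0.6, 1.0)]
        with pytest.raises(DataError, match="gap"):
            accumulate(FepSeries(windows=windows))


class TestHysteresis:
    def test_noiseless_deltas_vanish(self):
        sc = FepScenario(true_dg_per_window=[0.5] * 6, work_sd=1e-9,
                         samples_per_window=50, seed=0)
        report = hysteresis(gen_fep_dataset(sc))
        np.testing.assert_allclose(report.per_window_delta, 0.0, atol=1e-6)

    def test_deltas_shrink_with_sample_size(self):
        small = gen_fep_dataset(FepScenario(true_dg_per_window=[0.5] * 8,
                                            work_sd=1.0, samples_per_window=100, seed=3))
        large = gen_fep_dataset(FepScenario(true_dg_per_window=[0.5] * 8,
                                            work_sd=1.0, samples_per_window=10_000, seed=3))
        assert hysteresis(large).delta_max_abs < hysteresis(small).delta_max_abs

    def test_constructed_bias_detected(self):
        sc = FepScenario(true_dg_per_window=[0.5] * 10, work_sd=0.3,
                         samples_per_window=2000, seed=7)
        series = gen_fep_dataset(sc)
        for w in series.windows:
            w.backward_work = w.backward_work + 1.0
        report = hysteresis(series)
        # a +1 kcal/mol shift of backward work biases every delta by 1 kcal/mol
        np.testing.assert_allclose(np.abs(report.per_window_delta), 1.0, atol=0.1)
        assert len(set(np.sign(report.per_window_delta))) == 1
        assert report.runs_random is False

    def test_missing_direction_lists_windows(self):
        sc = FepScenario(true_dg_per_window=[0.5] * 3, samples_per_window=10)
        series = gen_fep_dataset(sc)
        series.windows[1].backward_work = np.array([])
        with pytest.raises(DataError, match=r"\[1\]"):
            hysteresis(series)


class TestHalfSplit:
    def test_stationary_series_passes(self):
        passes = 0
        for seed in range(20):
            sc = FepScenario(true_dg_per_window=[0.5] * 5, work_sd=1.0,
                             samples_per_window=400, seed=seed)
            if half_split(gen_fep_dataset(sc)).passes_1kcal:
                passes += 1
        assert passes >= 18

    def test_constructed_drift_fails(self):
        sc = FepScenario(true_dg_per_window=[0.5] * 5, work_sd=0.3,
                         samples_per_window=1000, seed=4)
        series = gen_fep_dataset(sc)
        w = series.windows[2]
        half = len(w.forward_work) // 2
        w.forward_work = np.concatenate([w.forward_work[:half],
                                         w.forward_work[half:] + 4.0])
        report = half_split(series)
        assert report.half_split[2] >= 1.0
        assert report.passes_1kcal is False

    def test_duplicated_halves_give_zero_diff(self):
        rng = np.random.default_rng(0)
        fwd = rng.normal(1.0, 0.5, 100)
        bwd = rng.normal(-1.0, 0.5, 100)
        w = _window(np.tile(fwd, 2), np.tile(bwd, 2))
        report = half_split(FepSeries(windows=[w]))
        assert report.half_split[2] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_samples_rejected(self):
        w = _window([1.0], [-1.0])
        with pytest.raises(DataError, match="2 samples"):
            half_split(FepSeries(windows=[w]))


class TestStatisticalInefficiency:
    def test_iid_white_noise(self):
        rng = np.random.default_rng(12)
        g, idx = statistical_inefficiency(rng.normal(size=10_000))
        assert g == pytest.approx(1.0, abs=0.1)
        assert idx[0] == 0

    def test_ar1_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(99)
        n = 100_000
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        g, _ = statistical_inefficiency(x)
        expected = (1 + phi) / (1 - phi)
        assert g == pytest.approx(expected, rel=0.25)

    def test_alternating_series_clamped_to_one(self):
        x = np.tile([1.0, -1.0], 50)
        g, idx = statistical_inefficiency(x)
        assert g == 1.0
        assert len(idx) == 100

    def test_constant_series_convention(self):
        g, _ = statistical_inefficiency(np.full(50, 2.0))
        assert g == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            statistical_inefficiency(np.array([1.0, 2.0, 3.0]))


class TestAggregateReplicas:
    def test_identical_values(self):
        ests = [DeltaGEstimate(value=-17.0, stat_error=0.5, method="BAR")] * 5
        agg = aggregate_replicas(ests)
        assert agg.value == -17.0
        assert agg.stat_error == 0.0

    def test_sem_hand_arithmetic(self):
        ests = [DeltaGEstimate(value=v, stat_error=0.1, method="BAR")
                for v in (-16.0, -17.0, -18.0)]
        agg = aggregate_replicas(ests)
        assert agg.value == pytest.approx(-17.0)
        assert agg.stat_error == pytest.approx(1.0 / np.sqrt(3), abs=1e-3)

    def test_single_replica_passthrough(self):
        est = DeltaGEstimate(value=2.5, stat_error=0.4, method="BAR")
        agg = aggregate_replicas([est])
        assert agg.value == 2.5
        assert agg.stat_error == 0.4
        assert "single_replica" in agg.method

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_replicas([])


class TestLambdaSchedule:
    def test_forty_windows(self):
        sched = make_lambda_schedule(40)
        assert len(sched.values) == 41
        np.testing.assert_allclose(np.diff(sched.values), 0.025)

    def test_one_hundred_twenty_windows(self):
        sched = make_lambda_schedule(120, elec_start=0.25)
        np.testing.assert_allclose(np.diff(sched.values), 1 / 120)
        assert sched.elec_start == 0.25

    def test_endpoints(self):
        for n in (1, 7, 40):
            sched = make_lambda_schedule(n)
            assert sched.values[0] == 0.0 and sched.values[-1] == 1.0

    def test_zero_windows_rejected(self):
        with pytest.raises(ParameterError):
            make_lambda_schedule(0)


def _geometry():
    rng = np.random.default_rng(7)
    frame = rng.normal(size=(10, 3)) * 6
    gly = rng.normal(size=(5, 3)) * 2
    return frame, gly


class TestDbc:
    def test_reference_snapshot_is_zero(self):
        frame, gly = _geometry()
        ref = DbcReference(frame_atom_coords=frame, glycerol_ref_coords=gly)
        assert dbc(frame, gly, ref) == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_invariance(self):
        frame, gly = _geometry()
        ref = DbcReference(frame_atom_coords=frame, glycerol_ref_coords=gly)
        rng = np.random.default_rng(11)
        for _ in range(10):
            rot = random_rotation(rng)
            t = rng.normal(0, 20, 3)
            assert dbc(frame @ rot.T + t, gly @ rot.T + t, ref) == pytest.approx(
                0.0, abs=1e-8
            )

    def test_uniform_displacement_matches_rmsd_oracle(self):
        frame, gly = _geometry()
        ref = DbcReference(frame_atom_coords=frame, glycerol_ref_coords=gly)
        shifted = gly + np.array([0.0, 1.0, 0.0])
        direct_rmsd = np.sqrt(np.mean(np.sum((shifted - gly) ** 2, axis=1)))
        assert dbc(frame, shifted, ref) == pytest.approx(direct_rmsd, abs=1e-10)
        assert direct_rmsd == pytest.approx(1.0)

    def test_atom_count_mismatch(self):
        frame, gly = _geometry()
        ref = DbcReference(frame_atom_coords=frame, glycerol_ref_coords=gly)
        with pytest.raises(ParameterError, match="mismatch"):
            dbc(frame[:-1], gly, ref)

    def test_collinear_frame_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        _, gly = _geometry()
        ref = DbcReference(frame_atom_coords=line, glycerol_ref_coords=gly)
        with pytest.raises(DataError, match="degenerate"):
            dbc(line, gly, ref)


class TestDbcWall:
    def test_constant_series(self):
        assert dbc_wall(np.full(30, 4.2)) == pytest.approx(4.2)

    def test_uniform_quantile(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 10, 100_000)
        assert dbc_wall(values, 95) == pytest.approx(9.5, abs=0.05)

    def test_q100_is_max(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 3, 50)
        assert dbc_wall(values, 100) == pytest.approx(values.max())

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            dbc_wall(np.array([]))
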