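"""Generator correctness: closed forms, determinism, and calibration."""

import math

import numpy as np
import pytest

from lhpulse import (
    ParameterError,
    SimParams,
    isolated_pulse_params,
    simulate_cohort,
    simulate_cycle_log,
    simulate_lh_series,
    simulate_qpcr,
    simulate_surge_cohort,
)
from lhpulse.synthetic_data import noiseless_curve


class TestLHSeries:
    def test_no_pulse_degenerate_case_is_flat_baseline(self):
        p = SimParams(noise_sd=0.0, mean_ipi=math.inf, baseline=0.4, lod=0.0)
        series, truth = simulate_lh_series(p)
        assert len(series) == 19
        assert np.all(series.values == 0.4)
        assert len(truth.onset_times) == 0

    def test_forced_pulse_matches_closed_form(self):
        # C(50) = 0.3 + 0.4 * 2^(-(50-30)/20) = 0.3 + 0.4/2 = 0.5
        p = SimParams(noise_sd=0.0, lod=0.0, baseline=0.3, half_life=20.0,
                      onset_times=(30.0,), amplitudes=(0.4,))
        series, truth = simulate_lh_series(p)
        assert series.values[5] == pytest.approx(0.5, abs=1e-12)
        assert series.values[2] == pytest.approx(0.3)  # before onset
        assert series.values[3] == pytest.approx(0.7)  # at onset
        assert np.allclose(series.values, truth.noiseless_values)

    def test_noiseless_sampling_equals_closed_form_everywhere(self):
        p = SimParams(noise_sd=0.0, lod=0.0, seed=11)
        series, truth = simulate_lh_series(p)
        direct = noiseless_curve(p, truth.onset_times, truth.amplitudes)
        assert np.allclose(series.values, direct, atol=1e-12)

    def test_same_seed_is_bit_reproducible(self):
        a, _ = simulate_lh_series(SimParams(seed=42))
        b, _ = simulate_lh_series(SimParams(seed=42))
        assert np.array_equal(a.values, b.values)
        c, _ = simulate_lh_series(SimParams(seed=43))
        assert not np.array_equal(a.values, c.values)

    def test_lod_floor_applied(self):
        p = SimParams(baseline=0.001, mean_ipi=math.inf, noise_sd=0.0, lod=0.0039)
        series, _ = simulate_lh_series(p)
        assert np.all(series.values == 0.0039)

    def test_expected_pulse_count_matches_renewal_rate(self):
        """Law of large numbers: mean count over seeds ~ duration/mean_ipi."""
        duration, mean_ipi = 10_000.0, 60.0
        counts = []
        for seed in range(200):
            _, truth = simulate_lh_series(
                SimParams(duration=duration, interval=10.0, mean_ipi=mean_ipi,
                          seed=seed))
            counts.append(len(truth.onset_times))
        expected = duration / mean_ipi
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SimParams(baseline=-0.1)
        with pytest.raises(ParameterError):
            SimParams(duration=175.0, interval=10.0)  # not a multiple
        with pytest.raises(ParameterError):
            SimParams(onset_times=(30.0,), amplitudes=(0.4, 0.5))
        with pytest.raises(ParameterError):
            SimParams(onset_times=(200.0,), amplitudes=(0.4,))  # past window

    def test_cohort_reproducible_and_distinct(self):
        series, _ = simulate_cohort(SimParams(seed=5), n_animals=4)
        series2, _ = simulate_cohort(SimParams(seed=5), n_animals=4)
        assert [s.animal_id for s in series] == [s.animal_id for s in series2]
        for a, b in zip(series, series2):
            assert np.array_equal(a.values, b.values)
        assert not np.array_equal(series[0].values, series[1].values)

    def test_isolated_pulse_preset_keeps_prepulse_grid_at_baseline(self):
        p = isolated_pulse_params(seed=1)
        series, truth = simulate_lh_series(p)
        assert truth.onset_times[0] >= 35.0
        assert np.all(np.diff(truth.onset_times) >= 50.0)
        assert np.all(series.values[:4] == p.baseline)


class TestCycleLog:
    def test_regular_log_contains_all_four_stages(self):
        log = simulate_cycle_log(15, "regular", seed=0)
        assert set(log.stages) == {"proestrus", "estrus", "metestrus", "diestrus"}

    def test_infinite_diestrus_dwell_gives_all_diestrus(self):
        log = simulate_cycle_log(15, "irregular", seed=0,
                                 diestrus_dwell_mean=math.inf)
        assert set(log.stages) == {"diestrus"}

    def test_seed_determinism(self):
        a = simulate_cycle_log(15, "irregular", seed=9)
        b = simulate_cycle_log(15, "irregular", seed=9)
        assert a.stages == b.stages

    def test_irregular_spends_more_time_in_diestrus(self):
        """Calibration: over many animals the irregular preset spends a larger
        fraction of days in diestrus than the regular one."""
        def frac_diestrus(regularity):
            days = 0
            di = 0
            for seed in range(40):
                log = simulate_cycle_log(15, regularity, seed=seed)
                days += len(log)
                di += sum(s in ("diestrus", "metestrus") for s in log.stages)
            return di / days

        assert frac_diestrus("irregular") > frac_diestrus("regular") + 0.15

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            simulate_cycle_log(3, "regular", seed=0)
        with pytest.raises(ParameterError):
            simulate_cycle_log(10, "chaotic", seed=0)


class TestSurgeCohort:
    def test_cv_zero_gives_exact_factor(self):
        recs = simulate_surge_cohort(5, am_mean=0.3,
                                     surge_factor_by_group={"ctrl": 5.0},
                                     cv=0.0, seed=1)
        for r in recs:
            assert r.lh_am == pytest.approx(0.3)
            assert r.lh_pm == pytest.approx(1.5)

    def test_null_factor_preserves_mean(self):
        recs = simulate_surge_cohort(4000, am_mean=0.3,
                                     surge_factor_by_group={"ko": 1.0},
                                     cv=0.2, seed=2)
        am = np.array([r.lh_am for r in recs])
        pm = np.array([r.lh_pm for r in recs])
        assert pm.mean() == pytest.approx(am.mean(), rel=0.02)

    def test_determinism_and_errors(self):
        a = simulate_surge_cohort(3, 0.3, {"c": 5.0}, cv=0.3, seed=7)
        b = simulate_surge_cohort(3, 0.3, {"c": 5.0}, cv=0.3, seed=7)
        assert [(r.lh_am, r.lh_pm) for r in a] == [(r.lh_am, r.lh_pm) for r in b]
        with pytest.raises(ParameterError):
            simulate_surge_cohort(0, 0.3, {"c": 5.0})
        with pytest.raises(ParameterError):
            simulate_surge_cohort(3, 0.3, {"c": -1.0})


class TestQpcr:
    def test_noise_free_fold_two_shifts_ct_one_cycle(self):
        recs = simulate_qpcr({"control": 1.0, "treated": 2.0},
                             ct_noise_sd=0.0, n_per_group=3, seed=0)
        target = {r.group: r.mean_ct for r in recs if not r.is_housekeeping}
        assert target["control"] - target["treated"] == pytest.approx(1.0)

    def test_fold_one_noise_zero_identical_cts(self):
        recs = simulate_qpcr({"a": 1.0, "b": 1.0}, ct_noise_sd=0.0,
                             n_per_group=2, seed=0)
        cts = {r.mean_ct for r in recs if not r.is_housekeeping}
        assert len(cts) == 1

    def test_determinism_and_errors(self):
        a = simulate_qpcr({"c": 1.0}, seed=3)
        b = simulate_qpcr({"c": 1.0}, seed=3)
        assert [r.ct_replicates for r in a] == [r.ct_replicates for r in b]
        with pytest.raises(ParameterError):
            simulate_qpcr({"c": 0.0})
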