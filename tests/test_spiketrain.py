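"""Rate-estimator exactness, normalization, onset detection and half-widths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from meq.spiketrain import (detect_discharge_onset,
                            epoch_mean_rate, half_width, instantaneous_rate,
                            median_aligned_rate, normalize_rate,
                            resolve_baseline_sd, DegenerateBaselineError)


class TestInstantaneousRate:
    def test_regular_train_gives_inverse_isi(self):
        spikes = np.arange(0.0, 500.0, 10.0)     # ISI 10 ms
        rf = instantaneous_rate(spikes)
        assert np.allclose(rf.rates, 100.0)
        assert len(rf) == len(spikes) - 5

    def test_direct_formula_evaluation(self):
        spikes = [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0]
        rf = instantaneous_rate(spikes)
        # for the spike at 30 ms the five surrounding ISIs span 10..100 ms
        i = list(rf.times).index(30.0)
        assert rf.rates[i] == pytest.approx(5.0 / 90.0 * 1000.0)

    def test_too_few_spikes_gives_empty(self):
        assert len(instantaneous_rate(np.arange(5.0))) == 0

    @given(shift=st_h.floats(-1e4, 1e4))
    @settings(max_examples=25, deadline=None)
    def test_time_translation_equivariance(self, shift):
        spikes = np.array([0, 13, 29, 41, 60, 72, 95, 110, 131.0])
        a = instantaneous_rate(spikes)
        b = instantaneous_rate(spikes + shift)
        assert np.allclose(b.times - a.times, shift)
        assert np.allclose(a.rates, b.rates)

    def test_invariant_to_distant_spikes(self):
        spikes = np.array([0, 13, 29, 41, 60, 72, 95, 110, 131.0])
        a = instantaneous_rate(spikes)
        b = instantaneous_rate(np.concatenate([[-5000.0], spikes, [9000.0]]))
        # estimates whose five-interval support is unchanged must be identical
        common = np.isin(b.times, a.times[3:-3])
        kept = np.isin(a.times, b.times[common])
        assert np.allclose(b.rates[common], a.rates[kept])

    def test_poisson_estimator_behavior(self, rng):
        # mean of R_n is biased to 5/4 lambda; the median is nearly unbiased
        lam = 40.0
        spikes = np.cumsum(rng.exponential(1000.0 / lam, size=2000))
        rf = instantaneous_rate(spikes)
        assert np.mean(rf.rates) == pytest.approx(1.25 * lam, rel=0.05)
        assert np.median(rf.rates) == pytest.approx(lam, rel=0.10)


class TestMedianAlignment:
    def test_identical_trials_reproduce_each(self):
        spikes = np.arange(0.0, 400.0, 8.0)
        fns = [instantaneous_rate(spikes)] * 4
        grid, med = median_aligned_rate(fns, np.zeros(4), 50.0, 300.0)
        assert np.allclose(med, 125.0)

    def test_pointwise_median(self):
        fns = [instantaneous_rate(np.arange(0.0, 1200.0, 1000.0 / r))
               for r in (10.0, 20.0, 90.0)]
        grid, med = median_aligned_rate(fns, np.zeros(3), 300.0, 700.0)
        assert np.allclose(med, 20.0)

    def test_homogeneous_poisson_median_near_rate(self, rng):
        lam = 50.0
        fns = []
        for _ in range(50):
            spikes = np.cumsum(rng.exponential(1000.0 / lam, size=120))
            fns.append(instantaneous_rate(spikes))
        grid, med = median_aligned_rate(fns, np.zeros(50), 200.0, 1500.0)
        assert np.nanmean(med) == pytest.approx(lam, rel=0.15)


class TestNormalization:
    def test_zero_when_rate_equals_mean(self):
        assert np.allclose(normalize_rate(np.full(5, 20.0), 20.0, 5.0), 0.0)

    def test_arithmetic(self):
        assert normalize_rate(np.array([30.0]), 20.0, 5.0)[0] == pytest.approx(2.0)

    def test_degenerate_baseline_fallbacks(self):
        assert resolve_baseline_sd(10.0, 4.0) == 4.0
        assert resolve_baseline_sd(10.0, 0.0, pooled_sd=3.0) == 3.0
        poisson_sd = resolve_baseline_sd(10.0, 0.0)
        assert poisson_sd == pytest.approx(np.sqrt(10.0 * 0.3) / 0.3)
        with pytest.raises(DegenerateBaselineError):
            resolve_baseline_sd(0.0, 0.0)


class TestDischargeOnset:
    def test_flat_trial_has_no_discharge(self):
        grid = np.arange(0.0, 500.0)
        assert detect_discharge_onset(grid, np.zeros(500), (0.0, 500.0)) is None

    def test_step_input_detected_at_step(self):
        grid = np.arange(-300.0, 300.0)
        norm = np.where(grid >= -70.0, 10.0, 0.0)
        onset = detect_discharge_onset(grid, norm, (-200.0, 200.0))
        assert onset == pytest.approx(-70.0, abs=1.0)


class TestHalfWidth:
    def test_rectangular_burst(self):
        grid = np.arange(0.0, 500.0)
        rate = np.where((grid >= 100) & (grid < 180), 100.0, 0.0)
        burst = half_width(grid, rate, 0.0)
        assert burst.half_width == pytest.approx(80.0, abs=2.0)

    def test_triangular_burst_half_base(self):
        # symmetric triangle of base 100 ms crosses half height over 50 ms
        grid = np.arange(0.0, 300.0)
        rate = np.clip(50.0 - np.abs(grid - 150.0), 0.0, None)
        burst = half_width(grid, rate, 0.0)
        assert burst.half_width == pytest.approx(50.0, abs=2.0)

    def test_no_burst_sentinel(self):
        grid = np.arange(0.0, 100.0)
        assert half_width(grid, np.full(100, 7.0), 7.0) is None

    @given(scale=st_h.floats(0.1, 50.0), offset=st_h.floats(0.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance(self, scale, offset):
        grid = np.arange(0.0, 400.0)
        rate = np.where((grid >= 120) & (grid < 260), 90.0, 10.0)
        a = half_width(grid, rate, 10.0)
        b = half_width(grid, scale * rate + offset, scale * 10.0 + offset)
        assert b.half_width == pytest.approx(a.half_width)


class TestEpochRate:
    def test_count_over_duration(self):
        spikes = np.array([10.0, 30.0, 50.0, 70.0])
        assert epoch_mean_rate(spikes, (0.0, 80.0), 0.0) == pytest.approx(50.0)

    def test_baseline_subtraction(self):
        spikes = np.array([5.0, 25.0, 45.0])
        assert epoch_mean_rate(spikes, (0.0, 60.0), 10.0) == pytest.approx(40.0)

    def test_poisson_mean_recovery(self, rng):
        lam, base = 60.0, 12.0
        vals = [epoch_mean_rate(np.sort(rng.uniform(0, 500, rng.poisson(lam * 0.5))),
                                (100.0, 400.0), base) for _ in range(500)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(lam - base, abs=3 * se)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            epoch_mean_rate(np.array([1.0]), (10.0, 10.0), 0.0)
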