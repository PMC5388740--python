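"""von Mises fits, field widths, 2D movement fields and circular statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from meq.tuning import (default_slice_windows, dynamic_fields, fit_field_2d,
                        fit_von_mises, fit_von_mises_grid, rayleigh_test,
                        tuning_half_width, von_mises_curve,
                        watson_williams_test, watson_williams_permutation)
from meq.utils import circ_abs_dist_deg, wrap_deg

EIGHT_DIRS = np.arange(0.0, 360.0, 45.0)


class TestVonMisesFit:
    def test_noiseless_parameter_recovery(self):
        y = von_mises_curve(EIGHT_DIRS, 120.0, 246.0, 1.5)
        fit = fit_von_mises(EIGHT_DIRS, y)
        assert circ_abs_dist_deg(fit.mu_pd, 246.0) < 1.0
        assert fit.k == pytest.approx(1.5, rel=0.02)

    def test_sinusoidal_field_width_is_117(self):
        y = 1.0 + np.cos(np.deg2rad(EIGHT_DIRS))
        fit = fit_von_mises(EIGHT_DIRS, y)
        assert fit.width == pytest.approx(116.5, abs=1.0)
        # and the optimum agrees with the brute-force grid oracle
        oracle = fit_von_mises_grid(EIGHT_DIRS, y)
        assert fit.width == pytest.approx(oracle.width, abs=1.0)
        assert fit.rss <= oracle.rss + 1e-6

    def test_uniform_rates_are_untuned(self):
        fit = fit_von_mises(EIGHT_DIRS, np.full(8, 12.0))
        assert fit.untuned

    def test_all_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_von_mises(EIGHT_DIRS, -np.ones(8))

    @given(delta=st_h.floats(0.0, 360.0))
    @settings(max_examples=20, deadline=None)
    def test_rotation_equivariance(self, delta):
        y = von_mises_curve(EIGHT_DIRS, 80.0, 100.0, 1.2)
        base = fit_von_mises(EIGHT_DIRS, y)
        rot = fit_von_mises(wrap_deg(EIGHT_DIRS + delta), y)
        assert circ_abs_dist_deg(rot.mu_pd, base.mu_pd + delta) < 1.5
        assert rot.k == pytest.approx(base.k, rel=0.02)

    def test_width_decreases_with_concentration(self):
        from meq.tuning import TuningFit
        widths = [TuningFit(1.0, 0.0, k, 0.0).width for k in (0.5, 1.0, 5.0, 50.0)]
        assert all(a > b for a, b in zip(widths, widths[1:]))


class TestTuningHalfWidth:
    def test_sinusoid_is_exactly_90(self):
        assert tuning_half_width(lambda x: 1 + np.cos(np.deg2rad(x))) == 90.0

    def test_narrow_von_mises_shrinks(self):
        w = [tuning_half_width(lambda x, k=k: von_mises_curve(x, 1.0, 180.0, k))
             for k in (1.0, 5.0, 25.0)]
        assert w[0] > w[1] > w[2]

    def test_flat_curve_sentinel(self):
        assert tuning_half_width(lambda x: np.ones_like(np.asarray(x))) is None

    def test_matches_grid_scan_on_sampled_curve(self):
        rng = np.random.default_rng(0)
        y = np.abs(rng.normal(10, 5, 8)) + von_mises_curve(EIGHT_DIRS, 50, 120, 2.0)
        got = tuning_half_width((EIGHT_DIRS, y))
        # independent brute force on the same periodic interpolation
        grid = np.arange(0.0, 360.0, 0.1)
        vals = np.interp(grid, np.concatenate([EIGHT_DIRS, [360.0]]),
                         np.concatenate([y, [y[0]]]))
        thr = vals.min() + (vals.max() - vals.min()) / 2.0
        peak = np.argmax(vals)
        rolled = np.roll(vals, -peak)
        right = np.argmax(rolled <= thr)
        left = np.argmax(rolled[::-1] <= thr) + 1
        expected = 0.5 * (right + left) * 0.1
        assert got == pytest.approx(expected, abs=0.3)


class TestField2D:
    def test_separable_field_recovery(self):
        amps = np.tile([10.0, 20.0], 8)
        dirs = np.repeat(EIGHT_DIRS, 2)
        gain, a0, sig, mu, k = 80.0, 15.0, 6.0, 210.0, 1.0
        y = gain * np.exp(-0.5 * ((amps - a0) / sig) ** 2) * np.exp(
            k * (np.cos(np.deg2rad(dirs - mu)) - 1.0))
        f = fit_field_2d(amps, dirs, y)
        assert circ_abs_dist_deg(f.direction.mu_pd, mu) < 2.0
        assert f.direction.k == pytest.approx(k, rel=0.05)
        # two amplitudes leave the Gaussian underdetermined; the fitted
        # surface itself must reproduce the data
        from meq.tuning import _field_model
        pred = _field_model((amps, dirs), f.gain, f.amplitude_mean,
                            f.amplitude_sd, f.direction.mu_pd, f.direction.k)
        assert np.allclose(pred, y, atol=1e-3)

    def test_single_amplitude_degenerates_to_direction_fit(self):
        dirs = np.repeat(EIGHT_DIRS, 2)
        y = von_mises_curve(dirs, 50.0, 90.0, 1.0)
        f = fit_field_2d(np.full(len(dirs), 10.0), dirs, y)
        assert f.degenerate_amplitude
        assert circ_abs_dist_deg(f.direction.mu_pd, 90.0) < 3.0

    def test_all_zero_rates_give_zero_gain(self):
        f = fit_field_2d(np.tile([10.0, 20.0], 4), np.repeat(EIGHT_DIRS[:4], 2),
                         np.zeros(8))
        assert f.gain == 0.0


class TestDynamicFields:
    def test_default_windows_tile_minus30_to_130(self):
        windows = default_slice_windows()
        assert len(windows) == 8
        assert windows[0] == (-30.0, -10.0)
        assert windows[-1] == (110.0, 130.0)

    def test_drifting_field_moves_across_slices(self, rng):
        windows = default_slice_windows()
        dirs = np.repeat(np.tile(EIGHT_DIRS, 10), 2)
        amps = np.tile([10.0, 20.0], len(dirs) // 2)
        pd_start, pd_end = 270.0, 90.0
        rates = np.empty((len(dirs), len(windows)))
        for j, (w0, w1) in enumerate(windows):
            frac = (0.5 * (w0 + w1) + 30.0) / 150.0
            pd = pd_start + frac * (pd_end - pd_start)
            lam = 60.0 * np.exp(0.8 * (np.cos(np.deg2rad(dirs - pd)) - 1.0))
            rates[:, j] = rng.poisson(lam * 0.02) / 0.02
        dyn = dynamic_fields(amps, dirs, rates, windows)
        pds = np.asarray(dyn.preferred_directions())
        assert circ_abs_dist_deg(pds[0], pd_start) < 45.0
        assert circ_abs_dist_deg(pds[-1], pd_end) < 45.0

    def test_static_field_is_stable(self, rng):
        windows = default_slice_windows()
        dirs = np.repeat(np.tile(EIGHT_DIRS, 10), 2)
        amps = np.tile([10.0, 20.0], len(dirs) // 2)
        lam = 80.0 * np.exp(1.0 * (np.cos(np.deg2rad(dirs - 135.0)) - 1.0))
        rates = rng.poisson(np.tile(lam[:, None], (1, 8)) * 0.02) / 0.02
        dyn = dynamic_fields(amps, dirs, rates, windows)
        pds = np.asarray(dyn.preferred_directions())
        assert np.all([circ_abs_dist_deg(p, 135.0) < 20.0
                       for p in pds[np.isfinite(pds)]])

    def test_empty_slice_flagged(self):
        windows = default_slice_windows()
        rates = np.full((10, 8), np.nan)
        rates[:, 0] = 50.0
        dyn = dynamic_fields(np.tile([10.0, 20.0], 5),
                             np.repeat(EIGHT_DIRS[:5], 2), rates, windows)
        assert dyn.fields[1] is None


class TestRayleigh:
    def test_equally_spaced_angles_uniform(self):
        z, p = rayleigh_test(EIGHT_DIRS)
        assert p > 0.9

    def test_concentrated_angles_significant(self):
        z, p = rayleigh_test(np.full(20, 90.0))
        assert p < 1e-4

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 90.0])


class TestWatsonWilliams:
    def test_identical_groups_not_significant(self, rng):
        a = wrap_deg(rng.vonmises(np.pi / 2, 5.0, 30) * 180 / np.pi)
        assert watson_williams_test(a, a).pvalue > 0.5

    def test_well_separated_groups_significant(self, rng):
        a = wrap_deg(np.rad2deg(rng.vonmises(0.0, 5.0, 20)))
        b = wrap_deg(np.rad2deg(rng.vonmises(np.pi / 2, 5.0, 20)))
        res = watson_williams_test(a, b)
        assert res.pvalue < 0.001
        # the permutation version agrees on rejection
        _, p_perm = watson_williams_permutation(a, b, n_perm=500, seed=1)
        assert p_perm < 0.01

    def test_low_concentration_flagged(self, rng):
        a = rng.uniform(0, 360, 30)
        b = rng.uniform(0, 360, 30)
        assert watson_williams_test(a, b).low_concentration

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            watson_williams_test([0, 10, 20], [40, 50, 60])
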