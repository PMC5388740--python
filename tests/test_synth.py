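"""Generator contracts: kinematic calibration, reaction-time structure,
Poisson spike statistics and reproducibility."""

import numpy as np
import pytest

from meq.synth import (CellArchetype, ConfigurationError, KinematicsModel,
                       TaskConfig, generate_session, generate_spikes,
                       generate_trajectory, make_reference_population,
                       minimum_jerk_position)
from meq.utils import substream

from conftest import constant_rate_cell


class TestTrajectories:
    @pytest.mark.parametrize("effector,amp,expected", [
        ("eye", 10.0, 45.0), ("eye", 20.0, 58.0),
        ("hand", 10.0, 198.0), ("hand", 20.0, 257.0)])
    def test_detected_duration_matches_calibration(self, kin, effector, amp,
                                                   expected):
        _, _, info = generate_trajectory(effector, 0.0, amp, kin)
        assert info["offset"] - info["onset"] == pytest.approx(expected, abs=1.5)

    def test_endpoint_hits_target_window(self, kin):
        _, xy, _ = generate_trajectory("hand", 135.0, 20.0, kin)
        end = xy[-1]
        target = 20.0 * np.array([np.cos(np.deg2rad(135)), np.sin(np.deg2rad(135))])
        assert np.all(np.abs(end - target) < 0.75)   # inside the 1.5 deg window

    def test_minimum_jerk_integrates_to_amplitude(self):
        # closed form: displacement profile must reach exactly 1 at tau=1
        tau = np.linspace(0, 1, 100001)
        v = np.gradient(minimum_jerk_position(tau), tau)
        integral = np.trapezoid(v, tau)
        assert integral == pytest.approx(1.0, rel=1e-3)

    def test_zero_amplitude_is_stationary(self, kin):
        _, xy, info = generate_trajectory("eye", 0.0, 0.0, kin)
        assert info["onset"] is None
        assert np.allclose(xy, 0.0)

    def test_unknown_effector_rejected(self, kin):
        with pytest.raises(ConfigurationError):
            generate_trajectory("head", 0.0, 10.0, kin)


class TestSession:
    def test_every_combination_represented(self, small_session, small_task):
        seen = {(t.condition, t.target_direction, t.target_amplitude)
                for t in small_session}
        expected = {(c, float(d), float(a)) for c in small_task.conditions
                    for d in small_task.directions for a in small_task.amplitudes}
        assert seen == expected

    def test_regeneration_is_identical(self, small_task, kin, basic_cells,
                                       small_session):
        again = generate_session(small_task, kin, basic_cells, seed=7)
        for a, b in zip(small_session, again):
            assert a.event_times == b.event_times
            assert np.array_equal(a.eye_trace, b.eye_trace)
            for sa, sb in zip(a.spike_times, b.spike_times):
                assert np.array_equal(sa, sb)

    def test_eye_hand_interval_statistics(self, kin):
        # saccades lead hand movements by the configured 81 +/- 33 ms
        task = TaskConfig(n_trials_per_condition=8, amplitudes=(10.0,),
                          conditions=("eye-hand",), seed=11)
        cells = [constant_rate_cell(5.0)]
        trials = generate_session(task, kin, cells, seed=11,
                                  include_traces=False)
        # top up to >= 500 trials with more seeds
        for s in range(12, 20):
            trials += generate_session(TaskConfig(
                n_trials_per_condition=8, amplitudes=(10.0,),
                conditions=("eye-hand",), seed=s), kin, cells, seed=s,
                include_traces=False)
        iv = np.array([t.ground_truth["hand_onset"] - t.ground_truth["saccade_onset"]
                       for t in trials])
        assert len(iv) >= 500
        assert abs(iv.mean() - 81.0) < 3 * 33.0 / np.sqrt(len(iv))
        assert abs(iv.std(ddof=1) - 33.0) < 5.0

    def test_command_correlation_squares(self, kin):
        # each effector correlates 0.7 with the command; effectors pairwise ~0.49
        rng = substream(99, 0)
        draws = np.array([kin.draw_reaction_times(rng) for _ in range(20000)])
        c, e, h = draws.T
        assert np.corrcoef(c, e)[0, 1] == pytest.approx(0.7, abs=0.02)
        assert np.corrcoef(e, h)[0, 1] == pytest.approx(0.49, abs=0.03)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TaskConfig(directions=())
        with pytest.raises(ConfigurationError):
            TaskConfig(delay_ms=(300.0, 100.0))
        with pytest.raises(ConfigurationError):
            generate_session(TaskConfig(), KinematicsModel(), [], seed=0)


class TestSpikes:
    def _fixation_trial(self, kin, end=2000.0):
        task = TaskConfig(n_trials_per_condition=1, amplitudes=(10.0,),
                          conditions=("fixation",), seed=3)
        trial = generate_session(task, kin, [constant_rate_cell(50.0)],
                                 seed=3, include_traces=False)[0]
        trial.event_times["end"] = end
        return trial

    def test_homogeneous_counts_are_poisson(self, kin):
        trial = self._fixation_trial(kin)
        cell = constant_rate_cell(50.0)
        counts = []
        for s in range(1000):
            spikes = generate_spikes(cell, trial, substream(5, s),
                                     record_truth=False)
            counts.append(len(spikes))
        counts = np.asarray(counts, float)
        expected = 50.0 * trial.end / 1000.0
        assert counts.mean() == pytest.approx(expected, rel=0.05)
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_zero_envelope_yields_no_spikes(self, kin):
        task = TaskConfig(n_trials_per_condition=1, amplitudes=(10.0,),
                          conditions=("eye",), directions=(0.0,), seed=4)
        # anti-preferred direction with zero baseline and very narrow field
        cell = CellArchetype(pd_eye=180.0, width_eye=25.0, baseline_rate=0.0,
                             peak_rate_eye=80.0)
        trial = generate_session(task, kin, [cell], seed=4,
                                 include_traces=False)[0]
        spikes = generate_spikes(cell, trial, substream(6, 0),
                                 record_truth=False)
        assert len(spikes) <= 1     # vm gain at 180 deg off is ~exp(-2k) ~ 0

    def test_burst_onset_leads_saccade_by_configured_lead(self, kin):
        task = TaskConfig(n_trials_per_condition=25, amplitudes=(10.0,),
                          conditions=("eye",), directions=(90.0,), seed=8)
        cell = CellArchetype(pd_eye=90.0, lead_eye=70.0, onset_lock="eye",
                             onset_jitter_sd=10.0, peak_rate_eye=90.0)
        trials = generate_session(task, kin, [cell], seed=8,
                                  include_traces=False)
        leads = [t.ground_truth["saccade_onset"] - t.ground_truth["discharge_onset"][0]
                 for t in trials]
        assert np.mean(leads) == pytest.approx(70.0, abs=3 * 10.0 / np.sqrt(len(leads)))

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            CellArchetype(baseline_rate=-1.0)


def test_reference_population_composition():
    cells = make_reference_population(seed=0)
    on = [c.true_labels()["on_direction"] for c in cells]
    assert len(cells) == 55
    assert on.count("invariant") == 27
    assert on.count("eye") == 10
    assert on.count("hand") == 8
    locks = [c.onset_lock for c in cells]
    assert locks.count("both") == 36 and locks.count("hand") == 4
    peaks = [c.peak_rate_eye for c in cells] + [c.peak_rate_hand for c in cells]
    assert 18.0 <= min(peaks) and max(peaks) <= 166.0
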