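"""Screening gate and the four effector-preference label columns."""

import numpy as np
import pytest

from meq.analysis import analyze_cell, movement_onsets
from meq.classification import (classify_cell, compare_preferred_directions,
                                screen_cell, summarize_population)
from meq.synth import (CellArchetype, TaskConfig, generate_session,
                       make_archetype)
from meq.utils import substream


@pytest.fixture(scope="module")
def archetype_run(kin):
    """One session holding a spread of archetypes plus screening controls."""
    rng = substream(0, 2)
    labels = [("invariant", "same", "same", "both"),
              ("eye", "same", "eye", "eye"),
              ("hand", "hand", "hand", "hand"),
              ("intermediate", "intermediate", "intermediate", "both"),
              ("mixed", "same", "mixed", "eye")]
    cells = [make_archetype(*lab, rng, f"c{i}") for i, lab in enumerate(labels)]
    # screening controls: post-movement, visual-only, silent
    cells.append(CellArchetype(lead_eye=-60.0, lead_hand=-60.0,
                               onset_lock="eye", cell_id="post"))
    cells.append(CellArchetype(response_mode="visual", peak_rate_eye=80.0,
                               width_eye=300.0, cell_id="vis"))
    cells.append(CellArchetype(peak_rate_eye=0.0, peak_rate_hand=0.0,
                               peak_rate_eyehand=0.0, baseline_rate=8.0,
                               cell_id="none"))
    task = TaskConfig(n_trials_per_condition=10, seed=2)
    trials = generate_session(task, kin, cells, seed=2, include_traces=False)
    onsets = movement_onsets(trials)
    analyses = [analyze_cell(trials, i, onsets=onsets)
                for i in range(len(cells))]
    return labels, cells, trials, analyses


class TestScreening:
    def test_meq_cells_pass_the_gate(self, archetype_run):
        labels, cells, trials, analyses = archetype_run
        for i in range(len(labels)):
            assert screen_cell(analyses[i]).category == "meq"

    def test_post_movement_cell_excluded(self, archetype_run):
        *_, analyses = archetype_run
        assert screen_cell(analyses[5]).category == "post-movement-only"

    def test_visual_only_cell_excluded(self, archetype_run):
        *_, analyses = archetype_run
        assert screen_cell(analyses[6]).category == "visual-only"

    def test_silent_cell_is_non_task(self, archetype_run):
        *_, analyses = archetype_run
        assert screen_cell(analyses[7]).category == "non-task"

    def test_missing_condition_undetermined(self, kin):
        rng = substream(1, 1)
        cell = make_archetype("invariant", "same", "same", "both", rng)
        task = TaskConfig(n_trials_per_condition=4, conditions=("eye",), seed=5)
        trials = generate_session(task, kin, [cell], seed=5,
                                  include_traces=False)
        ca = analyze_cell(trials, 0)
        assert screen_cell(ca).category == "undetermined"


class TestLabels:
    @pytest.mark.parametrize("idx", range(5))
    def test_archetype_labels_recovered(self, archetype_run, idx):
        labels, cells, trials, analyses = archetype_run
        cl = classify_cell(analyses[idx], seed=10 + idx)
        got = (cl.on_direction, cl.intensity, cl.duration, cl.onset)
        # single small session: allow one column off.  The all-intermediate
        # archetype sits between the decision boundaries of every column;
        # its aggregate recovery is covered by the population-level test, so
        # here only its on-direction label is required.
        if labels[idx][0] == "intermediate":
            assert got[0] == "intermediate"
        else:
            assert sum(g == l for g, l in zip(got, labels[idx])) >= 3

    def test_on_direction_examples(self, archetype_run):
        labels, cells, trials, analyses = archetype_run
        assert classify_cell(analyses[0], seed=10).on_direction == "invariant"
        assert classify_cell(analyses[1], seed=11).on_direction == "eye"
        assert classify_cell(analyses[4], seed=14).on_direction == "mixed"

    def test_labels_stable_under_trial_permutation(self, archetype_run, kin):
        labels, cells, trials, analyses = archetype_run
        rng = np.random.default_rng(3)
        shuffled = [trials[i] for i in rng.permutation(len(trials))]
        ca = analyze_cell(shuffled, 1, onsets=movement_onsets(shuffled))
        cl_a = classify_cell(analyses[1], seed=11)
        cl_b = classify_cell(ca, seed=11)
        assert (cl_a.on_direction, cl_a.intensity, cl_a.duration) == \
            (cl_b.on_direction, cl_b.intensity, cl_b.duration)


class TestPdComparison:
    def test_same_tuning_rarely_flagged(self, rng):
        dirs = np.repeat(np.arange(0, 360, 45.0), 10)
        k = 0.5
        lam = 80 * np.exp(k * (np.cos(np.deg2rad(dirs - 90)) - 1))
        ps = []
        for rep in range(20):
            ra = rng.poisson(lam * 0.06) / 0.06
            rb = rng.poisson(lam * 0.06) / 0.06
            ps.append(compare_preferred_directions(dirs, ra, dirs, rb,
                                                   seed=rep)[1])
        assert np.mean(np.asarray(ps) < 0.05) <= 0.15

    def test_opposite_tuning_detected(self, rng):
        dirs = np.repeat(np.arange(0, 360, 45.0), 10)
        k = 0.5
        la = 80 * np.exp(k * (np.cos(np.deg2rad(dirs - 90)) - 1))
        lb = 80 * np.exp(k * (np.cos(np.deg2rad(dirs - 250)) - 1))
        d, p = compare_preferred_directions(
            dirs, rng.poisson(la * 0.06) / 0.06,
            dirs, rng.poisson(lb * 0.06) / 0.06, seed=0)
        assert p < 0.05 and d > 90.0


def test_population_summary_counts(archetype_run):
    labels, cells, trials, analyses = archetype_run
    cls = [classify_cell(a, seed=20 + i) for i, a in enumerate(analyses[:5])]
    summary = summarize_population(cls)
    assert summary["n_cells"] == 5
    assert sum(summary["counts"]["on_direction"].values()) == 5
    assert summarize_population([])["n_cells"] == 0
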