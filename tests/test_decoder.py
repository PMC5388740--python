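"""Population decoder: training, chance levels, invariances and ablation."""

import numpy as np
import pytest

from meq.decoder import (NetworkSpec, assemble_dataset, ablation_curve,
                         compare_ablation_curves, stratified_split,
                         train_network, DecoderDataset)
from meq.utils import substream

CONDS = ("eye", "hand", "eye-hand")
DIRS = tuple(np.arange(0.0, 360.0, 45.0))


def _separable_pool(rng, n_cells=24, n_trials=12, noise=1.0):
    """One dedicated high-rate cell per (condition, direction) stratum."""
    pool = rng.normal(0.0, noise, size=(n_cells, 3, 8, n_trials))
    for ci in range(3):
        for di in range(8):
            pool[ci * 8 + di, ci, di, :] += 60.0
    return pool


class TestDataset:
    def test_dimensions_and_strata(self, rng):
        pool = _separable_pool(rng)
        ds = assemble_dataset(pool, "direction", CONDS, DIRS, 10, seed=0)
        assert ds.inputs.shape == (3 * 8 * 10, 24)
        assert set(ds.labels) == set(range(8))

    def test_fixed_seed_reproducible(self, rng):
        pool = _separable_pool(rng)
        a = assemble_dataset(pool, "effector", CONDS, DIRS, 10, seed=5)
        b = assemble_dataset(pool, "effector", CONDS, DIRS, 10, seed=5)
        assert np.array_equal(a.inputs, b.inputs)

    def test_stratum_with_unusable_cell_skipped(self, rng):
        pool = _separable_pool(rng)
        pool[0, 0, 0, :] = np.nan
        ds = assemble_dataset(pool, "direction", CONDS, DIRS, 10, seed=0)
        assert ds.inputs.shape[0] == (3 * 8 - 1) * 10
        assert not np.any([p == ("eye", 0.0) for p in ds.provenance])


class TestTraining:
    def test_separable_dataset_reaches_full_accuracy(self, rng):
        pool = _separable_pool(rng)
        ds = assemble_dataset(pool, "direction", CONDS, DIRS, 20, seed=1)
        net = train_network(ds, NetworkSpec(output_units=8, restarts=3), seed=1)
        assert net.test_accuracy == 1.0

    def test_shuffled_labels_fall_to_chance(self, rng):
        pool = _separable_pool(rng)
        ds = assemble_dataset(pool, "direction", CONDS, DIRS, 20, seed=1)
        shuffled = DecoderDataset(ds.inputs,
                                  substream(9, 9).permutation(ds.labels),
                                  ds.n_classes, ds.provenance)
        net = train_network(shuffled, NetworkSpec(output_units=8, restarts=2),
                            seed=2)
        se = np.sqrt(0.125 * 0.875 / (0.35 * len(ds)))
        assert abs(net.test_accuracy - 0.125) < 5 * se

    def test_input_permutation_invariance(self, rng):
        pool = _separable_pool(rng)
        ds = assemble_dataset(pool, "effector", CONDS, DIRS, 15, seed=1)
        perm = substream(4, 4).permutation(ds.inputs.shape[1])
        ds_p = DecoderDataset(ds.inputs[:, perm], ds.labels, ds.n_classes,
                              ds.provenance)
        a = train_network(ds, NetworkSpec(output_units=3, restarts=2), seed=5)
        b = train_network(ds_p, NetworkSpec(output_units=3, restarts=2), seed=5)
        assert abs(a.test_accuracy - b.test_accuracy) < 0.05

    def test_split_fractions_respected(self):
        labels = np.repeat(np.arange(4), 40)
        tr, va, te = stratified_split(labels, (0.6, 0.05, 0.35),
                                      np.random.default_rng(0))
        assert len(tr) == 96 and len(va) == 8 and len(te) == 56
        assert set(np.concatenate([tr, va, te])) == set(range(160))

    def test_mismatched_output_units_rejected(self, rng):
        pool = _separable_pool(rng)
        ds = assemble_dataset(pool, "direction", CONDS, DIRS, 10, seed=0)
        with pytest.raises(ValueError):
            train_network(ds, NetworkSpec(output_units=3), seed=0)


class TestAblation:
    def test_zero_removed_matches_full_population(self, rng):
        pool = _separable_pool(rng)
        spec = NetworkSpec(output_units=8, restarts=1)
        res = ablation_curve(pool, CONDS, DIRS, "direction",
                             np.arange(12), np.arange(12, 24), "half",
                             [0], reps=3, spec=spec,
                             n_samples_per_stratum=15, seed=1)
        assert res.mean_accuracy[0] == pytest.approx(1.0, abs=0.05)

    def test_removal_capped_at_group_size(self, rng):
        pool = _separable_pool(rng)
        spec = NetworkSpec(output_units=3, restarts=1)
        res = ablation_curve(pool, CONDS, DIRS, "effector",
                             np.arange(4), np.arange(4, 24), "tiny",
                             [99], reps=2, spec=spec,
                             n_samples_per_stratum=10, seed=2)
        assert res.n_removed == [4]

    def test_identical_curves_not_significant(self, rng):
        pool = _separable_pool(rng)
        spec = NetworkSpec(output_units=3, restarts=1)
        res = ablation_curve(pool, CONDS, DIRS, "effector", np.arange(6),
                             np.arange(6, 24), "g", [2], reps=4, spec=spec,
                             n_samples_per_stratum=10, seed=3)
        p = compare_ablation_curves(res, res)
        assert p[0] == pytest.approx(1.0)

    def test_mismatched_grids_rejected(self, rng):
        pool = _separable_pool(rng)
        spec = NetworkSpec(output_units=3, restarts=1)
        a = ablation_curve(pool, CONDS, DIRS, "effector", np.arange(6),
                           np.arange(6, 24), "g", [1], reps=2, spec=spec,
                           n_samples_per_stratum=8, seed=3)
        b = ablation_curve(pool, CONDS, DIRS, "effector", np.arange(6),
                           np.arange(6, 24), "g", [2], reps=2, spec=spec,
                           n_samples_per_stratum=8, seed=3)
        with pytest.raises(ValueError):
            compare_ablation_curves(a, b)
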