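"""Population decoding of movement direction and effector identity.

A three-layer feedforward network reads a vector of per-cell movement-epoch
rates (one input unit per cell, 55 by default), passes it through 50 tanh
hidden units to 8 (direction) or 3 (effector) tanh output units, and is
trained by full-batch gradient descent (Adam) on the sum-of-squared-errors
against one-hot targets.  Data are split 60/5/35 into train/validation/test
per class; training stops when validation error stops improving, and the
best of 10 random restarts (by validation error) is evaluated on the test
set.  Ablation curves retrain the network after randomly removing
progressively more cells of one class (invariant vs non-invariant
preferred direction) and average accuracy over many removal draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .utils import substream


@dataclass
class NetworkSpec:
    hidden_units: int = 50
    output_units: int = 8
    split: tuple[float, float, float] = (0.60, 0.05, 0.35)
    restarts: int = 10
    learning_rate: float = 0.02
    max_epochs: int = 2000
    patience: int = 30           # validation checks without improvement
    check_every: int = 1         # epochs between validation checks
    zscore_inputs: bool = True

    def __post_init__(self):
        if self.hidden_units < 1 or self.output_units < 1:
            raise ValueError("layer sizes must be positive")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class DecoderDataset:
    """Input vectors (n_samples x n_cells) with integer class labels."""

    inputs: np.ndarray
    labels: np.ndarray
    n_classes: int
    provenance: list = field(default_factory=list)   # (condition, direction)

    def __len__(self):
        return len(self.labels)


def assemble_dataset(pool: np.ndarray, task: str, conditions,
                     directions, n_samples_per_stratum: int = 40,
                     seed: int = 0, cell_subset=None) -> DecoderDataset:
    """Build decoder samples from a movement-epoch rate pool.

    `pool` has shape (n_cells, n_conditions, n_directions, n_trials); each
    sample's elements are drawn independently per cell from that cell's
    trials of the sample's (condition, direction) stratum.  `task` is
    'direction' (8-way) or 'effector' (one class per condition).  A stratum
    in which some cell has no usable trial is skipped (no imputation).
    """
    if task not in ("direction", "effector"):
        raise ValueError("task must be 'direction' or 'effector'")
    cells = np.arange(pool.shape[0]) if cell_subset is None \
        else np.asarray(cell_subset)
    rng = substream(seed, 7040)
    X, y, prov = [], [], []
    for ci, cond in enumerate(conditions):
        for di, direction in enumerate(directions):
            block = pool[cells, ci, di, :]            # n_cells x n_trials
            ok = np.isfinite(block)
            if np.any(ok.sum(axis=1) == 0):
                continue
            if np.all(ok):
                idx = rng.integers(0, block.shape[1],
                                   size=(n_samples_per_stratum, len(cells)))
                samples = block[np.arange(len(cells))[None, :], idx]
            else:
                ok_trials = [np.flatnonzero(ok[j]) for j in range(len(cells))]
                samples = np.empty((n_samples_per_stratum, len(cells)))
                for j, tset in enumerate(ok_trials):
                    samples[:, j] = block[j, rng.choice(
                        tset, size=n_samples_per_stratum)]
            X.append(samples)
            y.extend([di if task == "direction" else ci]
                     * n_samples_per_stratum)
            prov.extend([(cond, direction)] * n_samples_per_stratum)
    X = [row for block in X for row in block]
    n_classes = len(directions) if task == "direction" else len(conditions)
    return DecoderDataset(np.asarray(X, float), np.asarray(y, int),
                          n_classes, prov)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _forward(params, X):
    W1, b1, W2, b2 = params
    H = np.tanh(X @ W1 + b1)
    return np.tanh(H @ W2 + b2), H


def _loss_grad(params, X, Y):
    W1, b1, W2, b2 = params
    O, H = _forward(params, X)
    E = O - Y
    loss = float(np.sum(E * E))
    dO = 2.0 * E * (1.0 - O * O)
    gW2 = H.T @ dO
    gb2 = dO.sum(axis=0)
    dH = (dO @ W2.T) * (1.0 - H * H)
    gW1 = X.T @ dH
    gb1 = dH.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def _init_params(n_in, n_hidden, n_out, rng):
    # weights start uniform, scaled by fan-in: raw U(-1, 1) weights over
    # 50+ standardized inputs saturate every tanh unit and stall training
    return [rng.uniform(-1.0, 1.0, (n_in, n_hidden)) / np.sqrt(n_in),
            rng.uniform(-1.0, 1.0, n_hidden),
            rng.uniform(-1.0, 1.0, (n_hidden, n_out)) / np.sqrt(n_hidden),
            rng.uniform(-1.0, 1.0, n_out)]


def _val_loss(params, X, Y):
    O, _ = _forward(params, X)
    return float(np.sum((O - Y) ** 2))


def _train_once(Xtr, Ytr, Xva, Yva, spec: NetworkSpec, rng):
    params = _init_params(Xtr.shape[1], spec.hidden_units, Ytr.shape[1], rng)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1m, b2m = 0.9, 0.999
    eps = 1e-8
    lr = spec.learning_rate
    best = ([p.copy() for p in params], _val_loss(params, Xva, Yva))
    bad = 0
    t = 0
    for epoch in range(spec.max_epochs):
        t += 1
        _, grads = _loss_grad(params, Xtr, Ytr)
        for i in range(4):
            m[i] = b1m * m[i] + (1 - b1m) * grads[i]
            v[i] = b2m * v[i] + (1 - b2m) * grads[i] ** 2
            mh = m[i] / (1 - b1m ** t)
            vh = v[i] / (1 - b2m ** t)
            params[i] = params[i] - lr * mh / (np.sqrt(vh) + eps)
        if (epoch + 1) % spec.check_every == 0:
            vl = _val_loss(params, Xva, Yva)
            if vl < best[1] - 1e-9:
                best = ([p.copy() for p in params], vl)
                bad = 0
            else:
                bad += 1
                if bad >= spec.patience:     # validation deteriorating: stop
                    break
    return best


def stratified_split(labels: np.ndarray, fractions, rng):
    """Index arrays (train, val, test) with every class in every part."""
    tr, va, te = [], [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        n = len(idx)
        n_tr = max(1, int(round(fractions[0] * n)))
        n_va = max(1, int(round(fractions[1] * n)))
        if n_tr + n_va >= n:
            raise ValueError(f"class {c} too small to split {fractions}")
        tr.extend(idx[:n_tr])
        va.extend(idx[n_tr:n_tr + n_va])
        te.extend(idx[n_tr + n_va:])
    return (np.array(sorted(tr)), np.array(sorted(va)), np.array(sorted(te)))


@dataclass
class TrainedNetwork:
    params: list
    input_mean: np.ndarray
    input_sd: np.ndarray
    test_accuracy: float
    val_loss: float
    n_classes: int

    def predict(self, X):
        Xn = (X - self.input_mean) / self.input_sd
        O, _ = _forward(self.params, Xn)
        return np.argmax(O, axis=1)


def train_network(dataset: DecoderDataset, spec: NetworkSpec | None = None,
                  seed: int = 0) -> TrainedNetwork:
    """Best-of-restarts training with validation early stopping.

    Restarts differ only in their weight initialization; the split is fixed
    by the seed so restarts compete on the same data.  Reports accuracy on
    the held-out test set.
    """
    if spec is None:
        spec = NetworkSpec(output_units=dataset.n_classes)
    if spec.output_units != dataset.n_classes:
        raise ValueError("spec.output_units must match dataset.n_classes")
    rng = substream(seed, 3300)
    tr, va, te = stratified_split(dataset.labels, spec.split, rng)
    X = dataset.inputs
    mean = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0)
    if not spec.zscore_inputs:
        mean = np.zeros_like(mean)
        sd = np.ones_like(sd)
    sd = np.where(sd > 0, sd, 1.0)
    Xn = (X - mean) / sd
    Y = np.zeros((len(X), dataset.n_classes))
    Y[np.arange(len(X)), dataset.labels] = 1.0

    best = None
    for r in range(spec.restarts):
        params, vl = _train_once(Xn[tr], Y[tr], Xn[va], Y[va], spec,
                                 substream(seed, 3300, r + 1))
        if best is None or vl < best[1]:
            best = (params, vl)
    params, vl = best
    O, _ = _forward(params, Xn[te])
    acc = float(np.mean(np.argmax(O, axis=1) == dataset.labels[te]))
    return TrainedNetwork(params=params, input_mean=mean, input_sd=sd,
                          test_accuracy=acc, val_loss=vl,
                          n_classes=dataset.n_classes)


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    group_removed: str            # 'invariant' | 'non-invariant'
    task: str
    n_removed: list
    reps: int
    accuracies: np.ndarray        # len(n_removed) x reps

    @property
    def mean_accuracy(self):
        return self.accuracies.mean(axis=1)


def ablation_curve(pool, conditions, directions, task: str, group_cells,
                   other_cells, group_name: str, n_removed_list,
                   reps: int = 200, spec: NetworkSpec | None = None,
                   n_samples_per_stratum: int = 40, seed: int = 0,
                   restarts_per_rep: int = 1) -> AblationResult:
    """Retrain-after-removal accuracy curve for one cell group.

    For each n in `n_removed_list`, `reps` random subsets of `group_cells`
    of size n are removed, the network is retrained on the remaining
    population, and test accuracies are collected.  Removal counts beyond
    the group size are capped (with the cap recorded in ``n_removed``).
    """
    group_cells = np.asarray(group_cells)
    other_cells = np.asarray(other_cells)
    if spec is None:
        n_classes = len(directions) if task == "direction" else len(conditions)
        spec = NetworkSpec(output_units=n_classes, restarts=restarts_per_rep)
    capped = [min(int(n), len(group_cells)) for n in n_removed_list]
    acc = np.zeros((len(capped), reps))
    for i, n_rm in enumerate(capped):
        for r in range(reps):
            rng = substream(seed, 100 + i, r)
            keep_group = rng.permutation(group_cells)[n_rm:]
            cells = np.sort(np.concatenate([keep_group, other_cells]))
            ds = assemble_dataset(pool, task, conditions, directions,
                                  n_samples_per_stratum,
                                  seed=int(rng.integers(2**31 - 1)),
                                  cell_subset=cells)
            net = train_network(ds, spec, seed=int(rng.integers(2**31 - 1)))
            acc[i, r] = net.test_accuracy
    return AblationResult(group_removed=group_name, task=task,
                          n_removed=capped, reps=reps, accuracies=acc)


def compare_ablation_curves(result_a: AblationResult, result_b: AblationResult):
    """Per-size unpaired t-test p-values between two ablation curves."""
    from scipy.stats import ttest_ind
    if result_a.n_removed != result_b.n_removed or result_a.reps != result_b.reps:
        raise ValueError("ablation grids/reps must match")
    out = []
    for i in range(len(result_a.n_removed)):
        a, b = result_a.accuracies[i], result_b.accuracies[i]
        if np.std(a) == 0 and np.std(b) == 0:
            out.append(1.0 if np.allclose(a.mean(), b.mean()) else 0.0)
        else:
            out.append(float(ttest_ind(a, b, equal_var=False).pvalue))
    return np.array(out)
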