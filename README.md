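# meq — analysis of motor-equivalence neurons

Tools for studying **motor-equivalence (Meq) neurons**: premotor cells that
fire phasically before and during movements of either the eyes or the hand,
and that may encode a desired displacement vector independently of the
effector that executes it.  The package covers the full analysis chain for
a center-out eye/hand task, plus a synthetic-data generator that emulates
the task and the reported response statistics so everything runs without
external recordings:

* **Simulation** (`meq.synth`) — trial-structured sessions: behavioral
  traces (eye 1000 Hz, hand cursor 666 Hz), task events, and spike trains
  of parameterized cell archetypes (inhomogeneous Poisson by thinning) with
  exact ground truth.
* **Kinematics** (`meq.kinematics`) — smoothed speed, saccade onset at
  20 deg/s, hand onset at 1% of peak speed, movement vectors.
* **Spike trains** (`meq.spiketrain`) — the interval-based instantaneous
  rate R_n = 5/(t_{n+3} − t_{n−2}), baseline normalization, 2-SD discharge
  onset detection, burst half-widths, movement-epoch rates.
* **Tuning** (`meq.tuning`) — von Mises fits
  A·e^{k cos(θ−μ)}/(2π I₀(k)) with field width 2/√k, Gaussian × von Mises
  2-D movement fields, time-sliced dynamic fields, Rayleigh and
  Watson–Williams tests.
* **Timing** (`meq.timing`) — onset-jitter regressions, latency-spread
  ratios SD_E/SD_H, Bartlett and Kepner–Randles scale tests.
* **Classification** (`meq.classification`) — the Meq screening gate and
  the four effector-preference labels per cell (On-direction, Intensity,
  Duration, Onset), with population summaries and a packaged 55-cell
  reference table.
* **Decoding** (`meq.decoder`) — a 55-50-8 tanh network that reads
  per-cell discharge intensities to classify movement direction (8-way) or
  effector (3-way), with invariant/non-invariant ablation curves.

## Worked example

```python
import numpy as np
from meq import (KinematicsModel, TaskConfig, NetworkSpec, fit_von_mises,
                 make_reference_population, simulate_rate_pool,
                 assemble_dataset, train_network, tuning_half_width)
from meq.tuning import von_mises_curve

# directional tuning: fit a synthetic cell sampled at the 8 task directions
dirs = np.arange(0.0, 360.0, 45.0)
fit = fit_von_mises(dirs, von_mises_curve(dirs, 120.0, 246.0, 1.0))
print(fit.mu_pd, fit.width)       # -> 246.0 114.6

# analytic anchors of a purely sinusoidal field
print(tuning_half_width(lambda x: 1 + np.cos(np.deg2rad(x))))   # -> 90.0
print(fit_von_mises(dirs, 1 + np.cos(np.deg2rad(dirs))).width)  # -> 116.5

# decode movement direction from a calibrated 55-cell synthetic population
cells = make_reference_population(seed=0)
task = TaskConfig(n_trials_per_condition=10, seed=1)
pool = simulate_rate_pool(cells, task, KinematicsModel(), seed=1)
ds = assemble_dataset(pool, "direction", task.conditions, task.directions,
                      40, seed=2)
net = train_network(ds, NetworkSpec(output_units=8, restarts=10), seed=3)
print(net.test_accuracy)          # -> 0.943
```

The tuning fit recovers the preferred direction (246°) and a field width of
114.6° (2/√k in degrees); a pure sinusoid has a half-width at half height of
exactly 90° and a fitted von Mises width of ≈117°.  The decoder reads
single-trial discharge intensities of 55 model cells and identifies the
movement direction on held-out trials 94% of the time (chance 12.5%).

`examples/` holds one short script per capability (simulation, movement
detection, tuning, timing, classification, decoding); each prints the
numbers it computes and a line on what they mean.  A thin CLI mirrors the
pipeline stages:

```bash
meq simulate --seed 1 --out session.jsonl
meq classify --session session.jsonl --out labels.csv
meq report --seed 1 --out report.json
```

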