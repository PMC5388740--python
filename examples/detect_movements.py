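"""Detect movement onsets from position traces and compare to ground truth.

Saccade onset is the first crossing of 20 deg/s of smoothed eye speed; hand
onset the first crossing of 1% of the trial's peak cursor speed.  On clean
synthetic traces both recover the generator's onsets to within a sample or
two.
"""

import numpy as np

from meq import (KinematicsModel, TaskConfig, detect_trial_movements,
                 generate_session, make_archetype)
from meq.utils import substream

cells = [make_archetype("invariant", "same", "same", "both",
                        substream(0, 1), "demo")]
trials = generate_session(TaskConfig(n_trials_per_condition=2, seed=3),
                          KinematicsModel(), cells, seed=3)

eye_err, hand_err, durations = [], [], {}
for trial in trials:
    det = detect_trial_movements(trial)
    gt = trial.ground_truth
    if det["eye"] and gt["saccade_onset"] is not None:
        eye_err.append(det["eye"].onset - gt["saccade_onset"])
        durations.setdefault(("eye", trial.target_amplitude), []).append(
            det["eye"].duration)
    if det["hand"] and gt["hand_onset"] is not None:
        hand_err.append(det["hand"].onset - gt["hand_onset"])

print(f"saccade onset error: mean {np.mean(np.abs(eye_err)):.2f} ms "
      f"over {len(eye_err)} movements (1 sample = 1 ms)")
print(f"hand onset error:    mean {np.mean(np.abs(hand_err)):.2f} ms "
      f"over {len(hand_err)} movements (1 sample = 1.5 ms)")
for (eff, amp), d in sorted(durations.items()):
    print(f"detected {eff} duration at {amp:.0f} deg: {np.mean(d):.0f} ms "
          "(calibrated: 45 ms at 10 deg, 58 ms at 20 deg)")
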