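"""Velocity estimation and movement-event detection from position traces.

Saccade onset is the first crossing of 20 deg/s; hand onset the first
crossing of 1% of the trial's peak speed (the conventional automatic rules
for the two effectors).  Speed is obtained by central differences followed
by a short moving average -- 7 samples for the 1000-Hz eye trace, 5 for the
666-Hz hand trace; results on clean traces are insensitive to +/-2 samples
of window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .utils import wrap_deg

SACCADE_THRESHOLD = 20.0     # deg/s
HAND_PEAK_FRACTION = 0.01    # fraction of per-trial max speed
HAND_OFFSET_FRACTION = 0.05  # offset: below this fraction of peak for >= 50 ms
EYE_SMOOTH_SAMPLES = 7
HAND_SMOOTH_SAMPLES = 5

#: sentinel for "no movement detected"
NO_MOVEMENT = None


@dataclass
class MovementEvent:
    """A detected movement of one effector."""

    effector: str          # 'eye' | 'hand'
    onset: float           # ms
    offset: float          # ms
    peak_velocity: float   # deg/s
    direction: float       # deg, [0, 360)
    amplitude: float       # deg

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def compute_speed(trace: np.ndarray, sample_rate: float,
                  smooth_samples: int | None = None) -> np.ndarray:
    """Smoothed speed (deg/s) of a 2D position trace.

    Central differences on each coordinate, then a boxcar moving average of
    `smooth_samples` on the speed.  Output has the same length as the input.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 2:
        raise ValueError("trace must be n x 2 (x, y in deg)")
    if len(trace) < 5:
        raise ValueError("trace too short for differentiation (need >= 5 samples)")
    if smooth_samples is None:
        smooth_samples = EYE_SMOOTH_SAMPLES if sample_rate >= 800 else HAND_SMOOTH_SAMPLES

    dt = 1.0 / sample_rate                       # seconds per sample
    vx = np.gradient(trace[:, 0], dt)
    vy = np.gradient(trace[:, 1], dt)
    speed = np.hypot(vx, vy)
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        # reflect-pad so the average is unbiased at the edges
        pad = smooth_samples // 2
        padded = np.pad(speed, pad, mode="edge")
        speed = np.convolve(padded, kernel, mode="same")[pad:len(padded) - pad]
        if smooth_samples % 2 == 0:
            speed = speed[:len(trace)]
    return speed


def _first_crossing(times, speed, threshold, t_start, t_stop):
    mask = (times >= t_start) & (times <= t_stop)
    idx = np.flatnonzero(mask & (speed >= threshold))
    if idx.size == 0:
        return None, None
    on = idx[0]
    below = np.flatnonzero((np.arange(len(speed)) > on) & (speed < threshold))
    off = below[0] if below.size else len(speed) - 1
    return on, off


def detect_saccade(times: np.ndarray, speed: np.ndarray, search_start: float,
                   search_stop: float | None = None,
                   threshold: float = SACCADE_THRESHOLD):
    """(onset, offset) ms of the first saccade after `search_start`, or
    ``(None, None)`` when speed never crosses the threshold."""
    times = np.asarray(times, dtype=float)
    if search_stop is None:
        search_stop = times[-1]
    on, off = _first_crossing(times, np.asarray(speed, dtype=float),
                              threshold, search_start, search_stop)
    if on is None:
        return NO_MOVEMENT, NO_MOVEMENT
    return float(times[on]), float(times[off])


def detect_saccade_onset(times, speed, search_start, search_stop=None):
    return detect_saccade(times, speed, search_start, search_stop)[0]


def detect_hand_movement(times: np.ndarray, speed: np.ndarray,
                         search_start: float, search_stop: float | None = None,
                         min_quiet_ms: float = 50.0):
    """(onset, offset) of a hand movement by the 1%-of-peak rule.

    The peak is taken within the search window; onset is the first crossing
    of 1% of it.  Offset is the first time speed falls below 5% of peak and
    stays there for at least `min_quiet_ms`.  Returns ``(None, None)`` for a
    trace with no movement (zero peak speed).
    """
    times = np.asarray(times, dtype=float)
    speed = np.asarray(speed, dtype=float)
    if search_stop is None:
        search_stop = times[-1]
    window = (times >= search_start) & (times <= search_stop)
    if not np.any(window):
        return NO_MOVEMENT, NO_MOVEMENT
    peak = speed[window].max()
    if peak <= 0:
        return NO_MOVEMENT, NO_MOVEMENT
    on, _ = _first_crossing(times, speed, HAND_PEAK_FRACTION * peak,
                            search_start, search_stop)
    if on is None:
        return NO_MOVEMENT, NO_MOVEMENT

    peak_idx = np.flatnonzero(window)[np.argmax(speed[window])]
    dt = float(np.median(np.diff(times)))
    need = max(1, int(round(min_quiet_ms / dt)))
    quiet = speed < HAND_OFFSET_FRACTION * peak
    off = None
    run = 0
    for i in range(peak_idx, len(speed)):
        run = run + 1 if quiet[i] else 0
        if run >= need:
            off = i - need + 1
            break
    if off is None:
        off = len(speed) - 1
    return float(times[on]), float(times[off])


def detect_hand_onset(times, speed, search_start, search_stop=None):
    return detect_hand_movement(times, speed, search_start, search_stop)[0]


def movement_vector(trace: np.ndarray, times: np.ndarray, onset: float,
                    offset: float):
    """(direction deg in [0, 360), amplitude deg) of the displacement between
    onset and offset.  Zero displacement yields ``(None, 0.0)``."""
    if onset is None or offset is None or offset <= onset:
        raise ValueError("onset/offset must be valid with offset > onset")
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    p0 = np.array([np.interp(onset, times, trace[:, 0]),
                   np.interp(onset, times, trace[:, 1])])
    p1 = np.array([np.interp(offset, times, trace[:, 0]),
                   np.interp(offset, times, trace[:, 1])])
    d = p1 - p0
    amp = float(np.hypot(*d))
    if amp == 0.0:
        return None, 0.0
    return float(wrap_deg(np.rad2deg(np.arctan2(d[1], d[0])))), amp


def detect_trial_movements(trial, deadline_pad: float = 0.0) -> dict:
    """Detect the eye and hand movements of one TrialRecord.

    Returns ``{'eye': MovementEvent | None, 'hand': MovementEvent | None}``.
    The search starts at the go cue (earlier movements abort a trial under
    the task rules).
    """
    out = {"eye": None, "hand": None}
    go = trial.go_cue
    if trial.eye_trace is not None:
        t = trial.eye_times()
        sp = compute_speed(trial.eye_trace, trial.eye_sample_rate)
        on, off = detect_saccade(t, sp, go)
        if on is not None:
            direction, amp = movement_vector(trial.eye_trace, t, on, off)
            out["eye"] = MovementEvent("eye", on, off, float(sp.max()),
                                       direction if direction is not None else np.nan,
                                       amp)
    if trial.hand_trace is not None:
        t = trial.hand_times()
        sp = compute_speed(trial.hand_trace, trial.hand_sample_rate)
        on, off = detect_hand_movement(t, sp, go)
        if on is not None:
            direction, amp = movement_vector(trial.hand_trace, t, on, off)
            out["hand"] = MovementEvent("hand", on, off, float(sp.max()),
                                        direction if direction is not None else np.nan,
                                        amp)
    return out
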