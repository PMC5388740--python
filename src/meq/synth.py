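"""Synthetic sessions of the center-out eye/hand task with model Meq cells.

The generator emulates a trial-structured primate experiment: a subject
fixates, is instructed which effector to use (eye, hand, or both), and on a
go cue moves to one of 8 targets at 10 or 20 deg eccentricity.  Eye position
is sampled at 1000 Hz, the joystick-driven hand cursor at 666 Hz.  Spike
trains of parameterized cell archetypes are drawn from an inhomogeneous
Poisson process whose envelope carries the archetype's directional tuning,
burst duration and discharge lead time, so every downstream estimator has
exact ground truth to recover.

Reaction times follow a shared-command model: a latent central command time
C is drawn per trial and each effector's onset is C plus independent noise,
with the command-effector correlation configurable (default 0.7).  This
makes the eye-hand onset correlation converge to rho^2 (~0.49), the regime
discussed for coordinated eye-hand movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .utils import circ_abs_dist_deg, circ_dist_deg, substream, unit_vector_deg, wrap_deg

DEFAULT_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))
MAIN_CONDITIONS = ("eye", "hand", "eye-hand")

#: velocity threshold defining saccade onset, deg/s
SACCADE_VEL_THRESHOLD = 20.0
#: hand onset threshold as a fraction of peak speed
HAND_VEL_FRACTION = 0.01


class ConfigurationError(ValueError):
    """Raised when a task/kinematics configuration is invalid."""


@dataclass
class TaskConfig:
    """Layout of the center-out task and its sampling rates."""

    n_trials_per_condition: int = 10          # per condition x direction x amplitude
    directions: Sequence[float] = DEFAULT_DIRECTIONS
    amplitudes: Sequence[float] = (10.0, 20.0)
    fixation_ms: tuple[float, float] = (200.0, 300.0)
    instruction_ms: tuple[float, float] = (200.0, 300.0)
    delay_ms: tuple[float, float] = (300.0, 1200.0)
    window_deg: float = 1.5                   # square fixation/target window, side
    eye_sample_rate: float = 1000.0
    hand_sample_rate: float = 666.0
    eye_deadline_ms: float = 600.0
    hand_deadline_ms: float = 1200.0
    conditions: Sequence[str] = MAIN_CONDITIONS
    seed: int = 0

    def __post_init__(self):
        if len(self.directions) == 0:
            raise ConfigurationError("directions must be non-empty")
        if any((d < 0.0) or (d >= 360.0) for d in self.directions):
            raise ConfigurationError("directions must lie in [0, 360)")
        for name in ("fixation_ms", "instruction_ms", "delay_ms"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigurationError(f"{name} must be a positive range")
        if self.eye_sample_rate <= 0 or self.hand_sample_rate <= 0:
            raise ConfigurationError("sample rates must be positive")
        if self.n_trials_per_condition < 1:
            raise ConfigurationError("n_trials_per_condition must be >= 1")


def _linear_law(slope: float, intercept: float) -> Callable[[float], float]:
    return lambda amp: slope * amp + intercept


@dataclass
class KinematicsModel:
    """Movement-duration laws and the shared-command reaction-time model.

    Duration laws give the *detected* movement duration (threshold-crossing
    to threshold-crossing) as a function of amplitude; the underlying
    velocity-profile support is solved from them at generation time.
    Defaults calibrate saccades to 45 ms at 10 deg / 58 ms at 20 deg and
    hand movements to 198 / 257 ms.
    """

    saccade_duration_law: Callable[[float], float] = field(
        default_factory=lambda: _linear_law(1.3, 32.0))
    hand_duration_law: Callable[[float], float] = field(
        default_factory=lambda: _linear_law(5.9, 139.0))
    eye_hand_interval_mean: float = 81.0      # hand onset - saccade onset, ms
    eye_hand_interval_sd: float = 33.0
    command_correlation: float = 0.7          # corr(command, each effector onset)
    eye_rt_mean: float = 200.0                # saccade reaction time from go cue, ms
    position_noise_sd: float = 0.0            # deg, additive white noise on traces

    def __post_init__(self):
        if not (0.0 < self.command_correlation < 1.0):
            raise ConfigurationError("command_correlation must be in (0, 1)")
        if self.eye_hand_interval_sd <= 0:
            raise ConfigurationError("eye_hand_interval_sd must be positive")

    @property
    def effector_noise_sd(self) -> float:
        """SD of each effector's private onset noise, from the interval SD."""
        return self.eye_hand_interval_sd / np.sqrt(2.0)

    @property
    def command_sd(self) -> float:
        """SD of the shared command time implied by the configured correlation."""
        rho = self.command_correlation
        return self.effector_noise_sd * rho / np.sqrt(1.0 - rho * rho)

    def draw_reaction_times(self, rng: np.random.Generator):
        """Return (command, eye_rt, hand_rt) in ms from the go cue."""
        c = self.eye_rt_mean + self.command_sd * rng.standard_normal()
        eye = c + self.effector_noise_sd * rng.standard_normal()
        hand = c + self.eye_hand_interval_mean + self.effector_noise_sd * rng.standard_normal()
        return c, max(60.0, eye), max(60.0, hand)


# ---------------------------------------------------------------------------
# velocity profiles
# ---------------------------------------------------------------------------

_MINJERK_TAU1 = (1.0 - np.sqrt(1.0 - 4.0 * np.sqrt(HAND_VEL_FRACTION) / 4.0)) / 2.0
# fraction of the minimum-jerk support lying above 1% of peak speed
_MINJERK_DETECTED_FRACTION = 1.0 - 2.0 * _MINJERK_TAU1


def minimum_jerk_position(tau):
    """Normalized minimum-jerk displacement, 0 at tau=0 to 1 at tau=1."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def raised_cosine_position(tau):
    """Normalized raised-cosine-velocity displacement (symmetric bell speed)."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


def _saccade_support_ms(amplitude: float, detected_ms: float,
                        threshold: float = SACCADE_VEL_THRESHOLD) -> float:
    """Support D of the raised-cosine speed bell whose time above `threshold`
    equals `detected_ms`.  Peak speed is 2000*A/D deg/s."""

    def detected(d):
        vp = 2000.0 * amplitude / d
        if vp <= 2.0 * threshold:
            return -detected_ms
        t1 = d / (2.0 * np.pi) * np.arccos(1.0 - 2.0 * threshold / vp)
        return d - 2.0 * t1 - detected_ms

    return brentq(detected, detected_ms, 10.0 * detected_ms)


def _hand_support_ms(detected_ms: float) -> float:
    """Support of the minimum-jerk profile given the 1%-of-peak detected span."""
    return detected_ms / _MINJERK_DETECTED_FRACTION


def _threshold_crossing_offsets(effector: str, amplitude: float, support: float):
    """(t_on, t_off) of the detection threshold within the profile support."""
    if effector == "eye":
        vp = 2000.0 * amplitude / support
        t1 = support / (2.0 * np.pi) * np.arccos(1.0 - 2.0 * SACCADE_VEL_THRESHOLD / vp)
        return t1, support - t1
    t1 = _MINJERK_TAU1 * support
    return t1, support - t1


def generate_trajectory(effector: str, direction: float, amplitude: float,
                        kin: KinematicsModel, *, sample_rate: float | None = None,
                        movement_start: float = 300.0, total_ms: float | None = None,
                        rng: np.random.Generator | None = None):
    """Position trace (times ms, n-by-2 deg) of one movement.

    The profile starts at `movement_start`; the trace holds at the origin
    before it and at the target after.  `amplitude == 0` yields a stationary
    trace.  Returns ``(times, xy, info)`` where ``info`` carries the analytic
    onset/offset (threshold-crossing times) and the profile support.
    """
    if effector not in ("eye", "hand"):
        raise ConfigurationError(f"unknown effector {effector!r}")
    if amplitude < 0:
        raise ConfigurationError("amplitude must be >= 0")
    if sample_rate is None:
        sample_rate = 1000.0 if effector == "eye" else 666.0

    if amplitude > 0:
        if effector == "eye":
            support = _saccade_support_ms(amplitude, kin.saccade_duration_law(amplitude))
            profile = raised_cosine_position
        else:
            support = _hand_support_ms(kin.hand_duration_law(amplitude))
            profile = minimum_jerk_position
        t_on, t_off = _threshold_crossing_offsets(effector, amplitude, support)
        info = {"onset": movement_start + t_on, "offset": movement_start + t_off,
                "support": support, "profile_start": movement_start}
    else:
        support = 0.0
        profile = None
        info = {"onset": None, "offset": None, "support": 0.0,
                "profile_start": movement_start}

    if total_ms is None:
        total_ms = movement_start + support + 400.0
    n = int(np.floor(total_ms * sample_rate / 1000.0)) + 1
    times = np.arange(n) * (1000.0 / sample_rate)
    xy = np.zeros((n, 2))
    if amplitude > 0:
        tau = (times - movement_start) / support
        disp = amplitude * profile(tau)
        xy += np.outer(disp, unit_vector_deg(direction))
    if rng is not None and kin.position_noise_sd > 0:
        xy += kin.position_noise_sd * rng.standard_normal(xy.shape)
    return times, xy, info


# ---------------------------------------------------------------------------
# cell archetypes
# ---------------------------------------------------------------------------

def width_to_kappa(width_deg: float) -> float:
    """Invert the field-width measure 2/sqrt(k) (in degrees) to concentration k."""
    w = np.deg2rad(width_deg)
    return (2.0 / w) ** 2


@dataclass
class CellArchetype:
    """Parameter set of one model Meq cell.

    Preferred directions and peak rates are given per effector condition so
    that invariant, eye-preferring, hand-preferring, intermediate and mixed
    (dynamically drifting) field configurations can all be expressed.
    """

    pd_eye: float = 90.0
    pd_hand: float = 90.0
    pd_eyehand: float = 90.0
    width_eye: float = 160.0
    width_hand: float = 160.0
    peak_rate_eye: float = 90.0
    peak_rate_hand: float = 90.0
    peak_rate_eyehand: float = 90.0
    baseline_rate: float = 10.0
    burst_duration_eye: float = 120.0
    burst_duration_hand: float = 320.0
    burst_duration_eyehand_rule: str | float = "eye-like"
    lead_eye: float = 70.0
    lead_hand: float = 152.0
    onset_lock: str = "both"                  # {'eye', 'hand', 'both'}
    onset_jitter_sd: float = 12.0             # ms, around the locked event
    mixed_field_transition: tuple[float, float] | None = None
    # when set, pd drifts pd_eye -> pd_hand over this window re saccade onset
    response_mode: str = "movement"           # 'movement' | 'visual' | 'none'
    cell_id: str | None = None

    def __post_init__(self):
        for name in ("peak_rate_eye", "peak_rate_hand", "peak_rate_eyehand",
                     "baseline_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("width_eye", "width_hand"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.onset_lock not in ("eye", "hand", "both"):
            raise ConfigurationError("onset_lock must be 'eye', 'hand' or 'both'")

    def burst_duration_eyehand(self, direction: float) -> float:
        rule = self.burst_duration_eyehand_rule
        if isinstance(rule, (int, float)):
            return float(rule)
        if rule == "eye-like":
            return self.burst_duration_eye
        if rule == "hand-like":
            return self.burst_duration_hand
        if rule == "intermediate":
            return 0.5 * (self.burst_duration_eye + self.burst_duration_hand)
        if rule == "mixed":
            # short in eye-preferred directions, long in hand-preferred ones
            if circ_abs_dist_deg(direction, self.pd_eye) <= circ_abs_dist_deg(
                    direction, self.pd_hand):
                return self.burst_duration_eye
            return self.burst_duration_hand
        raise ConfigurationError(f"unknown burst rule {rule!r}")

    def true_labels(self) -> dict:
        """Ground-truth effector-preference labels implied by the parameters."""
        d_eh = circ_abs_dist_deg(self.pd_eye, self.pd_hand)
        if self.mixed_field_transition is not None:
            on = "mixed"
        elif d_eh < 30.0:
            on = "invariant"
        elif circ_abs_dist_deg(self.pd_eyehand, self.pd_eye) < 30.0:
            on = "eye"
        elif circ_abs_dist_deg(self.pd_eyehand, self.pd_hand) < 30.0:
            on = "hand"
        else:
            on = "intermediate"

        re_, rh, reh = self.peak_rate_eye, self.peak_rate_hand, self.peak_rate_eyehand
        if abs(re_ - rh) <= 0.15 * max(re_, rh):
            intensity = "same"
        elif abs(reh - re_) <= 0.15 * max(reh, re_):
            intensity = "eye"
        elif abs(reh - rh) <= 0.15 * max(reh, rh):
            intensity = "hand"
        else:
            intensity = "intermediate"

        de, dh = self.burst_duration_eye, self.burst_duration_hand
        rule = self.burst_duration_eyehand_rule
        if abs(de - dh) <= 0.2 * max(de, dh):
            duration = "same"
        elif rule == "mixed":
            duration = "mixed"
        elif rule == "eye-like":
            duration = "eye"
        elif rule == "hand-like":
            duration = "hand"
        else:
            duration = "intermediate"

        return {"on_direction": on, "intensity": intensity,
                "duration": duration, "onset": self.onset_lock}


# ---------------------------------------------------------------------------
# trials
# ---------------------------------------------------------------------------

@dataclass
class TrialRecord:
    """One trial: events, behavioral traces, spikes and generator truth."""

    trial_id: int
    condition: str                            # eye | hand | eye-hand | memory-saccade | fixation
    target_direction: float
    target_amplitude: float
    event_times: dict                         # fixation_on, instruction, target_on, go, end
    eye_sample_rate: float = 1000.0
    hand_sample_rate: float = 666.0
    eye_trace: np.ndarray | None = None       # n x 2, deg
    hand_trace: np.ndarray | None = None
    spike_times: list = field(default_factory=list)   # one array per cell
    ground_truth: dict = field(default_factory=dict)

    @property
    def go_cue(self) -> float:
        return self.event_times["go"]

    @property
    def end(self) -> float:
        return self.event_times["end"]

    def eye_times(self) -> np.ndarray:
        return np.arange(len(self.eye_trace)) * (1000.0 / self.eye_sample_rate)

    def hand_times(self) -> np.ndarray:
        return np.arange(len(self.hand_trace)) * (1000.0 / self.hand_sample_rate)


def _vm_gain(direction, pd, kappa):
    """Direction gain in [exp(-2k), 1], equal to 1 at the preferred direction."""
    return np.exp(kappa * (np.cos(np.deg2rad(direction - pd)) - 1.0))


def _burst_onset(cell: CellArchetype, trial: TrialRecord, rng: np.random.Generator):
    """Discharge (burst) onset time implied by the cell's locking rule.

    A cell whose onset is not locked to the executed effector still bursts
    ahead of the movement on average: its burst is centered so the expected
    lead relative to the executed effector matches the configured lead, but
    trial-to-trial it tracks only the go cue (or the shared command for
    'both'-locked cells), not the movement's own jitter.
    """
    gt = trial.ground_truth
    jit = cell.onset_jitter_sd * rng.standard_normal()
    if cell.response_mode == "none":
        return None
    if cell.response_mode == "visual":
        tgt = trial.event_times.get("target_on")
        return None if tgt is None else tgt + 60.0 + jit
    cond = trial.condition
    sacc, hand = gt.get("saccade_onset"), gt.get("hand_onset")
    go = trial.go_cue
    exp_eye = gt.get("expected_eye_rt", 200.0)
    exp_hand = gt.get("expected_hand_rt", 281.0)
    if cond in ("eye", "memory-saccade"):
        if sacc is None:
            return None
        if cell.onset_lock == "hand":
            return go + exp_eye - cell.lead_eye + jit
        if cell.onset_lock == "both":
            return go + gt["command_rt"] - cell.lead_eye + jit
        return sacc - cell.lead_eye + jit
    if cond == "hand":
        if hand is None:
            return None
        if cell.onset_lock == "eye":
            return go + exp_hand - cell.lead_hand + jit
        if cell.onset_lock == "both":
            return go + gt["command_rt"] + (exp_hand - exp_eye) - cell.lead_hand + jit
        return hand - cell.lead_hand + jit
    if cond == "eye-hand":
        if sacc is None or hand is None:
            return None
        if cell.onset_lock == "eye":
            return sacc - cell.lead_eye + jit
        if cell.onset_lock == "hand":
            return hand - cell.lead_hand + jit
        return go + gt["command_rt"] - cell.lead_eye + jit
    return None      # fixation trials: no movement-related burst


def discharge_envelope(cell: CellArchetype, trial: TrialRecord,
                       burst_onset: float | None):
    """Rate envelope lambda(t) (spikes/s) and its maximum for thinning."""
    cond = trial.condition
    direction = trial.target_direction
    if cell.response_mode == "visual" and burst_onset is not None:
        gain = cell.peak_rate_eye * _vm_gain(direction, cell.pd_eye,
                                             width_to_kappa(cell.width_eye))

        def rate(t):
            t = np.asarray(t, dtype=float)
            in_burst = (t >= burst_onset) & (t < burst_onset + 150.0)
            return cell.baseline_rate + gain * in_burst
        return rate, cell.baseline_rate + cell.peak_rate_eye
    if burst_onset is None or cond == "fixation" or trial.target_amplitude == 0:
        lam_max = max(cell.baseline_rate, 1e-9)
        return (lambda t: np.full(np.shape(t), cell.baseline_rate, dtype=float),
                lam_max)

    if cond in ("eye", "memory-saccade"):
        peak, pd, kappa = (cell.peak_rate_eye, cell.pd_eye,
                           width_to_kappa(cell.width_eye))
        dur = cell.burst_duration_eye
    elif cond == "hand":
        peak, pd, kappa = (cell.peak_rate_hand, cell.pd_hand,
                           width_to_kappa(cell.width_hand))
        dur = cell.burst_duration_hand
    else:
        peak = cell.peak_rate_eyehand
        pd = cell.pd_eyehand
        kappa = width_to_kappa(0.5 * (cell.width_eye + cell.width_hand))
        dur = cell.burst_duration_eyehand(direction)

    drift = cell.mixed_field_transition if cond == "eye-hand" else None
    sacc = trial.ground_truth.get("saccade_onset")

    if drift is None:
        gain = peak * _vm_gain(direction, pd, kappa)

        def rate(t):
            t = np.asarray(t, dtype=float)
            in_burst = (t >= burst_onset) & (t < burst_onset + dur)
            return cell.baseline_rate + gain * in_burst
    else:
        t0, t1 = (sacc + drift[0], sacc + drift[1])

        def rate(t):
            t = np.asarray(t, dtype=float)
            frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
            pd_t = cell.pd_eye + frac * circ_dist_deg(cell.pd_hand, cell.pd_eye)
            in_burst = (t >= burst_onset) & (t < burst_onset + dur)
            return cell.baseline_rate + peak * _vm_gain(direction, pd_t, kappa) * in_burst

    return rate, cell.baseline_rate + peak


def generate_spikes(cell: CellArchetype, trial: TrialRecord,
                    rng: np.random.Generator | int, record_truth: bool = True
                    ) -> np.ndarray:
    """Spike times (ms) of `cell` on `trial` via Poisson thinning.

    The burst-onset jitter draw precedes the thinning draws, so the same RNG
    stream always yields the same (onset, spikes) pair.  When
    ``record_truth`` is set, the realized burst onset is appended to
    ``trial.ground_truth['discharge_onset']``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t_on = _burst_onset(cell, trial, rng)
    rate, lam_max = discharge_envelope(cell, trial, t_on)
    total = trial.end
    n_cand = rng.poisson(lam_max * total / 1000.0)
    cand = np.sort(rng.uniform(0.0, total, n_cand))
    keep = rng.uniform(0.0, lam_max, n_cand) < rate(cand)
    spikes = cand[keep]
    if record_truth:
        trial.ground_truth.setdefault("discharge_onset", []).append(t_on)
    return spikes


def generate_session(task: TaskConfig, kin: KinematicsModel,
                     cells: Sequence[CellArchetype], seed: int | None = None,
                     include_traces: bool = True) -> list[TrialRecord]:
    """Full session: every condition x direction x amplitude combination,
    `task.n_trials_per_condition` trials each, with ground truth recorded.

    Each trial draws from its own RNG stream keyed by (seed, trial_id), and
    each cell's spikes from (seed, trial_id, cell index), so any trial can be
    regenerated independently and regeneration is bit-identical.
    """
    if len(cells) == 0:
        raise ConfigurationError("at least one cell archetype is required")
    if seed is None:
        seed = task.seed

    trials: list[TrialRecord] = []
    trial_id = 0
    for condition in task.conditions:
        for direction in task.directions:
            for amplitude in task.amplitudes:
                for _ in range(task.n_trials_per_condition):
                    trial = _generate_trial(trial_id, condition, float(direction),
                                            float(amplitude), task, kin,
                                            include_traces)
                    for ci, cell in enumerate(cells):
                        rng = substream(seed, trial_id, ci)
                        trial.spike_times.append(
                            generate_spikes(cell, trial, rng))
                    trials.append(trial)
                    trial_id += 1
    return trials


def _generate_trial(trial_id: int, condition: str, direction: float,
                    amplitude: float, task: TaskConfig, kin: KinematicsModel,
                    include_traces: bool) -> TrialRecord:
    rng = substream(task.seed, trial_id)
    fix = 0.0
    instr = fix + rng.uniform(*task.fixation_ms)
    target_on = instr + rng.uniform(*task.instruction_ms)
    go = target_on + rng.uniform(*task.delay_ms)

    command, eye_rt, hand_rt = kin.draw_reaction_times(rng)
    gt: dict = {"command_rt": command, "saccade_onset": None, "hand_onset": None,
                "saccade_offset": None, "hand_offset": None,
                "expected_eye_rt": kin.eye_rt_mean,
                "expected_hand_rt": kin.eye_rt_mean + kin.eye_hand_interval_mean,
                "discharge_onset": []}

    move_eye = condition in ("eye", "eye-hand", "memory-saccade") and amplitude > 0
    move_hand = condition in ("hand", "eye-hand") and amplitude > 0

    end = go + 600.0
    eye_info = hand_info = None
    if move_eye:
        sacc_support = _saccade_support_ms(amplitude, kin.saccade_duration_law(amplitude))
        t_on, t_off = _threshold_crossing_offsets("eye", amplitude, sacc_support)
        eye_start = go + eye_rt - t_on          # profile start so onset = go + RT
        eye_info = (eye_start, sacc_support)
        gt["saccade_onset"] = eye_start + t_on
        gt["saccade_offset"] = eye_start + t_off
        end = max(end, eye_start + sacc_support + 400.0)
    if move_hand:
        hand_support = _hand_support_ms(kin.hand_duration_law(amplitude))
        t_on, t_off = _threshold_crossing_offsets("hand", amplitude, hand_support)
        hand_start = go + hand_rt - t_on
        hand_info = (hand_start, hand_support)
        gt["hand_onset"] = hand_start + t_on
        gt["hand_offset"] = hand_start + t_off
        end = max(end, hand_start + hand_support + 400.0)

    trial = TrialRecord(trial_id=trial_id, condition=condition,
                        target_direction=direction, target_amplitude=amplitude,
                        event_times={"fixation_on": fix, "instruction": instr,
                                     "target_on": target_on, "go": go, "end": end},
                        eye_sample_rate=task.eye_sample_rate,
                        hand_sample_rate=task.hand_sample_rate,
                        ground_truth=gt)

    if include_traces:
        trial.eye_trace = _trace(task.eye_sample_rate, end, eye_info, direction,
                                 amplitude, raised_cosine_position, kin, rng)
        trial.hand_trace = _trace(task.hand_sample_rate, end, hand_info, direction,
                                  amplitude, minimum_jerk_position, kin, rng)
    return trial


def _trace(rate_hz, end, info, direction, amplitude, profile, kin, rng):
    n = int(np.floor(end * rate_hz / 1000.0)) + 1
    times = np.arange(n) * (1000.0 / rate_hz)
    xy = np.zeros((n, 2))
    if info is not None:
        start, support = info
        tau = (times - start) / support
        xy += np.outer(amplitude * profile(tau), unit_vector_deg(direction))
    if kin.position_noise_sd > 0:
        xy += kin.position_noise_sd * rng.standard_normal(xy.shape)
    return xy


# ---------------------------------------------------------------------------
# population factory
# ---------------------------------------------------------------------------

#: per-column category composition of the reference 55-cell population
REFERENCE_COMPOSITION = {
    "on_direction": {"invariant": 27, "eye": 10, "hand": 8,
                     "intermediate": 6, "mixed": 4},
    "onset": {"both": 36, "eye": 15, "hand": 4},
}


def make_archetype(label_on: str, label_intensity: str, label_duration: str,
                   label_onset: str, rng: np.random.Generator,
                   cell_id: str | None = None) -> CellArchetype:
    """One archetype whose parameters realize the requested label tuple."""
    pd_eye = rng.uniform(0.0, 360.0)
    sep = rng.uniform(120.0, 180.0) * rng.choice([-1.0, 1.0])
    mixed_transition = None
    if label_on == "invariant":
        pd_hand = pd_eye
        pd_eyehand = pd_eye
    elif label_on == "eye":
        pd_hand = wrap_deg(pd_eye + sep)
        pd_eyehand = pd_eye
    elif label_on == "hand":
        pd_hand = wrap_deg(pd_eye + sep)
        pd_eyehand = pd_hand
    elif label_on == "intermediate":
        pd_hand = wrap_deg(pd_eye + sep)
        pd_eyehand = wrap_deg(pd_eye + sep / 2.0)
    elif label_on == "mixed":
        pd_hand = wrap_deg(pd_eye + sep)
        pd_eyehand = pd_eye
        mixed_transition = (-30.0, 120.0)
    else:
        raise ConfigurationError(f"unknown on-direction label {label_on!r}")

    base_rate = rng.uniform(60.0, 130.0)
    if label_intensity == "same":
        re_ = rh = reh = base_rate
    elif label_intensity == "eye":
        re_ = base_rate
        rh = base_rate / 2.4
        reh = re_
    elif label_intensity == "hand":
        rh = base_rate
        re_ = base_rate / 2.4
        reh = rh
    else:
        re_ = base_rate
        rh = base_rate / 2.4
        reh = 0.5 * (re_ + rh)

    short, long_ = 120.0, 340.0
    if label_duration == "same":
        de = dh = rng.uniform(200.0, 280.0)
        rule: str | float = "eye-like"
    elif label_duration == "eye":
        de, dh, rule = short, long_, "eye-like"
    elif label_duration == "hand":
        de, dh, rule = short, long_, "hand-like"
    elif label_duration == "intermediate":
        de, dh, rule = short, long_, "intermediate"
    elif label_duration == "mixed":
        de, dh, rule = short, long_, "mixed"
    else:
        raise ConfigurationError(f"unknown duration label {label_duration!r}")

    width = float(np.clip(rng.normal(160.0, 30.0), 100.0, 240.0))
    return CellArchetype(
        pd_eye=pd_eye, pd_hand=pd_hand, pd_eyehand=pd_eyehand,
        width_eye=width, width_hand=float(np.clip(rng.normal(162.0, 30.0), 100.0, 240.0)),
        peak_rate_eye=re_, peak_rate_hand=rh, peak_rate_eyehand=reh,
        baseline_rate=rng.uniform(5.0, 15.0),
        burst_duration_eye=de, burst_duration_hand=dh,
        burst_duration_eyehand_rule=rule,
        lead_eye=70.0, lead_hand=152.0, onset_lock=label_onset,
        onset_jitter_sd=12.0, mixed_field_transition=mixed_transition,
        cell_id=cell_id)


def make_reference_population(seed: int = 0, n_cells: int = 55
                           ) -> list[CellArchetype]:
    """A population mirroring the packaged 55-cell reference classification
    table row by row: each synthetic cell realizes the printed label tuple
    (on-direction, intensity, duration, onset lock) with randomized preferred
    directions, widths and peak rates in the reported 18-166 spikes/s range.

    Two printed label combinations cannot be realized literally and are
    mapped to their nearest realizable archetype: a direction-dependent
    ('mixed') burst duration requires distinct eye/hand preferred directions,
    so mixed duration on an on-direction-invariant cell becomes 'eye'
    (short) duration; an 'invariant' duration entry maps to 'same'.
    """
    from .io import load_reference_table

    rng = substream(seed, 9155)
    table = load_reference_table()
    cells = []
    for i in range(n_cells):
        row = table.iloc[i % len(table)]
        on = row["on_direction"].lower()
        intensity = row["intensity"].lower()
        duration = row["duration"].lower()
        onset = row["onset"].lower()
        if duration == "invariant":
            duration = "same"
        if duration == "mixed" and on in ("invariant",):
            duration = "eye"
        cells.append(make_archetype(on, intensity, duration, onset, rng,
                                    cell_id=f"S{i:03d}_{row['cell_id']}"))
    return cells


def simulate_rate_pool(cells: Sequence[CellArchetype], task: TaskConfig,
                       kin: KinematicsModel, seed: int = 0,
                       epoch: str = "steady-state") -> np.ndarray:
    """Per-trial discharge-intensity pool for the decoder.

    Returns an array of shape (n_cells, n_conditions, n_directions, n_trials)
    of baseline-subtracted rates (spikes/s) from freshly generated spike
    trains (traces are skipped; the generator's movement onsets anchor the
    windows).  Conditions are ordered as in ``task.conditions``; amplitudes
    are collapsed into the trial axis.

    ``epoch`` selects the input definition.  The default ``'steady-state'``
    is the average intensity over the cell's movement-related discharge: for
    each (cell, condition, direction) stratum the half-width window of the
    median-aligned rate is found once, and each trial contributes its count
    rate in that window.  ``'me'`` instead uses the brief movement-epoch
    windows (hand [-60, +20] ms, saccade [-30, +30] ms), which carry far
    more counting noise.
    """
    from .spiketrain import (HAND_ME, SACCADE_ME, epoch_mean_rate, half_width,
                             instantaneous_rate, median_aligned_rate)

    if epoch not in ("steady-state", "me"):
        raise ConfigurationError("epoch must be 'steady-state' or 'me'")
    trials = generate_session(task, kin, cells, seed=seed, include_traces=False)
    n_dir = len(task.directions)
    n_cond = len(task.conditions)
    n_rep = task.n_trials_per_condition * len(task.amplitudes)
    dir_index = {float(d): i for i, d in enumerate(task.directions)}
    cond_index = {c: i for i, c in enumerate(task.conditions)}
    pool = np.full((len(cells), n_cond, n_dir, n_rep), np.nan)

    # bucket trials per stratum
    strata: dict[tuple[int, int], list[TrialRecord]] = {}
    for trial in trials:
        key = (cond_index[trial.condition], dir_index[trial.target_direction])
        strata.setdefault(key, []).append(trial)

    for (ci, di), bucket in strata.items():
        cond = task.conditions[ci]
        anchors = []
        for trial in bucket:
            gt = trial.ground_truth
            anchors.append(gt["hand_onset"] if cond == "hand"
                           else gt["saccade_onset"])
        usable = [i for i, a in enumerate(anchors) if a is not None]
        if not usable:
            continue
        me_win = HAND_ME if cond == "hand" else SACCADE_ME
        for n in range(len(cells)):
            bases = np.array([
                np.sum((bucket[i].spike_times[n] >= bucket[i].go_cue - 300.0)
                       & (bucket[i].spike_times[n] < bucket[i].go_cue)) / 0.3
                for i in usable])
            window = me_win
            if epoch == "steady-state":
                fns = [instantaneous_rate(bucket[i].spike_times[n])
                       for i in usable]
                grid, med = median_aligned_rate(
                    fns, np.array([anchors[i] for i in usable]), -400.0, 600.0)
                burst = half_width(grid, np.nan_to_num(med, nan=0.0),
                                   float(np.median(bases)))
                if burst is not None and burst.half_width >= 40.0:
                    window = (burst.onset, burst.offset)
            for k, i in enumerate(usable):
                pool[n, ci, di, k] = epoch_mean_rate(
                    bucket[i].spike_times[n],
                    (anchors[i] + window[0], anchors[i] + window[1]), bases[k])
    return pool


def archetype_to_dict(cell: CellArchetype) -> dict:
    d = asdict(cell)
    if d["mixed_field_transition"] is not None:
        d["mixed_field_transition"] = list(d["mixed_field_transition"])
    return d
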