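"""Per-cell analysis pipeline: from raw trials to the measurements that the
classification, timing and decoding stages consume.

For one cell this computes, per effector condition: per-trial baseline and
movement-epoch rates, the directional tuning fit, per-trial discharge
onsets (2-SD rule on the normalized instantaneous rate, refined to the
first burst spike) and per-target burst half-widths from median-aligned
rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinematics as kin_mod
from . import spiketrain as st
from .spiketrain import HAND_ME, SACCADE_ME, REFERENCE_MS
from .tuning import TuningFit, fit_von_mises
from .utils import circ_abs_dist_deg

MAIN_CONDITIONS = ("eye", "hand", "eye-hand")


@dataclass
class ConditionData:
    """Vectorized per-trial measurements of one cell in one condition."""

    direction: np.ndarray
    amplitude: np.ndarray
    go: np.ndarray
    saccade_onset: np.ndarray      # NaN where absent
    hand_onset: np.ndarray
    baseline_rate: np.ndarray      # count-based, reference window, spikes/s
    me_rate_sacc: np.ndarray       # baseline-subtracted, NaN where undefined
    me_rate_hand: np.ndarray
    discharge_onset: np.ndarray    # NaN where not computed / not found
    onset_refined: np.ndarray | None = None   # True where spike-level refined
    half_width: np.ndarray | None = None      # per-trial, ms; NaN where not computed
    spikes: list = field(default_factory=list)
    rate_fns: list = field(default_factory=list)

    def __len__(self):
        return len(self.direction)


@dataclass
class CellAnalysis:
    """Everything the classifiers need to know about one cell."""

    cell_index: int
    conditions: dict               # condition -> ConditionData
    fits: dict                     # condition -> TuningFit or None
    pooled_baseline_sd: float
    visual_response_p: float       # t-test p of post-target vs baseline rate
    target_half_widths: dict = field(default_factory=dict)
    # condition -> (directions, amplitudes, half-widths) per retained target

    def pd(self, condition: str):
        f = self.fits.get(condition)
        return None if f is None or f.untuned else f.mu_pd

    def on_direction_mask(self, condition: str, window: float = 45.0):
        """Trials whose target lies within `window` deg of the condition pd."""
        pd = self.pd(condition)
        cd = self.conditions[condition]
        if pd is None:
            return np.zeros(len(cd), dtype=bool)
        return circ_abs_dist_deg(cd.direction, pd) <= window

    def primary_me(self, condition: str) -> np.ndarray:
        """The effector-appropriate ME rate: hand window in hand trials,
        saccade window otherwise."""
        cd = self.conditions[condition]
        return cd.me_rate_hand if condition == "hand" else cd.me_rate_sacc


def movement_onsets(trials, prefer_ground_truth: bool = False) -> dict:
    """Per-trial movement onsets, {trial_id: (saccade_onset, hand_onset)}.

    Onsets are detected from the traces; ``prefer_ground_truth`` (or absent
    traces) falls back to the generator's recorded truth, which is how the
    trace-free fast path used for large simulated populations runs.
    """
    out = {}
    for trial in trials:
        gt = trial.ground_truth or {}
        if prefer_ground_truth or trial.eye_trace is None:
            out[trial.trial_id] = (gt.get("saccade_onset"), gt.get("hand_onset"))
            continue
        det = kin_mod.detect_trial_movements(trial)
        sacc = det["eye"].onset if det["eye"] is not None else None
        hand = det["hand"].onset if det["hand"] is not None else None
        out[trial.trial_id] = (sacc, hand)
    return out


def _trial_rates(spikes, go, sacc_on, hand_on):
    """Baseline and movement-epoch rates for one trial."""
    ref = (go - REFERENCE_MS, go)
    base = st.count_rate(spikes, ref)
    me_s = me_h = np.nan
    if sacc_on is not None:
        me_s = st.epoch_mean_rate(
            spikes, (sacc_on + SACCADE_ME[0], sacc_on + SACCADE_ME[1]), base)
    if hand_on is not None:
        me_h = st.epoch_mean_rate(
            spikes, (hand_on + HAND_ME[0], hand_on + HAND_ME[1]), base)
    return base, me_s, me_h


def _trial_onset(spikes, rf, go, end, pooled_sd_hint, burst_rate_hint):
    """Discharge onset for one trial: 2-SD grid crossing, then spike-level
    refinement against the stratum-average burst rate.

    Both the search window and the refinement threshold are fixed relative
    to the go cue / the stratum, never the trial's own movement onset:
    per-trial movement timing must not leak into the detected discharge
    onset, or downstream jitter regressions would see spurious coupling.
    """
    onset = np.nan
    refined = False
    if len(rf) == 0:
        return onset, refined
    grid = np.arange(go - REFERENCE_MS, end, 1.0)
    rate = rf.on_grid(grid)
    mu, sd, _ = st.baseline_stats(rf, (go - REFERENCE_MS, go))
    try:
        sd_use = st.resolve_baseline_sd(mu, sd, pooled_sd_hint)
    except st.DegenerateBaselineError:
        return onset, refined
    if not np.isfinite(mu):
        return onset, refined
    norm = (rate - mu) / sd_use
    hi = min(go + 800.0, grid[-1])
    o = st.detect_discharge_onset(grid, norm, (go - 50.0, hi))
    if o is not None and np.isfinite(burst_rate_hint) and burst_rate_hint > mu:
        r = st.refine_burst_onset(spikes, o, mu, burst_rate_hint, hi)
        if r is not None:
            o, refined = r, True
    return (np.nan if o is None else o), refined


def analyze_cell(trials, cell_index: int, onsets: dict | None = None,
                 conditions=MAIN_CONDITIONS) -> CellAnalysis:
    """Full per-cell measurement pass over a session.

    `onsets` maps trial_id to (saccade_onset, hand_onset); when omitted it is
    computed from the traces (or ground truth for trace-free sessions).
    """
    if onsets is None:
        onsets = movement_onsets(trials)

    # first pass: baseline + ME rates (cheap), pooled baseline SD
    rows = {c: [] for c in conditions}
    pooled_sds = []
    visual_elev = []
    visual_base = []
    for trial in trials:
        c = trial.condition
        if c not in rows:
            continue
        spikes = trial.spike_times[cell_index]
        sacc_on, hand_on = onsets[trial.trial_id]
        go = trial.go_cue
        base = st.count_rate(spikes, (go - REFERENCE_MS, go))
        rf = st.instantaneous_rate(spikes)
        _, sd, nref = st.baseline_stats(rf, (go - REFERENCE_MS, go))
        if np.isfinite(sd) and sd > 0:
            pooled_sds.append(sd)
        tgt = trial.event_times.get("target_on")
        if tgt is not None:
            visual_elev.append(st.count_rate(spikes, (tgt + 30.0, tgt + 230.0)))
            visual_base.append(base)
        rows[c].append((trial, spikes, sacc_on, hand_on, rf))

    pooled_sd = float(np.median(pooled_sds)) if pooled_sds else None

    conds: dict[str, ConditionData] = {}
    for c, items in rows.items():
        if not items:
            continue
        n = len(items)
        cd = ConditionData(
            direction=np.array([t.target_direction for t, *_ in items]),
            amplitude=np.array([t.target_amplitude for t, *_ in items]),
            go=np.array([t.go_cue for t, *_ in items]),
            saccade_onset=np.array([np.nan if s is None else s
                                    for _, _, s, _, _ in items]),
            hand_onset=np.array([np.nan if h is None else h
                                 for _, _, _, h, _ in items]),
            baseline_rate=np.full(n, np.nan), me_rate_sacc=np.full(n, np.nan),
            me_rate_hand=np.full(n, np.nan), discharge_onset=np.full(n, np.nan),
            onset_refined=np.zeros(n, dtype=bool), half_width=np.full(n, np.nan),
            spikes=[sp for _, sp, _, _, _ in items],
            rate_fns=[rf for *_, rf in items])
        for i, (trial, spikes, sacc_on, hand_on, rf) in enumerate(items):
            base, me_s, me_h = _trial_rates(spikes, trial.go_cue, sacc_on,
                                            hand_on)
            cd.baseline_rate[i] = base
            cd.me_rate_sacc[i] = me_s
            cd.me_rate_hand[i] = me_h

        # burst-rate hint per (direction, amplitude) stratum: averaging over
        # the stratum keeps the refinement threshold independent of any one
        # trial's movement timing
        me_best = np.fmax(np.nan_to_num(cd.me_rate_sacc, nan=-np.inf),
                          np.nan_to_num(cd.me_rate_hand, nan=-np.inf))
        me_best[~np.isfinite(me_best)] = np.nan
        hint = np.full(n, np.nan)
        for d in np.unique(cd.direction):
            for a in np.unique(cd.amplitude):
                sel = (cd.direction == d) & (cd.amplitude == a)
                if np.any(np.isfinite(me_best[sel])):
                    hint[sel] = (np.nanmean(me_best[sel])
                                 + np.nanmean(cd.baseline_rate[sel]))
        for i, (trial, spikes, sacc_on, hand_on, rf) in enumerate(items):
            onset, refined = _trial_onset(spikes, rf, trial.go_cue, trial.end,
                                          pooled_sd, hint[i])
            cd.discharge_onset[i] = onset
            cd.onset_refined[i] = refined
        conds[c] = cd

    fits = {}
    for c, cd in conds.items():
        me = cd.me_rate_hand if c == "hand" else cd.me_rate_sacc
        ok = np.isfinite(me)
        fits[c] = None
        if ok.sum() >= 4:
            uniq = np.unique(cd.direction[ok])
            if len(uniq) >= 4:
                means = np.array([np.mean(me[ok & (cd.direction == d)])
                                  for d in uniq])
                if np.any(means > 0):
                    try:
                        fits[c] = fit_von_mises(uniq, means)
                    except (ValueError, RuntimeError):
                        fits[c] = None

    from scipy.stats import ttest_ind
    vis_p = np.nan
    if len(visual_elev) >= 5:
        vis_p = float(ttest_ind(visual_elev, visual_base,
                                equal_var=False).pvalue)
        if np.mean(visual_elev) <= np.mean(visual_base):
            vis_p = 1.0

    target_hw = {c: _target_half_widths(cd, c) for c, cd in conds.items()}

    return CellAnalysis(cell_index=cell_index, conditions=conds, fits=fits,
                        pooled_baseline_sd=pooled_sd if pooled_sd else np.nan,
                        visual_response_p=vis_p,
                        target_half_widths=target_hw)


def _target_half_widths(cd: ConditionData, condition: str,
                        min_trials: int = 3, alpha: float = 0.05):
    """Half-width of the median-aligned rate for every retained target.

    Per-trial R_n estimates are too noisy for a stable half-width (their
    peaks are inflated by short-interval fluctuations), so trials of one
    target are aligned on movement onset, the per-point median rate is
    taken, and the half-width is read off that curve.  Targets whose ME
    discharge does not significantly exceed baseline (unpaired t-test) are
    discarded.  Returns (directions, amplitudes, half_widths) arrays.
    """
    from scipy.stats import ttest_ind

    align = cd.hand_onset if condition == "hand" else cd.saccade_onset
    me = cd.me_rate_hand if condition == "hand" else cd.me_rate_sacc
    dirs_out, amps_out, hw_out = [], [], []
    for d in np.unique(cd.direction):
        for a in np.unique(cd.amplitude):
            idx = np.flatnonzero((cd.direction == d) & (cd.amplitude == a)
                                 & np.isfinite(align) & np.isfinite(me))
            if len(idx) < min_trials:
                continue
            me_abs = me[idx] + cd.baseline_rate[idx]
            res = ttest_ind(me_abs, cd.baseline_rate[idx], equal_var=False)
            if not (np.isfinite(res.pvalue) and res.pvalue < alpha
                    and me[idx].mean() > 0):
                continue
            fns = [cd.rate_fns[i] for i in idx]
            grid, med = st.median_aligned_rate(fns, align[idx], -400.0, 600.0)
            # boxcar: the ISI estimator leaves multiplicative noise on the
            # plateau that would fragment the half-height region; a symmetric
            # kernel leaves the half-height width of a burst unchanged
            kernel = np.ones(51) / 51.0
            med = np.convolve(np.nan_to_num(med, nan=np.nanmedian(med)),
                              kernel, mode="same")
            base = float(np.median(cd.baseline_rate[idx]))
            burst = st.half_width(grid, med, base)
            if burst is None:
                continue
            dirs_out.append(d)
            amps_out.append(a)
            hw_out.append(burst.half_width)
    return (np.asarray(dirs_out), np.asarray(amps_out), np.asarray(hw_out))


def slice_rates_for_dynamic_fields(ca: CellAnalysis, windows) -> tuple:
    """(amplitudes, directions, n_trials x n_slices rates) for eye-hand trials,
    slices taken relative to each trial's saccade onset."""
    cd = ca.conditions.get("eye-hand")
    if cd is None:
        raise ValueError("no eye-hand trials")
    ok = np.isfinite(cd.saccade_onset)
    amps, dirs, rates = [], [], []
    for i in np.flatnonzero(ok):
        sacc = cd.saccade_onset[i]
        base = cd.baseline_rate[i]
        row = [st.epoch_mean_rate(cd.spikes[i], (sacc + w0, sacc + w1), base)
               for (w0, w1) in windows]
        amps.append(cd.amplitude[i])
        dirs.append(cd.direction[i])
        rates.append(row)
    return np.array(amps), np.array(dirs), np.array(rates)
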