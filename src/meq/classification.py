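"""Screening gate and the four effector-preference labels per cell.

A cell qualifies as a motor-equivalence (Meq) neuron when its discharge
onset precedes movement onset for both effectors and its movement-epoch
rate significantly exceeds background in the eye, hand and eye-hand
conditions.  Qualified cells then receive one label per column:

* On-direction: invariant / eye / hand / intermediate / mixed
* Intensity:    same / eye / hand / intermediate
* Duration:     same / eye / hand / intermediate / mixed / invariant
* Onset:        both / eye / hand / undetermined

Preferred-direction equality between conditions is decided by a
permutation test on the rate-weighted circular mean of movement directions
(trial labels shuffled between conditions); with fields as broad as these
(~160 deg) per-trial angular samples sit far below the concentration range
where the parametric Watson-Williams approximation is reliable, so the
exact permutation version of the same comparison is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ttest_ind

from .analysis import CellAnalysis
from .timing import (ALPHA, MIN_TRIALS, JitterResult, jitter_regression)
from .tuning import default_slice_windows, dynamic_fields
from .utils import circ_abs_dist_deg, circular_mean_deg

PD_MATCH_ALPHA = ALPHA
MIN_TRIALS_PER_CONDITION = 5


@dataclass
class ScreeningResult:
    category: str            # visual-only | post-movement-only | phasic-premovement | meq | non-task | undetermined
    reasons: list = field(default_factory=list)

    @property
    def is_meq(self) -> bool:
        return self.category == "meq"


@dataclass
class CellClassification:
    cell_id: str
    is_meq: bool
    on_direction: str
    intensity: str
    duration: str
    onset: str
    supporting: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# preferred-direction comparison
# ---------------------------------------------------------------------------

def _weighted_pd(directions, weights):
    w = np.clip(weights, 0.0, None)
    if w.sum() <= 0:
        return None
    return circular_mean_deg(directions, w)


def _mean_vector(rad, weights):
    w = np.clip(weights, 0.0, None)
    s = w.sum()
    if s <= 0:
        return np.zeros(2)
    return np.array([np.sum(w * np.cos(rad)), np.sum(w * np.sin(rad))]) / s


def compare_preferred_directions(dirs_a, rates_a, dirs_b, rates_b,
                                 n_perm: int = 400, seed: int = 0):
    """Permutation p-value for 'the two conditions share a preferred direction'.

    The test statistic is the Euclidean distance between the rate-weighted
    mean direction vectors of the two conditions (weights are the clipped
    movement-epoch rates); trial labels are shuffled between conditions.
    Using the full mean vectors rather than their angles keeps the test
    powerful for broadly tuned fields, where angular estimates alone are
    poorly concentrated.  Returns (observed pd difference in deg, p).
    """
    da, db = np.asarray(dirs_a, float), np.asarray(dirs_b, float)
    wa = np.clip(np.nan_to_num(np.asarray(rates_a, float)), 0.0, None)
    wb = np.clip(np.nan_to_num(np.asarray(rates_b, float)), 0.0, None)
    pa, pb = _weighted_pd(da, wa), _weighted_pd(db, wb)
    if pa is None or pb is None:
        return np.nan, np.nan
    ra, rb = np.deg2rad(da), np.deg2rad(db)
    obs_stat = np.linalg.norm(_mean_vector(ra, wa) - _mean_vector(rb, wb))
    rad = np.concatenate([ra, rb])
    wts = np.concatenate([wa, wb])
    n1 = len(da)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        idx = rng.permutation(len(rad))
        d = np.linalg.norm(_mean_vector(rad[idx[:n1]], wts[idx[:n1]])
                           - _mean_vector(rad[idx[n1:]], wts[idx[n1:]]))
        if d >= obs_stat:
            hits += 1
    return float(circ_abs_dist_deg(pa, pb)), hits / (n_perm + 1)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def _me_significant(ca: CellAnalysis, condition: str):
    """Unpaired t-test of on-direction ME rates against baseline rates."""
    cd = ca.conditions[condition]
    mask = ca.on_direction_mask(condition)
    me = ca.primary_me(condition) + cd.baseline_rate   # un-subtracted rate
    ok = mask & np.isfinite(me)
    if ok.sum() < MIN_TRIALS_PER_CONDITION:
        return False, np.nan
    res = ttest_ind(me[ok], cd.baseline_rate[ok], equal_var=False)
    sig = res.pvalue < ALPHA and me[ok].mean() > cd.baseline_rate[ok].mean()
    return bool(sig), float(res.pvalue)


def _median_lead(ca: CellAnalysis, condition: str, effector: str):
    """Median (movement onset - discharge onset) over on-direction trials."""
    cd = ca.conditions[condition]
    move = cd.saccade_onset if effector == "eye" else cd.hand_onset
    ok = (ca.on_direction_mask(condition) & np.isfinite(cd.discharge_onset)
          & np.isfinite(move))
    if ok.sum() < 3:
        return np.nan
    return float(np.median(move[ok] - cd.discharge_onset[ok]))


def _post_movement_significant(ca: CellAnalysis) -> bool:
    """t-test of post-movement (30-180 ms after onset) rate vs baseline."""
    from meq.spiketrain import count_rate

    for cond, attr in (("eye", "saccade_onset"), ("hand", "hand_onset")):
        cd = ca.conditions.get(cond)
        if cd is None:
            continue
        move = getattr(cd, attr)
        ok = np.isfinite(move)
        if ok.sum() < MIN_TRIALS_PER_CONDITION:
            continue
        post = [count_rate(cd.spikes[i], (move[i] + 30.0, move[i] + 180.0))
                for i in np.flatnonzero(ok)]
        res = ttest_ind(post, cd.baseline_rate[ok], equal_var=False)
        if res.pvalue < ALPHA and np.mean(post) > cd.baseline_rate[ok].mean():
            return True
    return False


def screen_cell(ca: CellAnalysis) -> ScreeningResult:
    """Apply the inclusion gate; see the module docstring for the criteria."""
    missing = [c for c in ("eye", "hand", "eye-hand") if c not in ca.conditions]
    if missing:
        return ScreeningResult("undetermined",
                               [f"missing condition(s): {missing}"])

    sig = {}
    for c in ("eye", "hand", "eye-hand"):
        sig[c], _ = _me_significant(ca, c)

    if not any(sig.values()):
        if np.isfinite(ca.visual_response_p) and ca.visual_response_p < ALPHA:
            return ScreeningResult("visual-only",
                                   ["target-locked response only"])
        # a cell silent in the pre/peri-movement epoch may still fire after
        # the movement; such cells are excluded as post-movement responders
        if _post_movement_significant(ca):
            return ScreeningResult("post-movement-only",
                                   ["discharge follows movement onset"])
        return ScreeningResult("non-task", ["no movement-epoch modulation"])

    lead_eye = _median_lead(ca, "eye", "eye")
    lead_hand = _median_lead(ca, "hand", "hand")
    leads = np.array([lead_eye, lead_hand])
    if np.all(np.isfinite(leads)) and np.all(leads <= 0):
        return ScreeningResult("post-movement-only",
                               [f"leads eye={lead_eye:.0f} hand={lead_hand:.0f} ms"])

    if all(sig.values()) and np.all(np.isfinite(leads)) and np.all(leads > 0):
        return ScreeningResult("meq", [])
    reasons = [f"ME significant: {sig}"]
    if not np.all(np.isfinite(leads)) or not np.all(leads > 0):
        reasons.append(f"leads eye={lead_eye} hand={lead_hand}")
    return ScreeningResult("phasic-premovement", reasons)


# ---------------------------------------------------------------------------
# the four label columns
# ---------------------------------------------------------------------------

def _pd_comparison(ca: CellAnalysis, cond_a: str, cond_b: str, seed: int = 0):
    a, b = ca.conditions[cond_a], ca.conditions[cond_b]
    return compare_preferred_directions(
        a.direction, (ca.primary_me(cond_a)), b.direction,
        (ca.primary_me(cond_b)), seed=seed)


def _detect_drift(ca: CellAnalysis):
    """Dynamic-field drift: does the eye-hand pd slide from the eye pd to the
    hand pd across the 20-ms slices around saccade onset?"""
    pd_eye, pd_hand = ca.pd("eye"), ca.pd("hand")
    if pd_eye is None or pd_hand is None:
        return False, None
    windows = default_slice_windows()
    from .analysis import slice_rates_for_dynamic_fields
    try:
        amps, dirs, rates = slice_rates_for_dynamic_fields(ca, windows)
    except ValueError:
        return False, None
    if len(amps) == 0:
        return False, None
    dyn = dynamic_fields(amps, dirs, rates, windows)
    pds = np.asarray(dyn.preferred_directions(), dtype=float)
    valid = np.flatnonzero(np.isfinite(pds))
    if len(valid) < 2:
        return False, dyn
    first, last = pds[valid[0]], pds[valid[-1]]
    drift = (circ_abs_dist_deg(first, pd_eye) <= 45.0
             and circ_abs_dist_deg(last, pd_hand) <= 45.0
             and circ_abs_dist_deg(first, last) > 60.0)
    return bool(drift), dyn


def classify_on_direction(ca: CellAnalysis, seed: int = 0):
    """invariant / eye / hand / intermediate / mixed, with supporting stats."""
    sup: dict = {}
    for c in ("eye", "hand", "eye-hand"):
        if ca.pd(c) is None:
            return "undetermined", {"reason": f"untuned in {c}"}
        sup[f"pd_{c}"] = ca.pd(c)

    d_eh, p_eh = _pd_comparison(ca, "eye", "hand", seed=seed)
    fit_dpd = circ_abs_dist_deg(ca.pd("eye"), ca.pd("hand"))
    sup["delta_pd_eye_hand"] = d_eh
    sup["fit_delta_pd_eye_hand"] = fit_dpd
    sup["p_eye_vs_hand"] = p_eh
    if not np.isfinite(p_eh):
        return "undetermined", sup
    # invariant: no significant difference, or a significant-but-small one
    # (non-invariant fields differ considerably, typically > 90 deg)
    if p_eh >= PD_MATCH_ALPHA or fit_dpd <= 30.0:
        return "invariant", sup

    # drifting fields would masquerade as intermediate: test drift first
    drift, dyn = _detect_drift(ca)
    if dyn is not None:
        sup["slice_pds"] = dyn.preferred_directions()
    if drift:
        return "mixed", sup

    # which single-effector pd does the eye-hand pd resemble?  Decided from
    # the fitted preferred directions; the match radius is a quarter of the
    # eye-hand separation (capped at 45 deg), the midpoint between "at one
    # end" and "halfway in between"
    d_e = circ_abs_dist_deg(ca.pd("eye-hand"), ca.pd("eye"))
    d_h = circ_abs_dist_deg(ca.pd("eye-hand"), ca.pd("hand"))
    radius = min(45.0, fit_dpd / 4.0)
    sup.update({"d_eyehand_to_eye": d_e, "d_eyehand_to_hand": d_h,
                "match_radius": radius})
    match_e, match_h = d_e <= radius, d_h <= radius
    if match_e and not match_h:
        return "eye", sup
    if match_h and not match_e:
        return "hand", sup
    if match_e and match_h:
        return ("eye", sup) if d_e <= d_h else ("hand", sup)
    return "intermediate", sup


def _trial_samples(ca: CellAnalysis, condition: str, values: np.ndarray):
    """On-direction, finite per-trial samples of `values`."""
    mask = ca.on_direction_mask(condition) & np.isfinite(values)
    return values[mask]


#: relative mean difference below which two samples are treated as
#: equivalent even when a t-test flags them (guards against calling small
#: systematic measurement biases a preference)
EQUIVALENCE_FRACTION = 0.25


def _differs(a, b):
    """(significantly different, p) with an effect-size guard."""
    p = float(ttest_ind(a, b, equal_var=False).pvalue)
    ma, mb = float(np.mean(a)), float(np.mean(b))
    big = abs(ma - mb) > EQUIVALENCE_FRACTION * 0.5 * (abs(ma) + abs(mb))
    return (p < ALPHA) and big, p


def _three_way_label(eye_vals, hand_vals, eh_vals):
    """same / eye / hand / intermediate from three per-trial samples."""
    if min(len(eye_vals), len(hand_vals), len(eh_vals)) < MIN_TRIALS_PER_CONDITION:
        return "undetermined", {}
    diff_e_h, p_e_h = _differs(eye_vals, hand_vals)
    sup = {"p_eye_vs_hand": p_e_h,
           "mean_eye": float(np.mean(eye_vals)),
           "mean_hand": float(np.mean(hand_vals)),
           "mean_eyehand": float(np.mean(eh_vals))}
    if not diff_e_h:
        return "same", sup
    diff_e, p_e = _differs(eh_vals, eye_vals)
    diff_h, p_h = _differs(eh_vals, hand_vals)
    sup.update({"p_eyehand_vs_eye": p_e, "p_eyehand_vs_hand": p_h})
    if not diff_e and diff_h:
        return "eye", sup
    if not diff_h and diff_e:
        return "hand", sup
    if not diff_e and not diff_h:
        d_e = abs(sup["mean_eyehand"] - sup["mean_eye"])
        d_h = abs(sup["mean_eyehand"] - sup["mean_hand"])
        return ("eye", sup) if d_e <= d_h else ("hand", sup)
    return "intermediate", sup


def classify_intensity(ca: CellAnalysis):
    """Burst-intensity preference from on-direction movement-epoch rates."""
    vals = {c: _trial_samples(ca, c, ca.primary_me(c))
            for c in ("eye", "hand", "eye-hand")}
    return _three_way_label(vals["eye"], vals["hand"], vals["eye-hand"])


MIN_TARGETS_PER_CONDITION = 4


def _trim_width_outliers(widths, n_mads: float = 3.0):
    """Boolean mask dropping implausibly long half-widths.

    Weakly driven targets occasionally yield a half-height region spanning a
    broad stretch of background noise; these inflate the condition mean (the
    analysis protocol discards noisy measurements).
    """
    w = np.asarray(widths, float)
    if len(w) < 4:
        return np.ones(len(w), bool)
    med = np.median(w)
    mad = 1.4826 * np.median(np.abs(w - med))
    if mad <= 0:
        return np.ones(len(w), bool)
    return w <= med + n_mads * mad


def classify_duration(ca: CellAnalysis):
    """Burst-duration preference from per-target discharge half-widths.

    Half-widths come from the median-aligned rate of each retained target
    (targets without a significant ME discharge are discarded upstream).
    When the single-effector durations differ, eye-hand targets are first
    split into eye-preferred vs hand-preferred direction bins (+/-45 deg);
    a significant short-vs-long split in the single-effector sense marks
    the cell 'mixed'.
    """
    hw = ca.target_half_widths
    if any(c not in hw for c in ("eye", "hand", "eye-hand")):
        return "undetermined", {}
    keep = {c: _trim_width_outliers(hw[c][2]) for c in ("eye", "hand", "eye-hand")}
    vals = {c: hw[c][2][keep[c]] for c in ("eye", "hand", "eye-hand")}
    if min(len(v) for v in vals.values()) < MIN_TARGETS_PER_CONDITION:
        return "undetermined", {}
    diff_e_h, p_e_h = _differs(vals["eye"], vals["hand"])
    if not diff_e_h:
        return "same", {"p_eye_vs_hand": p_e_h,
                        "mean_eye": float(np.mean(vals["eye"])),
                        "mean_hand": float(np.mean(vals["hand"]))}

    pd_eye, pd_hand = ca.pd("eye"), ca.pd("hand")
    if (pd_eye is not None and pd_hand is not None
            and circ_abs_dist_deg(pd_eye, pd_hand) > 60.0):
        dirs_eh, _, hw_eh_all = hw["eye-hand"]
        dirs_eh = dirs_eh[keep["eye-hand"]]
        hw_eh = hw_eh_all[keep["eye-hand"]]
        near_eye = circ_abs_dist_deg(dirs_eh, pd_eye) <= 45.0
        near_hand = circ_abs_dist_deg(dirs_eh, pd_hand) <= 45.0
        if near_eye.sum() >= 3 and near_hand.sum() >= 3:
            p_bins = float(ttest_ind(hw_eh[near_eye], hw_eh[near_hand],
                                     equal_var=False).pvalue)
            m_e, m_h = np.mean(hw_eh[near_eye]), np.mean(hw_eh[near_hand])
            short_eye = m_e < m_h
            split = min(m_e, m_h) / max(m_e, m_h) < 0.6   # a real short/long split
            if p_bins < ALPHA and split and short_eye == (
                    np.mean(vals["eye"]) < np.mean(vals["hand"])):
                return "mixed", {"p_eye_vs_hand": p_e_h,
                                 "p_direction_bins": p_bins,
                                 "mean_bin_eye": float(m_e),
                                 "mean_bin_hand": float(m_h)}
    return _three_way_label(vals["eye"], vals["hand"], vals["eye-hand"])


def onset_regressions(ca: CellAnalysis) -> dict:
    """The four jitter regressions backing the Onset column.

    In eye-hand trials: align on saccade onset and predict hand onset (hand
    coupling), align on hand onset and predict saccade onset (eye coupling).
    Follow-ups use single-effector trials aligned on the go cue.
    """
    out = {}
    cd = ca.conditions.get("eye-hand")
    if cd is not None:
        # only spike-refined onsets enter the regressions: fallback grid
        # crossings carry background-interval jitter that masks the coupling
        mask = (ca.on_direction_mask("eye-hand") & np.isfinite(cd.discharge_onset)
                & cd.onset_refined
                & np.isfinite(cd.saccade_onset) & np.isfinite(cd.hand_onset))
        onset = cd.discharge_onset[mask]
        sacc = cd.saccade_onset[mask]
        hand = cd.hand_onset[mask]
        out["hand_coupling"] = jitter_regression(
            onset - sacc, hand - sacc, "saccade", "hand", mad_trim=3.5)
        out["eye_coupling"] = jitter_regression(
            onset - hand, sacc - hand, "hand", "saccade", mad_trim=3.5)
    for cond, effector, move_attr in (("eye", "eye", "saccade_onset"),
                                      ("hand", "hand", "hand_onset")):
        cds = ca.conditions.get(cond)
        if cds is None:
            continue
        move = getattr(cds, move_attr)
        mask = (ca.on_direction_mask(cond) & np.isfinite(cds.discharge_onset)
                & cds.onset_refined & np.isfinite(move))
        out[f"followup_{effector}"] = jitter_regression(
            cds.discharge_onset[mask] - cds.go[mask],
            move[mask] - cds.go[mask], "go", effector, mad_trim=3.5)
    return out


def classify_onset(ca: CellAnalysis):
    """both / eye / hand / undetermined from the jitter regressions."""
    regs = onset_regressions(ca)
    sup = {k: {"r_squared": v.r_squared, "p": v.pvalue, "n": v.n_trials}
           for k, v in regs.items()}
    eye = regs.get("eye_coupling", JitterResult("", "", *[np.nan] * 4, 0))
    hand = regs.get("hand_coupling", JitterResult("", "", *[np.nan] * 4, 0))
    fu_eye = regs.get("followup_eye")
    fu_hand = regs.get("followup_hand")
    sig_e, sig_h = eye.significant, hand.significant
    if sig_e and sig_h:
        return "both", sup
    if sig_e:
        if fu_hand is not None and fu_hand.significant:
            return "both", sup
        return "eye", sup
    if sig_h:
        if fu_eye is not None and fu_eye.significant:
            return "both", sup
        return "hand", sup
    # neither eye-hand coupling reached significance: the single-effector
    # go-aligned regressions can still establish coupling to both effectors
    if (fu_eye is not None and fu_eye.significant
            and fu_hand is not None and fu_hand.significant):
        return "both", sup
    return "undetermined", sup


def classify_cell(ca: CellAnalysis, cell_id: str | None = None,
                  seed: int = 0) -> CellClassification:
    """Screening plus all four label columns for one cell."""
    screening = screen_cell(ca)
    on, sup_on = classify_on_direction(ca, seed=seed)
    intensity, sup_int = classify_intensity(ca)
    duration, sup_dur = classify_duration(ca)
    onset, sup_onset = classify_onset(ca)
    return CellClassification(
        cell_id=cell_id or f"cell{ca.cell_index}",
        is_meq=screening.is_meq, on_direction=on, intensity=intensity,
        duration=duration, onset=onset,
        supporting={"screening": screening.category, "on_direction": sup_on,
                    "intensity": sup_int, "duration": sup_dur,
                    "onset": sup_onset})


def classify_population(trials, n_cells: int, onsets=None, cell_ids=None,
                        seed: int = 0) -> list[CellClassification]:
    from .analysis import analyze_cell, movement_onsets
    if onsets is None:
        onsets = movement_onsets(trials)
    out = []
    for i in range(n_cells):
        ca = analyze_cell(trials, i, onsets=onsets)
        cid = cell_ids[i] if cell_ids is not None else None
        out.append(classify_cell(ca, cell_id=cid, seed=seed + i))
    return out


def summarize_population(classifications, pds_eye=None, pds_hand=None) -> dict:
    """Category counts per column, plus optional pd-uniformity tests."""
    import pandas as pd

    if len(classifications) == 0:
        return {"counts": pd.DataFrame(), "n_cells": 0}
    df = pd.DataFrame([{"cell_id": c.cell_id, "on_direction": c.on_direction,
                        "intensity": c.intensity, "duration": c.duration,
                        "onset": c.onset} for c in classifications])
    counts = {col: df[col].value_counts().to_dict()
              for col in ("on_direction", "intensity", "duration", "onset")}
    out = {"counts": counts, "n_cells": len(df), "table": df}
    if pds_eye is not None and len(pds_eye) >= 4:
        from .tuning import rayleigh_test
        z, p = rayleigh_test(pds_eye)
        out["rayleigh_eye"] = {"z": z, "p": p}
    if pds_hand is not None and len(pds_hand) >= 4:
        from .tuning import rayleigh_test
        z, p = rayleigh_test(pds_hand)
        out["rayleigh_hand"] = {"z": z, "p": p}
    return out
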