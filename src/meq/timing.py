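"""Trial-by-trial timing analysis: which effector does a cell's onset track?

After aligning coordinated eye-hand trials (within +/-45 deg of the cell's
on-direction) on the onset of one effector, the onset of the other
effector's movement is regressed on the discharge onset; a significant
slope means the discharge jitter propagates into that effector's timing.
Single-effector trials aligned on the go cue provide the follow-up check
that guards against range restriction.  Aligning instead on the discharge
onset yields the latency spreads SD_E and SD_H, compared with Bartlett's
parametric and the Kepner-Randles nonparametric scale tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

MIN_TRIALS = 8          # below this, timing labels are 'undetermined'
ON_DIRECTION_WINDOW = 45.0   # deg, inclusive
ALPHA = 0.05


@dataclass
class JitterResult:
    """OLS regression of an event's onset on the discharge onset."""

    alignment_event: str     # 'saccade', 'hand' or 'go'
    predicted_event: str
    slope: float
    intercept: float
    r_squared: float
    pvalue: float
    n_trials: int

    @property
    def significant(self) -> bool:
        return np.isfinite(self.pvalue) and self.pvalue < ALPHA


UNDEFINED_REGRESSION = JitterResult("", "", np.nan, np.nan, np.nan, np.nan, 0)


def jitter_regression(discharge_onsets, event_onsets, alignment_event: str = "",
                      predicted_event: str = "", min_trials: int = MIN_TRIALS,
                      mad_trim: float | None = None) -> JitterResult:
    """Regress `event_onsets` on `discharge_onsets` (both ms, same alignment).

    Trials with either onset missing are dropped; `mad_trim` additionally
    drops trials whose discharge onset lies more than that many scaled MADs
    from the median (gross detection failures would otherwise dominate the
    least-squares fit).  Fewer than `min_trials` usable trials, or zero
    variance of the discharge onset (perfect lock on the alignment event),
    give the undefined-regression sentinel.
    """
    x = np.asarray([np.nan if v is None else v for v in discharge_onsets], float)
    y = np.asarray([np.nan if v is None else v for v in event_onsets], float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if mad_trim is not None and len(x) >= MIN_TRIALS:
        mad = 1.4826 * np.median(np.abs(x - np.median(x)))
        if mad > 0:
            keep = np.abs(x - np.median(x)) <= mad_trim * mad
            x, y = x[keep], y[keep]
        # one round of residual-based rejection: single-trial onset
        # detection has a small heavy tail that would otherwise dominate
        # the least-squares fit
        if len(x) >= MIN_TRIALS and np.std(x) > 0 and np.std(y) > 0:
            fit = stats.linregress(x, y)
            resid = y - (fit.slope * x + fit.intercept)
            rmad = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if rmad > 0:
                keep = np.abs(resid - np.median(resid)) <= mad_trim * rmad
                x, y = x[keep], y[keep]
    n = len(x)
    if n < min_trials or np.std(x) == 0.0 or np.std(y) == 0.0:
        return JitterResult(alignment_event, predicted_event, np.nan, np.nan,
                            np.nan, np.nan, n)
    res = stats.linregress(x, y)
    return JitterResult(alignment_event, predicted_event, float(res.slope),
                        float(res.intercept), float(res.rvalue**2),
                        float(res.pvalue), n)


def single_effector_followup(discharge_onsets, movement_onsets,
                             effector: str) -> JitterResult:
    """Jitter regression for single-effector trials aligned on the go cue.

    Onsets are expressed relative to the go cue; the regression asks whether
    discharge-onset jitter predicts the movement onset of the rewarded
    effector.
    """
    return jitter_regression(discharge_onsets, movement_onsets,
                             alignment_event="go", predicted_event=effector)


@dataclass
class LatencySpread:
    """Spreads of effector latencies after aligning trials on discharge onset."""

    sd_eye: float
    sd_hand: float
    bartlett_stat: float
    bartlett_p: float
    kepner_randles_stat: float
    kepner_randles_p: float
    n_trials: int
    n_dropped: int

    @property
    def ratio(self) -> float:
        """SD_E / SD_H; < 1 means the discharge is better locked to the eye."""
        return self.sd_eye / self.sd_hand


def latency_spread(eye_latencies, hand_latencies) -> LatencySpread:
    """SD_E, SD_H and homoscedasticity tests from per-trial latencies
    (effector onset minus discharge onset, ms).  Trials with either latency
    missing are dropped and counted."""
    e = np.asarray([np.nan if v is None else v for v in eye_latencies], float)
    h = np.asarray([np.nan if v is None else v for v in hand_latencies], float)
    if len(e) != len(h):
        raise ValueError("latencies must be paired per trial")
    ok = np.isfinite(e) & np.isfinite(h)
    dropped = int(len(e) - ok.sum())
    e, h = e[ok], h[ok]
    if len(e) < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} trials with both latencies")
    b_stat, b_p = bartlett_test(e, h)
    k_stat, k_p = kepner_randles_test(e, h)
    return LatencySpread(sd_eye=float(np.std(e, ddof=1)),
                         sd_hand=float(np.std(h, ddof=1)),
                         bartlett_stat=b_stat, bartlett_p=b_p,
                         kepner_randles_stat=k_stat, kepner_randles_p=k_p,
                         n_trials=len(e), n_dropped=dropped)


def bartlett_test(sample_a, sample_b):
    """Bartlett's test of equal variances; returns (statistic, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if min(len(a), len(b)) < 5:
        raise ValueError("Bartlett test needs n >= 5 per sample")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("degenerate (constant) sample")
    stat, p = stats.bartlett(a, b)
    return float(stat), float(p)


def kepner_randles_test(x, y):
    """Nonparametric test of equal marginal scales for paired bivariate data.

    Under bivariate symmetry, the marginals of (X, Y) have equal scales
    exactly when the sum S = X + Y and difference D = X - Y (after centering
    each marginal) are unassociated.  The statistic is Kendall's tau between
    S and D with its large-sample normal null; it is mean-free by
    construction, and swapping the coordinates flips its sign without
    changing the p-value.  Returns (statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples required")
    if len(x) < MIN_TRIALS:
        raise ValueError(f"Kepner-Randles needs n >= {MIN_TRIALS} pairs")
    s = (x - x.mean()) + (y - y.mean())
    d = (x - x.mean()) - (y - y.mean())
    if np.std(s) == 0 or np.std(d) == 0:
        raise ValueError("degenerate sample (zero variance)")
    res = stats.kendalltau(s, d)
    n = len(x)
    # normal approximation for tau under the null
    var_tau = 2.0 * (2.0 * n + 5.0) / (9.0 * n * (n - 1.0))
    z = res.statistic / np.sqrt(var_tau)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
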