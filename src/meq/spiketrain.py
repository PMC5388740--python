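"""Instantaneous firing-rate estimation and discharge-event measures.

The rate estimator inverts a running average of five consecutive
inter-spike intervals: for the spike at t_n,

    R_n = 5 / (t_{n+3} - t_{n-2})

so an estimate exists for every spike except the first two and last three.
Rates are attached at spike times and linearly interpolated to a 1-ms grid
for alignment and medians.  Baseline statistics (mean and SD of R_n) come
from the reference period, the 300 ms ending at the go cue; discharge onset
is the first time the normalized rate exceeds 2 SD and stays there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: movement-epoch windows around movement onset, ms (start, stop)
HAND_ME = (-60.0, 20.0)
SACCADE_ME = (-30.0, 30.0)
#: reference (background) period: this long, ending at the go cue
REFERENCE_MS = 300.0
#: sustained-crossing requirement for onset detection, ms
ONSET_PERSIST_MS = 10.0
ONSET_SD_THRESHOLD = 2.0

#: sentinel for "no discharge onset found"
NO_DISCHARGE = None


@dataclass
class RateFunction:
    """Instantaneous firing rate attached at spike times."""

    times: np.ndarray   # ms, one per spike with a defined estimate
    rates: np.ndarray   # spikes/s

    def __len__(self):
        return len(self.times)

    def on_grid(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto `grid` (ms); NaN outside the support."""
        if len(self.times) == 0:
            return np.full(len(grid), np.nan)
        out = np.interp(grid, self.times, self.rates)
        out[(grid < self.times[0]) | (grid > self.times[-1])] = np.nan
        return out


def instantaneous_rate(spike_times: np.ndarray) -> RateFunction:
    """ISI-inverse rate estimate R_n = 5/(t_{n+3} - t_{n-2}) in spikes/s.

    Fewer than 6 spikes yield an empty rate function (a silent cell is not
    an error).
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if len(t) < 6:
        return RateFunction(np.empty(0), np.empty(0))
    span_ms = t[5:] - t[:-5]              # t_{n+3} - t_{n-2} for n = 2 .. N-4
    rates = 5.0 / span_ms * 1000.0
    return RateFunction(t[2:-3].copy(), rates)


def median_aligned_rate(rate_fns: list[RateFunction], align_times: np.ndarray,
                        t_start: float, t_stop: float, step: float = 1.0):
    """Median rate over trials on a common grid relative to an alignment event.

    Each trial's rate function is shifted so its alignment time is zero,
    interpolated to the grid, and the per-point median (ignoring undefined
    samples) is returned as ``(grid, median)``.
    """
    if len(rate_fns) == 0:
        raise ValueError("need at least one trial")
    grid = np.arange(t_start, t_stop + step / 2.0, step)
    stack = np.full((len(rate_fns), len(grid)), np.nan)
    for i, (rf, t0) in enumerate(zip(rate_fns, align_times)):
        shifted = RateFunction(rf.times - t0, rf.rates)
        stack[i] = shifted.on_grid(grid)
    med = np.full(len(grid), np.nan)
    defined = np.isfinite(stack).any(axis=0)
    if np.any(defined):
        med[defined] = np.nanmedian(stack[:, defined], axis=0)
    return grid, med


def baseline_stats(rate_fn: RateFunction, reference_window: tuple[float, float],
                   step: float = 1.0):
    """Mean and SD of the rate over the reference window, from 1-ms samples.

    Returns ``(mu, sd, n_samples)``; fewer than 2 defined samples give
    ``(nan, nan, n)``.
    """
    lo, hi = reference_window
    grid = np.arange(lo, hi, step)
    vals = rate_fn.on_grid(grid)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        return np.nan, np.nan, len(vals)
    return float(vals.mean()), float(vals.std(ddof=0)), len(vals)


class DegenerateBaselineError(ValueError):
    """Reference period has zero rate variance and no usable fallback."""


def resolve_baseline_sd(mu: float, sd: float, pooled_sd: float | None = None,
                        window_s: float = REFERENCE_MS / 1000.0) -> float:
    """SD to use for normalization, with fallbacks for degenerate baselines.

    A zero (or undefined) trial SD falls back to the pooled SD across the
    cell's trials; if that is also degenerate, to the Poisson-count SD
    sqrt(mu * T) / T over the reference window.
    """
    if np.isfinite(sd) and sd > 0:
        return sd
    if pooled_sd is not None and np.isfinite(pooled_sd) and pooled_sd > 0:
        return pooled_sd
    if np.isfinite(mu) and mu > 0:
        return float(np.sqrt(mu * window_s) / window_s)
    raise DegenerateBaselineError("zero-variance, zero-mean reference period")


def normalize_rate(rates: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Express rates as multiples of the baseline SD away from the mean."""
    if not np.isfinite(sd) or sd <= 0:
        raise DegenerateBaselineError("baseline SD must be positive; see resolve_baseline_sd")
    return (np.asarray(rates, dtype=float) - mu) / sd


def detect_discharge_onset(grid: np.ndarray, normalized: np.ndarray,
                           search_window: tuple[float, float],
                           threshold: float = ONSET_SD_THRESHOLD,
                           persist_ms: float = ONSET_PERSIST_MS):
    """Earliest grid time where the normalized rate exceeds `threshold` and
    stays above it for `persist_ms`.  Returns the sentinel ``NO_DISCHARGE``
    when there is no sustained crossing."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = search_window
    step = float(np.median(np.diff(grid))) if len(grid) > 1 else 1.0
    need = max(1, int(round(persist_ms / step)))
    ok = (grid >= lo) & (grid <= hi) & np.isfinite(normalized) & (normalized > threshold)
    run = 0
    for i in range(len(grid)):
        if ok[i]:
            run += 1
            if run >= need:
                return float(grid[i - need + 1])
        else:
            run = 0
    return NO_DISCHARGE


def refine_burst_onset(spike_times, crossing: float, mu: float,
                       burst_rate: float, search_hi: float,
                       lookback_ms: float = 20.0):
    """Sharpen a detected discharge onset to the first spike of the burst.

    The 2-SD crossing of the interpolated R_n can precede the burst by one
    or two background inter-spike intervals, because estimates attached to
    spikes just before the burst already span burst intervals.  This step
    (standing in for the manual onset checks such analyses traditionally
    relied on) advances the onset to the first spike at or after
    ``crossing - lookback_ms`` whose forward three-interval rate exceeds the
    half-height between baseline and the burst rate, minus one expected
    burst interval (the mean wait from envelope onset to its first spike).
    `burst_rate` should be a count-based estimate of the within-burst rate,
    e.g. baseline + movement-epoch rate.  Returns the refined time, or
    ``None`` when no spike qualifies.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if len(t) < 7 or not np.isfinite(burst_rate) or burst_rate <= mu:
        return None
    thr = mu + 0.35 * (burst_rate - mu)
    rate1 = 1.0 / np.diff(t) * 1000.0
    rate3 = 3.0 / (t[3:] - t[:-3]) * 1000.0
    rate5 = 5.0 / (t[5:] - t[:-5]) * 1000.0
    fast = rate3 >= thr
    # the candidate's own interval must already be burst-like (a lone
    # background spike shortly before the burst would otherwise qualify via
    # its forward-looking windows), two consecutive three-interval rates
    # must qualify, and a five-interval confirmation must hold
    ok = (t[:-6] >= crossing - lookback_ms) & (t[:-6] <= search_hi) \
        & (rate1[:-5] >= thr) & fast[:-3] & fast[1:-2] & (rate5[:-1] >= thr)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    return float(t[idx[0]] - 1000.0 / burst_rate)


@dataclass
class Burst:
    """Half-width measurement of one discharge burst."""

    onset: float       # first up-crossing of the half-height, ms
    offset: float      # first down-crossing after the peak, ms
    peak_time: float
    peak_rate: float   # spikes/s
    half_width: float  # ms


def half_width(grid: np.ndarray, rate: np.ndarray, baseline: float):
    """Burst duration between half-height crossings around the peak.

    Threshold is baseline + (peak - baseline)/2.  Returns a :class:`Burst`,
    or ``None`` when the rate never rises above the threshold (no burst).
    """
    grid = np.asarray(grid, dtype=float)
    rate = np.asarray(rate, dtype=float)
    finite = np.isfinite(rate)
    if not np.any(finite):
        return None
    peak_idx = int(np.nanargmax(rate))
    peak = rate[peak_idx]
    if not peak > baseline:
        return None
    thr = baseline + (peak - baseline) / 2.0
    above = finite & (rate > thr)
    if not above[peak_idx]:
        return None
    # walk out from the peak to the first crossings on each side
    i = peak_idx
    while i > 0 and above[i - 1]:
        i -= 1
    j = peak_idx
    while j < len(rate) - 1 and above[j + 1]:
        j += 1
    onset, offset = float(grid[i]), float(grid[j])
    if offset <= onset:
        offset = onset + float(np.median(np.diff(grid)))
    return Burst(onset=onset, offset=offset, peak_time=float(grid[peak_idx]),
                 peak_rate=float(peak), half_width=offset - onset)


def epoch_mean_rate(spike_times: np.ndarray, window: tuple[float, float],
                    baseline_rate: float) -> float:
    """Baseline-subtracted mean rate (spikes/s) in a window: count/length - baseline."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive length")
    spikes = np.asarray(spike_times, dtype=float)
    count = int(np.sum((spikes >= lo) & (spikes < hi)))
    return count / ((hi - lo) / 1000.0) - baseline_rate


def count_rate(spike_times: np.ndarray, window: tuple[float, float]) -> float:
    """Plain count-based mean rate (spikes/s) in a window."""
    lo, hi = window
    spikes = np.asarray(spike_times, dtype=float)
    return float(np.sum((spikes >= lo) & (spikes < hi)) / ((hi - lo) / 1000.0))
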