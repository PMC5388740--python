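"""Directional tuning: von Mises fits, field widths and circular statistics.

A cell's tuning curve over movement direction x is modeled as

    f(x) = A * exp(k * cos(x - mu)) / (2 * pi * I0(k))

with A a scaling factor, mu the preferred direction and k the
concentration; the field-width measure is 2/sqrt(k), reported in degrees
(broader fields have smaller k).  Two-dimensional movement fields over
(amplitude, direction) are the product of a Gaussian in amplitude and a von
Mises in direction, fit by least squares; time-sliced fits of eye-hand
trials expose dynamic drifts of the preferred direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import i0
from scipy.stats import f as f_dist

from .utils import circ_abs_dist_deg, circular_mean_deg, resultant_length, wrap_deg

UNTUNED_RATE_SD = 1e-9


@dataclass
class TuningFit:
    """Least-squares von Mises fit of a directional tuning curve."""

    A: float            # scaling factor, spikes/s
    mu_pd: float        # preferred direction, deg in [0, 360)
    k: float            # concentration
    rss: float
    untuned: bool = False

    @property
    def width(self) -> float:
        """Field width 2/sqrt(k), converted from radians to degrees."""
        return float(np.rad2deg(2.0 / np.sqrt(self.k)))

    def curve(self, directions_deg):
        return von_mises_curve(np.asarray(directions_deg, dtype=float),
                               self.A, self.mu_pd, self.k)


def von_mises_curve(x_deg, A, mu_deg, k):
    """A * exp(k cos(x - mu)) / (2 pi I0(k)), angles in degrees."""
    return A * np.exp(k * np.cos(np.deg2rad(x_deg - mu_deg))) / (2.0 * np.pi * i0(k))


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood-style inversion of the mean resultant length."""
    r = min(max(r, 1e-6), 1.0 - 1e-6)
    if r < 0.53:
        return 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    return 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)


def fit_von_mises(directions_deg, rates, n_restarts: int = 8) -> TuningFit:
    """Fit the von Mises tuning model to per-direction rates by least squares.

    `rates` are baseline-subtracted mean rates per direction.  Initialization
    uses the rate-weighted circular mean for mu and the resultant-length
    inversion for k; `n_restarts` additional starts offset mu to avoid local
    minima.  All-equal rates return an untuned sentinel; all-negative rates
    are rejected (baseline subtraction belongs upstream).
    """
    x = np.asarray(directions_deg, dtype=float)
    y = np.asarray(rates, dtype=float)
    if len(np.unique(np.round(wrap_deg(x), 6))) < 4:
        raise ValueError("need rates at >= 4 distinct directions")
    if np.all(y <= 0):
        raise ValueError("all rates non-positive; subtract baseline upstream")
    if np.std(y) <= UNTUNED_RATE_SD:
        return TuningFit(A=float(np.mean(y)) * 2.0 * np.pi, mu_pd=0.0, k=np.nan,
                         rss=0.0, untuned=True)

    w = np.clip(y, 0.0, None)
    mu0 = circular_mean_deg(x, w) if w.sum() > 0 else 0.0
    k0 = max(_kappa_from_r(resultant_length(x, w)), 0.05)
    A0 = max(y.max(), 1e-3) * 2.0 * np.pi * i0(k0) / np.exp(k0)

    best = None
    offsets = np.linspace(0.0, 360.0, n_restarts, endpoint=False)
    for off in offsets:
        try:
            popt, _ = curve_fit(
                von_mises_curve, x, y, p0=[A0, mu0 + off, k0],
                bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, 500.0]),
                maxfev=20000)
        except RuntimeError:
            continue
        resid = von_mises_curve(x, *popt) - y
        rss = float(resid @ resid)
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("von Mises fit failed to converge from any start")
    rss, (A, mu, k) = best
    return TuningFit(A=float(A), mu_pd=float(wrap_deg(mu)), k=float(k), rss=rss)


def fit_von_mises_grid(directions_deg, rates, k_grid=None, mu_step_deg: float = 0.5):
    """Brute-force least-squares von Mises fit on a (mu, k) grid.

    For each (mu, k) the optimal A is closed-form, so this scans the full
    parameter space; it serves as an independent oracle for the nonlinear
    optimizer.  Returns a :class:`TuningFit`.
    """
    x = np.deg2rad(np.asarray(directions_deg, dtype=float))
    y = np.asarray(rates, dtype=float)
    if k_grid is None:
        k_grid = np.concatenate([np.linspace(1e-3, 2.0, 4000),
                                 np.linspace(2.0, 20.0, 2000)])
    mus = np.deg2rad(np.arange(0.0, 360.0, mu_step_deg))
    best = (np.inf, 0.0, 0.0, 0.0)
    for k in k_grid:
        norm = 2.0 * np.pi * i0(k)
        basis = np.exp(k * np.cos(x[:, None] - mus[None, :])) / norm   # n x m
        num = y @ basis
        den = np.einsum("ij,ij->j", basis, basis)
        A = np.where(den > 0, np.clip(num, 0.0, None) / den, 0.0)
        rss = A**2 * den - 2.0 * A * num + y @ y
        j = int(np.argmin(rss))
        if rss[j] < best[0]:
            best = (float(rss[j]), float(A[j]), float(np.rad2deg(mus[j])), float(k))
    rss, A, mu, k = best
    return TuningFit(A=A, mu_pd=wrap_deg(mu), k=k, rss=rss)


def tuning_half_width(curve, grid_step_deg: float = 0.1):
    """Half-width at half height (deg) of a directional tuning curve.

    `curve` is either a callable of direction in degrees or a ``(angles,
    values)`` pair (interpolated periodically).  The threshold lies midway
    between the curve's minimum and maximum; the result is the mean angular
    distance from the peak to the two half-height crossings.  A flat curve
    returns ``None``.
    """
    grid = np.arange(0.0, 360.0, grid_step_deg)
    if callable(curve):
        vals = np.asarray(curve(grid), dtype=float)
    else:
        ang, v = curve
        ang = wrap_deg(np.asarray(ang, dtype=float))
        order = np.argsort(ang)
        ang, v = ang[order], np.asarray(v, dtype=float)[order]
        vals = np.interp(grid, np.concatenate([ang, [ang[0] + 360.0]]),
                         np.concatenate([v, [v[0]]]), period=360.0)
    vmax, vmin = vals.max(), vals.min()
    if vmax - vmin <= UNTUNED_RATE_SD:
        return None
    thr = vmin + (vmax - vmin) / 2.0
    peak = int(np.argmax(vals))
    n = len(grid)
    right = 0
    while right < n and vals[(peak + right + 1) % n] > thr:
        right += 1
        if right >= n:
            break
    left = 0
    while left < n and vals[(peak - left - 1) % n] > thr:
        left += 1
        if left >= n:
            break
    return 0.5 * (right + 1 + left + 1) * grid_step_deg


@dataclass
class Field2D:
    """Movement field over (amplitude, direction): Gaussian x von Mises."""

    gain: float            # spikes/s at the field center
    amplitude_mean: float  # deg
    amplitude_sd: float    # deg
    direction: TuningFit
    rss: float = np.nan
    degenerate_amplitude: bool = False


def _field_model(X, gain, a0, sigma, mu, k):
    amp, direction = X
    g = np.exp(-0.5 * ((amp - a0) / sigma) ** 2)
    vm = np.exp(k * (np.cos(np.deg2rad(direction - mu)) - 1.0))
    return gain * g * vm


def fit_field_2d(amplitudes, directions, rates) -> Field2D:
    """Least-squares 2D movement field from per-trial (amplitude, direction,
    movement-epoch rate) points.

    With a single amplitude represented the amplitude dimension is
    unidentifiable: a direction-only fit is returned with the
    ``degenerate_amplitude`` flag set.  All-zero rates give a zero-gain field.
    """
    amp = np.asarray(amplitudes, dtype=float)
    dirs = np.asarray(directions, dtype=float)
    y = np.asarray(rates, dtype=float)
    uniq_amp = np.unique(amp)

    if np.all(np.abs(y) <= UNTUNED_RATE_SD):
        tf = TuningFit(A=0.0, mu_pd=0.0, k=np.nan, rss=0.0, untuned=True)
        return Field2D(gain=0.0, amplitude_mean=float(np.mean(uniq_amp)),
                       amplitude_sd=np.nan, direction=tf, rss=0.0,
                       degenerate_amplitude=len(uniq_amp) < 2)

    if len(uniq_amp) < 2:
        mean_by_dir = _mean_by_direction(dirs, y)
        tf = fit_von_mises(*mean_by_dir)
        return Field2D(gain=float(np.clip(y.max(), 0, None)),
                       amplitude_mean=float(uniq_amp[0]), amplitude_sd=np.nan,
                       direction=tf, rss=tf.rss, degenerate_amplitude=True)

    w = np.clip(y, 0.0, None)
    mu0 = circular_mean_deg(dirs, w) if w.sum() > 0 else 0.0
    k0 = max(_kappa_from_r(resultant_length(dirs, w)), 0.05)
    a00 = float(np.average(amp, weights=w + 1e-9))
    s0 = max(float(np.std(uniq_amp)), 1.0)
    g0 = max(float(y.max()), 1e-3)
    best = None
    for off in (0.0, 90.0, 180.0, 270.0):
        try:
            popt, _ = curve_fit(
                _field_model, (amp, dirs), y, p0=[g0, a00, s0, mu0 + off, k0],
                bounds=([0.0, 0.0, 0.1, -np.inf, 1e-6],
                        [np.inf, 200.0, 500.0, np.inf, 500.0]), maxfev=20000)
        except RuntimeError:
            continue
        resid = _field_model((amp, dirs), *popt) - y
        rss = float(resid @ resid)
        if best is None or rss < best[0]:
            best = (rss, popt)
    if best is None:
        raise RuntimeError("2D field fit failed to converge")
    rss, (gain, a0, sigma, mu, k) = best
    tf = TuningFit(A=float(gain), mu_pd=float(wrap_deg(mu)), k=float(k), rss=rss)
    return Field2D(gain=float(gain), amplitude_mean=float(a0),
                   amplitude_sd=float(sigma), direction=tf, rss=rss)


def _mean_by_direction(directions, rates):
    dirs = np.asarray(directions, dtype=float)
    uniq = np.unique(dirs)
    means = np.array([np.mean(np.asarray(rates)[dirs == d]) for d in uniq])
    return uniq, means


def default_slice_windows(start: float = -30.0, stop: float = 120.0,
                          width: float = 20.0):
    """Contiguous half-open [t, t+width) windows tiling [start, stop].

    The tiling never truncates: the last window may extend past `stop`
    (e.g. -30..120 at 20 ms gives 8 windows, the last being [110, 130))."""
    starts = np.arange(start, stop, width)
    return [(float(s), float(s + width)) for s in starts]


@dataclass
class DynamicField:
    """Per-time-slice movement fields of eye-hand trials."""

    windows: list                 # (start, stop) ms relative to saccade onset
    fields: list = field(default_factory=list)   # Field2D or None per slice

    def preferred_directions(self):
        return [f.direction.mu_pd if f is not None and not f.direction.untuned
                else np.nan for f in self.fields]


def dynamic_fields(amplitudes, directions, slice_rates, windows=None
                   ) -> DynamicField:
    """Fit one movement field per time slice.

    `slice_rates` has shape (n_trials, n_slices): baseline-subtracted rates
    of each trial in each window (relative to saccade onset).  Slices where
    every rate is undefined, or where the fit degenerates, are flagged with
    ``None`` rather than fitted.
    """
    if windows is None:
        windows = default_slice_windows()
    slice_rates = np.asarray(slice_rates, dtype=float)
    if slice_rates.ndim != 2 or slice_rates.shape[1] != len(windows):
        raise ValueError("slice_rates must be n_trials x n_slices")
    out = DynamicField(windows=list(windows))
    for j in range(len(windows)):
        y = slice_rates[:, j]
        ok = np.isfinite(y)
        if ok.sum() < 4 or np.all(y[ok] <= 0):
            out.fields.append(None)
            continue
        try:
            out.fields.append(fit_field_2d(np.asarray(amplitudes)[ok],
                                           np.asarray(directions)[ok], y[ok]))
        except (RuntimeError, ValueError):
            out.fields.append(None)
    return out


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def rayleigh_test(angles_deg):
    """Rayleigh test of circular uniformity; returns (z statistic, p)."""
    a = np.asarray(angles_deg, dtype=float)
    if len(a) < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    from pingouin import circ_rayleigh
    z, p = circ_rayleigh(np.deg2rad(a))
    return float(z), float(p)


@dataclass
class WatsonWilliamsResult:
    statistic: float       # F
    pvalue: float
    low_concentration: bool = False

    def __iter__(self):
        return iter((self.statistic, self.pvalue))


def watson_williams_test(angles_a_deg, angles_b_deg) -> WatsonWilliamsResult:
    """Watson-Williams two-sample test of equal circular means.

    Standard F approximation with the 1 + 3/(8 k) correction factor.  The
    test assumes reasonably concentrated von Mises samples; the
    ``low_concentration`` flag is set when the pooled resultant length falls
    below 0.45 (consider :func:`watson_williams_permutation` there).
    """
    a = np.deg2rad(np.asarray(angles_a_deg, dtype=float))
    b = np.deg2rad(np.asarray(angles_b_deg, dtype=float))
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 5:
        raise ValueError("Watson-Williams needs n >= 5 per group")
    n = n1 + n2
    r1 = resultant_length(np.rad2deg(a)) * n1
    r2 = resultant_length(np.rad2deg(b)) * n2
    all_angles = np.concatenate([np.rad2deg(a), np.rad2deg(b)])
    r = resultant_length(all_angles) * n
    rw = (r1 + r2) / n
    kappa = _kappa_from_r(rw)
    corr = 1.0 + 3.0 / (8.0 * kappa)
    denom = n - (r1 + r2)
    if denom <= 0:
        # both samples perfectly concentrated: means equal iff directions equal
        same = circ_abs_dist_deg(circular_mean_deg(np.rad2deg(a)),
                                 circular_mean_deg(np.rad2deg(b))) < 1e-9
        return WatsonWilliamsResult(0.0 if same else np.inf,
                                    1.0 if same else 0.0, False)
    F = corr * ((n - 2) * (r1 + r2 - r)) / denom
    F = max(F, 0.0)
    p = float(f_dist.sf(F, 1, n - 2))
    return WatsonWilliamsResult(float(F), p, low_concentration=rw < 0.45)


def watson_williams_permutation(angles_a_deg, angles_b_deg, n_perm: int = 2000,
                                seed: int = 0):
    """Permutation test of equal circular means (|circular mean difference|
    as the statistic); validity does not depend on concentration."""
    a = np.asarray(angles_a_deg, dtype=float)
    b = np.asarray(angles_b_deg, dtype=float)
    obs = circ_abs_dist_deg(circular_mean_deg(a), circular_mean_deg(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n1 = len(a)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = circ_abs_dist_deg(circular_mean_deg(perm[:n1]),
                              circular_mean_deg(perm[n1:]))
        if d >= obs:
            count += 1
    return obs, count / (n_perm + 1)
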