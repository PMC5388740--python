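"""Small shared helpers: angle conventions and RNG streams.

Angles are degrees in [0, 360), 0 deg = rightward, counter-clockwise positive.
Times are milliseconds from trial start unless stated otherwise.
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Map angle(s) in degrees onto [0, 360)."""
    return np.mod(angle, 360.0)


def circ_dist_deg(a, b):
    """Signed minimal angular difference a - b in degrees, in (-180, 180]."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0, 360.0) - 180.0
    # keep +180 rather than -180 for the antipodal case
    return np.where(d == -180.0, 180.0, d) if np.ndim(d) else (180.0 if d == -180.0 else float(d))


def circ_abs_dist_deg(a, b):
    """Unsigned minimal angular distance in degrees, in [0, 180]."""
    return np.abs(circ_dist_deg(a, b))


def unit_vector_deg(direction_deg):
    """Unit 2-vector for a direction in degrees (x right, y up)."""
    r = np.deg2rad(direction_deg)
    return np.array([np.cos(r), np.sin(r)])


def substream(*keys) -> np.random.Generator:
    """Independent RNG stream keyed by a tuple of non-negative integers.

    Used so that every trial (and every cell within a trial) has its own
    reproducible stream derived from the session seed.
    """
    return np.random.default_rng([int(k) & 0x7FFFFFFF for k in keys])


def circular_mean_deg(angles_deg, weights=None):
    """(Weighted) circular mean of angles in degrees, in [0, 360)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    return float(wrap_deg(np.rad2deg(np.arctan2(s, c))))


def resultant_length(angles_deg, weights=None) -> float:
    """Mean resultant length R-bar of a sample of angles (0 uniform, 1 concentrated)."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    return float(np.hypot(s, c) / np.sum(w))
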