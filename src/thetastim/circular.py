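"""Circular statistics on angles in degrees.

Phase convention used throughout the package (cosine-referenced analytic
phase): 0 deg = oscillation peak, +/-180 deg = trough, +90 deg = falling
flank, -90 deg = rising flank.  All angles live on the half-open interval
[-180, 180) and all comparisons are circular.
"""

from __future__ import annotations

import numpy as np

#: Quarter-circle phase-bin labels in scan order and their arc centers (deg).
BIN_LABELS = ("peak", "falling", "trough", "rising")
BIN_CENTERS_DEG = {"peak": 0.0, "falling": 90.0, "trough": 180.0, "rising": -90.0}


def wrap_deg(angles):
    """Wrap angles (deg) onto [-180, 180)."""
    return (np.asarray(angles, dtype=float) + 180.0) % 360.0 - 180.0


def circ_diff_deg(a, b):
    """Signed circular difference a - b in degrees, on [-180, 180)."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def resultant_vector(angles_deg):
    """Mean resultant vector of a sample of angles.

    Returns
    -------
    (length, mean_angle_deg) : tuple of float
        ``length`` is in [0, 1]; ``mean_angle_deg`` is on [-180, 180) and is
        meaningless when ``length`` is ~0.
    """
    z = np.exp(1j * np.deg2rad(np.asarray(angles_deg, dtype=float)))
    m = z.mean()
    return float(np.abs(m)), float(wrap_deg(np.rad2deg(np.angle(m))))


def circ_mean_deg(angles_deg):
    """Circular mean angle in degrees."""
    return resultant_vector(angles_deg)[1]


def circ_r(angles_deg):
    """Mean resultant length (a.k.a. R-bar) in [0, 1]."""
    return resultant_vector(angles_deg)[0]


def mean_abs_circ_error_deg(estimates_deg, truth_deg):
    """Mean absolute circular error between two angle series, in degrees."""
    return float(np.mean(np.abs(circ_diff_deg(estimates_deg, truth_deg))))


def assign_phase_bins(phases_deg):
    """Map angles to the four quarter-circle bins.

    Each bin is the half-open arc [center - 45, center + 45) around the
    centers 0 (peak), +90 (falling), +/-180 (trough) and -90 (rising), which
    together partition the circle.

    Returns an array of labels from :data:`BIN_LABELS`.
    """
    phases = wrap_deg(phases_deg)
    idx = np.floor(((phases + 45.0) % 360.0) / 90.0).astype(int)
    return np.asarray(BIN_LABELS, dtype=object)[idx]


def rayleigh_test(angles_deg):
    """Rayleigh test of circular uniformity.

    Uses the statistic z = n * Rbar**2 and the exponential approximation

        p = exp( sqrt(1 + 4 n + 4 (n**2 - R**2)) - (1 + 2 n) ),   R = n * Rbar,

    which is accurate over the full range of z and exact at the two limits
    (Rbar = 0 -> p = 1; Rbar = 1, large n -> p -> 0).  The small-sample
    series correction exp(-z)(1 + (2 z - z**2) / (4 n)) turns negative for
    large z and is therefore not used.

    Parameters
    ----------
    angles_deg : array_like
        Sample of angles in degrees, n >= 3.

    Returns
    -------
    dict with keys ``rbar``, ``z``, ``p``, ``n``.
    """
    angles = np.asarray(angles_deg, dtype=float)
    n = angles.size
    if n < 3:
        raise ValueError(f"Rayleigh test requires n >= 3 angles, got {n}")
    rbar = circ_r(angles)
    big_r = n * rbar
    z = big_r**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))
    return {"rbar": rbar, "z": float(z), "p": float(min(max(p, 0.0), 1.0)), "n": int(n)}


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, None, or Generator into a numpy Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
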