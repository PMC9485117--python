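"""Circular statistics primitives shared across the package.

Angles are degrees in [0, 360) at every public boundary; helpers that work in
radians say so in their names. 0 deg is the arena reference direction,
counter-clockwise positive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_deg",
    "signed_diff_deg",
    "circ_mean_deg",
    "resultant_length",
    "unwrap_deg",
    "circular_gaussian_smooth",
    "rayleigh_z_p",
    "fisher_lee_correlation",
    "circ_interp_deg",
]


def wrap_deg(angles):
    """Wrap angles to [0, 360).

    Folds the float edge case (-tiny) % 360 == 360.0 back to 0.
    """
    out = np.asarray(angles, dtype=float) % 360.0
    return np.where(out >= 360.0, 0.0, out)


def signed_diff_deg(a, b):
    """Shortest signed angular difference a - b, in (-180, 180].

    Computed as arctan2(sin(a-b), cos(a-b)); the antipodal case maps to +180.
    """
    d = np.radians(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
    out = np.degrees(np.arctan2(np.sin(d), np.cos(d)))
    # arctan2(-0.0, -1.0) yields -180; fold onto +180 so the range is (-180, 180]
    return np.where(np.isclose(out, -180.0), 180.0, out)


def circ_mean_deg(angles, weights=None):
    """Weighted circular mean of angles (deg), result in [0, 360)."""
    a = np.radians(np.asarray(angles, dtype=float))
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, dtype=float)
    s = np.sum(w * np.sin(a))
    c = np.sum(w * np.cos(a))
    if s == 0.0 and c == 0.0:
        raise ValueError("circular mean undefined: zero resultant")
    return float(wrap_deg(np.degrees(np.arctan2(s, c))))


def resultant_length(angles, weights=None):
    """Weighted mean resultant length R-bar in [0, 1]."""
    a = np.radians(np.asarray(angles, dtype=float))
    if weights is None:
        weights = np.ones_like(a)
    w = np.asarray(weights, dtype=float)
    tot = np.sum(w)
    if tot <= 0:
        raise ValueError("resultant undefined for non-positive total weight")
    s = np.sum(w * np.sin(a)) / tot
    c = np.sum(w * np.cos(a)) / tot
    return float(min(1.0, np.hypot(s, c)))


def unwrap_deg(angles):
    """Unwrap a degree series so consecutive steps are in (-180, 180]."""
    return np.degrees(np.unwrap(np.radians(np.asarray(angles, dtype=float))))


def _gauss_kernel(sd, truncate=4.0):
    if sd <= 0:
        return np.array([1.0])
    half = int(np.ceil(truncate * sd))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


def circular_gaussian_smooth(values, sd_bins, truncate=4.0):
    """Smooth a circular (wrap-around) binned signal with a Gaussian kernel.

    The kernel is truncated at ``truncate`` standard deviations, wrapped, and
    renormalized, so the sum of the signal is conserved exactly.
    """
    v = np.asarray(values, dtype=float)
    k = _gauss_kernel(sd_bins, truncate)
    if k.size == 1:
        return v.copy()
    n = v.size
    half = k.size // 2
    idx = (np.arange(n)[:, None] - np.arange(-half, half + 1)[None, :]) % n
    return (v[idx] * k[None, :]).sum(axis=1)


def rayleigh_z_p(r_bar, n):
    """Rayleigh test statistic z = n * R-bar^2 and its p-value.

    Uses the standard large-sample approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with R = n * R-bar
    (Zar's formulation, the one circular-statistics packages implement).
    """
    if n <= 0:
        raise ValueError("Rayleigh test requires n > 0")
    r_bar = float(r_bar)
    big_r = n * r_bar
    z = n * r_bar**2
    arg = 1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)
    p = np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return float(z), float(min(1.0, p))


def fisher_lee_correlation(angles_a, angles_b):
    """Fisher–Lee circular–circular correlation coefficient in [-1, 1].

    r = sum_{i<j} sin(ai-aj) sin(bi-bj) /
        sqrt( sum_{i<j} sin^2(ai-aj) * sum_{i<j} sin^2(bi-bj) )
    """
    a = np.radians(np.asarray(angles_a, dtype=float))
    b = np.radians(np.asarray(angles_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("angle series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 angle pairs")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    num = np.sum(np.triu(sa * sb, 1))
    den = np.sum(np.triu(sa**2, 1)) * np.sum(np.triu(sb**2, 1))
    if den <= 0:
        raise ValueError("circular correlation undefined for constant input")
    return float(num / np.sqrt(den))


def circ_interp_deg(t, tp, ap):
    """Interpolate an angular series (deg) linearly on the circle.

    Interpolates unit vectors then takes the angle, which follows the shorter
    arc between neighbouring samples.
    """
    ar = np.radians(np.asarray(ap, dtype=float))
    s = np.interp(t, tp, np.sin(ar))
    c = np.interp(t, tp, np.cos(ar))
    return wrap_deg(np.degrees(np.arctan2(s, c)))
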