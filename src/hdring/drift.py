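"""Drift of the population representation relative to the actual direction.

The angular difference between actual and ring-decoded head direction,
Ang_diff = arctan2(sin(HD_actual - HD_iso), cos(HD_actual - HD_iso)),
is unwrapped, smoothed (Gaussian s.d. = 2 samples on the 200 ms grid) and
differentiated; its absolute rate of change is the angular drift velocity
(ADV). ADV is compared with the angular head velocity (AHV) per session, with
a cross-session null (each session's AHV paired with every other session's
ADV). Under-signaling of head turns by the attractor is quantified by the
through-origin regression slope of decoded on actual AHV and by the total
angular distance traveled on the manifold vs by the animal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import pearsonr

from ._circ import signed_diff_deg, unwrap_deg
from .session_io import TrackingTrace

SMOOTH_SD_SAMPLES = 2.0
EDGE_TRIM = int(np.ceil(4 * SMOOTH_SD_SAMPLES))   # half the truncated kernel
GRID_DT = 0.2


@dataclass
class DriftTrace:
    """Aligned 200 ms series of actual vs decoded direction and velocities."""

    times: np.ndarray
    hd_actual: np.ndarray            # deg
    hd_iso: np.ndarray               # deg
    ang_diff: np.ndarray             # deg in (-180, 180]
    unwrapped_smoothed_diff: np.ndarray
    adv: np.ndarray                  # deg/s, absolute, edge-trimmed grid
    ahv: np.ndarray                  # deg/s, signed, same grid as adv


@dataclass
class DriftStats:
    """Session-level drift summaries."""

    adv_mean: float                       # deg/s
    ahv_adv_pearson: tuple[float, float]  # (r, p)
    total_angular_distance_actual: float  # deg
    total_angular_distance_manifold: float
    ahv_undersignal_slope: float


def angular_difference(actual_deg, decoded_deg) -> np.ndarray:
    """Shortest signed difference actual - decoded, in (-180, 180]."""
    a = np.asarray(actual_deg, dtype=float)
    d = np.asarray(decoded_deg, dtype=float)
    if a.shape != d.shape:
        raise ValueError("series must have equal length")
    return signed_diff_deg(a, d)


def drift_velocity(ang_diff, dt: float = GRID_DT,
                   smooth_sd: float = SMOOTH_SD_SAMPLES
                   ) -> tuple[np.ndarray, float, np.ndarray]:
    """Angular drift velocity from an angular-difference series.

    Unwraps, smooths with a Gaussian kernel, takes the first difference over
    ``dt`` and trims half a kernel width at each edge. Returns
    (adv_series, adv_mean, unwrapped_smoothed_series); adv is the absolute
    rate of change and adv_mean its average.
    """
    x = np.asarray(ang_diff, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    unwrapped = unwrap_deg(x)
    smoothed = gaussian_filter1d(unwrapped, smooth_sd, mode="nearest")
    rate = np.abs(np.diff(smoothed)) / dt
    trim = int(np.ceil(4 * smooth_sd))
    if rate.size > 2 * trim:
        core = rate[trim:rate.size - trim]
    else:
        core = rate
    return core, float(core.mean()), smoothed


def ahv(trace: TrackingTrace, dt: float = GRID_DT) -> tuple[np.ndarray, np.ndarray]:
    """Signed angular head velocity on the 200 ms grid (deg/s).

    The head direction is unwrapped at the tracking rate, sampled at the grid
    points, and differenced. Returns (grid_times, ahv_series) with the series
    one element shorter than the grid.
    """
    t = trace.timestamps
    unwrapped = unwrap_deg(trace.head_direction)
    grid = np.arange(t[0], t[-1] + 1e-9, dt)
    u = np.interp(grid, t, unwrapped)
    return grid, np.diff(u) / dt


def drift_trace(actual_deg, decoded_deg, times=None,
                dt: float = GRID_DT) -> DriftTrace:
    """Assemble the drift series for one session (aligned 200 ms series)."""
    actual = np.asarray(actual_deg, dtype=float)
    decoded = np.asarray(decoded_deg, dtype=float)
    ok = np.isfinite(decoded)
    actual, decoded = actual[ok], decoded[ok]
    if times is None:
        times = np.arange(actual.size) * dt
    else:
        times = np.asarray(times, dtype=float)[ok]
    diff = angular_difference(actual, decoded)
    adv_series, _, smoothed = drift_velocity(diff, dt)
    ahv_series = np.diff(unwrap_deg(actual)) / dt
    trim = (ahv_series.size - adv_series.size) // 2
    if trim > 0:
        ahv_series = ahv_series[trim:trim + adv_series.size]
    return DriftTrace(times=times, hd_actual=actual, hd_iso=decoded,
                      ang_diff=diff, unwrapped_smoothed_diff=smoothed,
                      adv=adv_series, ahv=ahv_series)


def drift_stats(trace: DriftTrace) -> DriftStats:
    """Session-level summaries from an assembled DriftTrace."""
    r, p = pearsonr(np.abs(trace.ahv), trace.adv)
    d_actual, d_manifold = angular_distances(trace.hd_actual, trace.hd_iso)
    dt = float(np.median(np.diff(trace.times))) if trace.times.size > 1 else GRID_DT
    decoded_ahv = np.diff(unwrap_deg(trace.hd_iso)) / dt
    actual_ahv = np.diff(unwrap_deg(trace.hd_actual)) / dt
    slope, _ = ahv_undersignaling(actual_ahv, decoded_ahv)
    return DriftStats(adv_mean=float(trace.adv.mean()),
                      ahv_adv_pearson=(float(r), float(p)),
                      total_angular_distance_actual=d_actual,
                      total_angular_distance_manifold=d_manifold,
                      ahv_undersignal_slope=slope)


def ahv_adv_correlation(sessions: list[tuple[np.ndarray, np.ndarray]],
                        signed: bool = False):
    """Per-session AHV-ADV correlation with a cross-session null.

    ``sessions`` is a list of (ahv_series, adv_series) pairs. For each session
    the Pearson r between |AHV| (or signed AHV if ``signed``) and ADV is
    computed; the null pairs each session's AHV with every *other* session's
    ADV (series truncated to the common length), one r per ordered pair. A
    session is flagged significant iff p < 0.05 and |r| exceeds the 99th
    percentile of the null |r| distribution.

    Returns a list of dicts (r, p, significant) and the null |r| array; with
    a single session the null is empty and the flag is None.
    """
    results = []
    for a, d in sessions:
        n = min(len(a), len(d))
        r, p = pearsonr(np.abs(a[:n]) if not signed else a[:n], d[:n])
        results.append({"r": float(r), "p": float(p), "significant": None})
    null = []
    for i, (a, _) in enumerate(sessions):
        for j, (_, d) in enumerate(sessions):
            if i == j:
                continue
            n = min(len(a), len(d))
            r, _ = pearsonr(np.abs(a[:n]) if not signed else a[:n], d[:n])
            null.append(abs(r))
    null = np.asarray(null)
    if null.size:
        thresh = np.percentile(null, 99)
        for res in results:
            res["significant"] = bool(res["p"] < 0.05 and abs(res["r"]) > thresh)
    return results, null


def angular_distances(actual_deg, decoded_deg) -> tuple[float, float]:
    """Total angular distance traveled (deg): sum of absolute wrapped steps,
    for the actual and the decoded series."""
    a = np.asarray(actual_deg, dtype=float)
    d = np.asarray(decoded_deg, dtype=float)
    da = float(np.sum(np.abs(signed_diff_deg(a[1:], a[:-1]))))
    dd = float(np.sum(np.abs(signed_diff_deg(d[1:], d[:-1]))))
    return da, dd


def ahv_undersignaling(actual_ahv, decoded_ahv, n_bins: int = 8):
    """Through-origin regression of decoded on actual AHV plus an error
    profile binned by |actual AHV|.

    Returns (slope, DataFrame[bin_center, mean_abs_error, n]). A slope below 1
    means the manifold under-signals head turns.
    """
    import pandas as pd

    x = np.asarray(actual_ahv, dtype=float)
    y = np.asarray(decoded_ahv, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValueError("actual AHV is identically zero")
    slope = float(np.sum(x * y) / denom)
    mag = np.abs(x)
    edges = np.quantile(mag, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    idx = np.clip(np.searchsorted(edges, mag, side="right") - 1, 0, n_bins - 1)
    err = np.abs(y - x)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if m.any():
            rows.append((0.5 * (edges[b] + edges[b + 1]), float(err[m].mean()),
                         int(m.sum())))
    profile = pd.DataFrame(rows, columns=["bin_center", "mean_abs_error", "n"])
    return slope, profile
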