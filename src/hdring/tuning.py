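"""Tuning-curve construction and per-cell head-direction metrics.

A tuning curve is the occupancy-normalized firing rate over sixty 6-degree
bins of head direction. Spikes are assigned the angle of the temporally
nearest tracking sample; spike counts and occupancy are accumulated per bin;
the rate is counts/occupancy, then smoothed with a wrapped Gaussian kernel
(s.d. = 3 bins, truncated at 4 s.d., renormalized). Normalizing before
smoothing keeps the peak estimate free of occupancy-gradient bias, and the
wrapped kernel sums to one, so smoothing conserves the rate integral
exactly; the unsmoothed rate times occupancy recovers the spike count
exactly.

All scalar metrics (vector length, mutual information in bits/spike, FWHM
tuning width, preferred firing direction, Rayleigh z/p) are computed from the
tuning curve, so they inherit the occupancy correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._circ import (
    circ_mean_deg,
    circular_gaussian_smooth,
    fisher_lee_correlation,
    rayleigh_z_p,
)
from .session_io import TrackingTrace, UnitSpikes

N_BINS_DEFAULT = 60


@dataclass
class TuningCurve:
    """Occupancy-normalized, smoothed firing rate vs head-direction angle."""

    bin_centers: np.ndarray    # deg
    occupancy: np.ndarray      # s per bin (sums to tracked duration)
    raw_counts: np.ndarray     # spikes per bin
    rate: np.ndarray           # Hz per bin (smoothed)
    smoothing_sd: float        # bins
    rate_unsmoothed: np.ndarray = None   # Hz per bin, counts/occupancy

    def __post_init__(self):
        if self.rate_unsmoothed is None:
            self.rate_unsmoothed = self.rate
        for name in ("occupancy", "raw_counts", "rate"):
            if np.any(np.asarray(getattr(self, name)) < -1e-12):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    @property
    def n_spikes(self) -> int:
        return int(round(float(np.sum(self.raw_counts))))

    @property
    def spike_mass(self) -> float:
        """Unsmoothed rate integrated against occupancy; equals the spike
        count up to floating error (smoothing conserves the rate integral,
        see module docstring)."""
        return float(np.sum(self.rate_unsmoothed * self.occupancy))


def compute_tuning_curve(spikes: UnitSpikes, trace: TrackingTrace,
                         interval: tuple[float, float] | None = None,
                         bin_deg: float = 6.0,
                         smoothing_sd: float = 3.0) -> TuningCurve:
    """Build a tuning curve over ``interval`` (default: the whole trace)."""
    t = trace.timestamps
    if interval is None:
        interval = (float(t[0]), float(t[-1]))
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("empty interval")
    n_bins = int(round(360.0 / bin_deg))
    if not np.isclose(n_bins * bin_deg, 360.0):
        raise ValueError("bin_deg must divide 360")

    in_win = (t >= t0) & (t < t1)
    if not in_win.any():
        raise ValueError("tracking does not cover the interval")
    dt = 1.0 / trace.sample_rate
    ang = trace.head_direction[in_win]
    bins = np.minimum((ang / bin_deg).astype(int), n_bins - 1)
    occupancy = np.bincount(bins, minlength=n_bins).astype(float) * dt
    if occupancy.sum() <= 0:
        raise ValueError("zero total occupancy in interval")

    st = spikes.spike_times
    st = st[(st >= t0) & (st < t1)]
    # temporally nearest tracking sample
    idx = np.searchsorted(t, st)
    idx = np.clip(idx, 1, t.size - 1)
    nearer_left = (st - t[idx - 1]) < (t[idx] - st)
    idx = np.where(nearer_left, idx - 1, idx)
    sbins = np.minimum((trace.head_direction[idx] / bin_deg).astype(int), n_bins - 1)
    counts = np.bincount(sbins, minlength=n_bins).astype(float)

    zero = occupancy <= 0
    if zero.any() and counts[zero].any():
        warnings.warn("spikes in bins with zero occupancy; rate set to 0 there")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_rate = np.where(~zero, counts / np.where(~zero, occupancy, 1.0), 0.0)
    rate = circular_gaussian_smooth(raw_rate, smoothing_sd)

    centers = (np.arange(n_bins) + 0.5) * bin_deg
    return TuningCurve(bin_centers=centers, occupancy=occupancy,
                       raw_counts=counts, rate=rate, smoothing_sd=smoothing_sd,
                       rate_unsmoothed=raw_rate)


def vector_length(curve: TuningCurve) -> float:
    """Mean resultant length of the rate-weighted bin directions, in [0, 1]:
    0 for a uniform curve, 1 with all mass at one angle."""
    total = float(np.sum(curve.rate))
    if total <= 0:
        raise ValueError("vector length undefined for an all-zero curve")
    a = np.radians(curve.bin_centers)
    s = np.sum(curve.rate * np.sin(a)) / total
    c = np.sum(curve.rate * np.cos(a)) / total
    return float(min(1.0, np.hypot(s, c)))


def mutual_information(curve: TuningCurve) -> float:
    """Directional information in bits/spike:
    I = sum_j P_j (lambda_j / lambda) log2(lambda_j / lambda), with P_j the
    occupancy probability of bin j and lambda the occupancy-weighted mean
    rate. Zero-rate bins contribute 0."""
    occ = curve.occupancy
    p = occ / occ.sum()
    lam_j = curve.rate
    lam = float(np.sum(p * lam_j))
    if lam <= 0:
        raise ValueError("mutual information undefined for zero mean rate")
    ratio = lam_j / lam
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def tuning_width(curve: TuningCurve) -> tuple[float, bool]:
    """Full width at half maximum (deg) around the preferred direction.

    Linear interpolation in angle at the half-max crossings nearest the peak.
    Returns (width, full_circle_flag); a curve that never falls below half max
    yields (360, True).
    """
    rate = curve.rate
    peak = float(rate.max())
    if peak <= 0:
        raise ValueError("tuning width undefined for an all-zero curve")
    half = peak / 2.0
    n = rate.size
    j = int(np.argmax(rate))
    bin_w = 360.0 / n
    if rate.min() >= half:
        return 360.0, True

    def cross(direction):
        # walk from the peak until rate drops below half; interpolate
        dist = 0.0
        k = j
        for _ in range(n):
            k2 = (k + direction) % n
            if rate[k2] < half:
                frac = (rate[k] - half) / (rate[k] - rate[k2])
                return dist + frac * bin_w
            dist += bin_w
            k = k2
        return dist  # unreachable given the min() check

    return float(cross(+1) + cross(-1)), False


def rayleigh_test(curve: TuningCurve) -> tuple[float, float]:
    """Rayleigh test of circular non-uniformity on the occupancy-corrected
    tuning curve: z = n * R-bar^2 with n the spike count and R-bar the curve's
    resultant (vector_length)."""
    n = curve.n_spikes
    if n == 0:
        raise ValueError("Rayleigh test requires at least one spike")
    return rayleigh_z_p(vector_length(curve), n)


def preferred_firing_direction(curve: TuningCurve) -> float:
    """PFD: center of the bin with the highest normalized rate (ties -> the
    smallest angle)."""
    if curve.rate.max() <= 0:
        raise ValueError("PFD undefined for an all-zero curve")
    return float(curve.bin_centers[int(np.argmax(curve.rate))])


def mean_pfd(angles) -> float:
    """Circular mean of a set of angles (deg), in [0, 360)."""
    return circ_mean_deg(angles)


@dataclass
class HDMetrics:
    """Per-cell scalar summaries of head-direction tuning."""

    unit_id: str
    mean_rate: float       # Hz, temporal average
    peak_rate: float       # Hz, max of the normalized smoothed curve
    vector_length: float
    tuning_width: float    # deg FWHM
    width_full_circle: bool
    mutual_info: float     # bits/spike
    pfd: float             # deg
    mean_pfd: float        # deg
    rayleigh_z: float
    rayleigh_p: float


def compute_hd_metrics(spikes: UnitSpikes, trace: TrackingTrace,
                       interval: tuple[float, float] | None = None,
                       bin_deg: float = 6.0,
                       smoothing_sd: float = 3.0) -> HDMetrics:
    """All per-cell metrics from one pass over the data."""
    curve = compute_tuning_curve(spikes, trace, interval, bin_deg, smoothing_sd)
    t0 = trace.timestamps[0] if interval is None else interval[0]
    t1 = trace.timestamps[-1] if interval is None else interval[1]
    n_spk = curve.n_spikes
    if n_spk == 0:
        raise ValueError(f"unit {spikes.unit_id}: no spikes in interval")
    z, p = rayleigh_test(curve)
    width, flag = tuning_width(curve)
    st = spikes.spike_times
    st = st[(st >= t0) & (st < t1)]
    # circular mean of per-spike angles for mean PFD
    idx = np.clip(np.searchsorted(trace.timestamps, st), 0, trace.timestamps.size - 1)
    return HDMetrics(
        unit_id=spikes.unit_id,
        mean_rate=n_spk / (t1 - t0),
        peak_rate=float(curve.rate.max()),
        vector_length=vector_length(curve),
        tuning_width=width,
        width_full_circle=flag,
        mutual_info=mutual_information(curve),
        pfd=preferred_firing_direction(curve),
        mean_pfd=circ_mean_deg(trace.head_direction[idx]),
        rayleigh_z=z,
        rayleigh_p=p,
    )


def split_half_stability(units: list[UnitSpikes], trace: TrackingTrace,
                         bin_deg: float = 6.0, smoothing_sd: float = 3.0):
    """Per-cell preferred directions in the two session halves and their
    Fisher–Lee circular correlation across cells.

    Cells with no spikes in either half are excluded (and reported).
    Returns (DataFrame[unit_id, pfd_first, pfd_second], r, excluded_ids).
    """
    import pandas as pd

    t0, t1 = float(trace.timestamps[0]), float(trace.timestamps[-1])
    tm = 0.5 * (t0 + t1)
    rows, excluded = [], []
    for u in units:
        try:
            c1 = compute_tuning_curve(u, trace, (t0, tm), bin_deg, smoothing_sd)
            c2 = compute_tuning_curve(u, trace, (tm, t1), bin_deg, smoothing_sd)
            if c1.n_spikes == 0 or c2.n_spikes == 0:
                raise ValueError("empty half")
            rows.append((u.unit_id, preferred_firing_direction(c1),
                         preferred_firing_direction(c2)))
        except ValueError:
            excluded.append(u.unit_id)
    df = pd.DataFrame(rows, columns=["unit_id", "pfd_first", "pfd_second"])
    if len(df) < 2:
        raise ValueError("need >= 2 cells with spikes in both halves")
    r = fisher_lee_correlation(df["pfd_first"], df["pfd_second"])
    return df, r, excluded
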