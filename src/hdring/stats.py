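"""Rotation-gain, behavioral and grouped-variance statistics.

The field's named experimental scores implemented here:

* cue/floor rotation gain, Gain = |dPFD| / |dcue|, with a shuffle null built
  by assigning experimental rotation angles to unmanipulated re-exposure
  sessions;
* observed-vs-expected PFD shift with circular correlation across animals;
* 360-degree head-turn epochs (cumulative absolute rotation) and per-epoch
  vector length with spike-count-matched full-session controls;
* the chamber-preference score CP = (t_neut - t_avers) / (t_neut + t_avers);
* intraclass correlation ICC = sigma_b^2 / (sigma_b^2 + sigma_e^2) via the
  one-way random-effects ANOVA estimator with negative-variance truncation;
* the Fisher-Lee circular correlation.

Generic group comparisons (Mann-Whitney, Wilcoxon, Bonferroni) are left to
scipy/statsmodels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._circ import circ_mean_deg, fisher_lee_correlation, signed_diff_deg, unwrap_deg
from .session_io import TrackingTrace, UnitSpikes
from .tuning import compute_tuning_curve, vector_length


@dataclass
class RotationResult:
    """Per-cell cue-control result."""

    delta_pfd: float       # deg, wrapped signed PFD change
    delta_cue: float       # deg, 90 or 180
    gain: float            # |delta_pfd| / |delta_cue|
    expected_shift: float  # deg
    observed_shift: float  # deg

    def __post_init__(self):
        if abs(self.delta_pfd) > 180 or self.gain < 0:
            raise ValueError("invalid rotation result")


@dataclass
class ChamberOccupancy:
    """Dwell times in the two-chamber odor test."""

    t_neut: float
    t_avers: float
    cp: float = field(init=False)

    def __post_init__(self):
        if self.t_neut < 0 or self.t_avers < 0:
            raise ValueError("dwell times must be >= 0")
        if self.t_neut + self.t_avers <= 0:
            raise ValueError("total dwell time must be positive")
        self.cp = (self.t_neut - self.t_avers) / (self.t_neut + self.t_avers)


@dataclass
class ICCResult:
    """One-way random-effects variance components and their ratio."""

    sigma_b_sq: float
    sigma_e_sq: float
    icc: float

    def __post_init__(self):
        if self.sigma_b_sq < 0 or self.sigma_e_sq < 0:
            raise ValueError("variance components must be >= 0 after truncation")
        if not (0.0 <= self.icc <= 1.0):
            raise ValueError("ICC must be in [0, 1]")


@dataclass
class EpochSet:
    """Non-overlapping intervals each spanning 360 deg of cumulative
    absolute head rotation."""

    intervals: list[tuple[float, float]]

    @property
    def mean_duration(self) -> float:
        if not self.intervals:
            return float("nan")
        return float(np.mean([b - a for a, b in self.intervals]))


def rotation_gain(pfd_pre: float, pfd_post: float, delta_cue: float) -> RotationResult:
    """Cue-control gain of one cell: Gain = |dPFD| / |dcue|."""
    if abs(delta_cue) not in (90.0, 180.0):
        raise ValueError("delta_cue must be +-90 or +-180 degrees")
    d = float(signed_diff_deg(pfd_post, pfd_pre))
    return RotationResult(delta_pfd=d, delta_cue=float(delta_cue),
                          gain=abs(d) / abs(delta_cue),
                          expected_shift=float(delta_cue), observed_shift=d)


def rotation_shuffle_null(reexposure_pfd_pairs, rotation_angles,
                          n: int = 10000, seed: int = 0) -> np.ndarray:
    """Null gain distribution from unmanipulated re-exposure sessions.

    Each shuffle draws a re-exposure (pfd_1, pfd_2) pair and an experimental
    rotation angle, and computes the gain the pair's spontaneous PFD change
    would imply under that rotation.
    """
    pairs = np.asarray(reexposure_pfd_pairs, dtype=float)
    angles = np.asarray(rotation_angles, dtype=float)
    if pairs.size == 0 or angles.size == 0:
        raise ValueError("need at least one re-exposure pair and one angle")
    rng = np.random.default_rng(seed)
    pi = rng.integers(0, pairs.shape[0], size=n)
    ai = rng.integers(0, angles.size, size=n)
    dpfd = signed_diff_deg(pairs[pi, 1], pairs[pi, 0])
    return np.abs(dpfd) / np.abs(angles[ai])


def expected_vs_observed_shift(per_animal_delta_pfds, rotations_deg):
    """Observed mean PFD shift per animal vs the imposed rotation.

    ``per_animal_delta_pfds`` is a list (one entry per animal) of per-cell
    signed PFD changes; ``rotations_deg`` the imposed rotation per animal.
    Returns (observed array deg, circular r). Fewer than 3 animals still
    yields r but is statistically weak.
    """
    observed = np.array([circ_mean_deg(d) for d in per_animal_delta_pfds])
    expected = np.asarray(rotations_deg, dtype=float) % 360.0
    if observed.size != expected.size:
        raise ValueError("one rotation per animal required")
    r = fisher_lee_correlation(observed, expected)
    return observed, float(r)


def head_turn_epochs(trace: TrackingTrace, turn_deg: float = 360.0,
                     cumulative_abs: bool = True) -> EpochSet:
    """Greedy segmentation into epochs of ``turn_deg`` cumulative rotation.

    By default rotation accumulates in absolute value (a back-and-forth of
    +-180 deg completes a 360 epoch); set ``cumulative_abs=False`` for net
    rotation. The trailing incomplete epoch is discarded.
    """
    t = trace.timestamps
    u = unwrap_deg(trace.head_direction)
    steps = np.diff(u)
    acc = np.cumsum(np.abs(steps) if cumulative_abs else steps)
    intervals = []
    start_idx = 0
    base = 0.0
    for k in range(acc.size):
        moved = abs(acc[k] - base)
        if moved >= turn_deg:
            intervals.append((float(t[start_idx]), float(t[k + 1])))
            start_idx = k + 1
            base = acc[k]
    return EpochSet(intervals=intervals)


def epoch_vector_length(spikes: UnitSpikes, trace: TrackingTrace,
                        epochs: EpochSet, seed: int = 0,
                        bin_deg: float = 6.0, smoothing_sd: float = 0.0):
    """Per-epoch tuning-curve vector length with spike-count-matched control.

    For each complete head-turn epoch the cell's vector length is computed
    from an epoch tuning curve (unsmoothed by default: epochs are short); the
    control draws, for each epoch, the same number of spikes from the whole
    session (seeded, without replacement) and computes the vector length on
    the full-session trace. Epochs without spikes are skipped.

    Returns (per_epoch_vl array, mean_vl, matched_control_vl).
    """
    if not epochs.intervals:
        raise ValueError("no complete epochs")
    rng = np.random.default_rng(seed)
    all_spikes = spikes.spike_times
    vls, controls = [], []
    for (a, b) in epochs.intervals:
        try:
            curve = compute_tuning_curve(spikes, trace, (a, b), bin_deg, smoothing_sd)
        except ValueError:
            continue
        n = curve.n_spikes
        if n == 0:
            continue
        vls.append(vector_length(curve))
        take = min(n, all_spikes.size)
        sub = np.sort(rng.choice(all_spikes, take, replace=False))
        ctrl_curve = compute_tuning_curve(
            UnitSpikes(unit_id=spikes.unit_id, spike_times=sub), trace,
            None, bin_deg, smoothing_sd)
        controls.append(vector_length(ctrl_curve))
    if not vls:
        raise ValueError("no epoch contained spikes")
    vls = np.asarray(vls)
    return vls, float(vls.mean()), float(np.mean(controls))


def chamber_preference(occ: ChamberOccupancy) -> float:
    """CP = (t_neut - t_avers) / (t_neut + t_avers), in [-1, 1]: +1 when the
    whole session is spent in the neutral chamber, -1 in the aversive one."""
    return occ.cp


def icc(values, groups) -> ICCResult:
    """Intraclass correlation via one-way random-effects ANOVA.

    sigma_e^2 = MSW; sigma_b^2 = max(0, (MSB - MSW) / n0) with n0 the
    balanced-design-adjusted mean group size; ICC = sigma_b^2 /
    (sigma_b^2 + sigma_e^2).
    """
    df = pd.DataFrame({"v": np.asarray(values, dtype=float),
                       "g": np.asarray(groups)})
    sizes = df.groupby("g")["v"].count()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("ICC needs >= 2 groups with >= 2 values each")
    k = len(sizes)
    n_tot = len(df)
    grand = df["v"].mean()
    means = df.groupby("g")["v"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["v"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n_tot - k)
    n0 = (n_tot - float((sizes**2).sum()) / n_tot) / (k - 1)
    sigma_b = max(0.0, (msb - msw) / n0)
    sigma_e = msw
    total = sigma_b + sigma_e
    val = sigma_b / total if total > 0 else 0.0
    return ICCResult(sigma_b_sq=sigma_b, sigma_e_sq=sigma_e, icc=val)


def icc_from_variances(sigma_b_sq: float, sigma_e_sq: float) -> ICCResult:
    """ICC directly from known variance components."""
    if sigma_b_sq < 0 or sigma_e_sq < 0:
        raise ValueError("variances must be >= 0")
    total = sigma_b_sq + sigma_e_sq
    if total <= 0:
        raise ValueError("total variance must be positive")
    return ICCResult(sigma_b_sq=sigma_b_sq, sigma_e_sq=sigma_e_sq,
                     icc=sigma_b_sq / total)


def circular_correlation(angles_a, angles_b) -> float:
    """Fisher-Lee circular correlation coefficient, in [-1, 1]."""
    return fisher_lee_correlation(angles_a, angles_b)
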