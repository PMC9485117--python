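"""Synthetic ring-attractor sessions with known ground truth.

The generator produces phenomenological head-direction (HD) data with the
statistical structure the analyses assume, not a biophysical attractor model:

* a smoothly autocorrelated head trajectory (Ornstein–Uhlenbeck angular
  velocity integrated on the circle, reflected random-walk position);
* an *internal* direction that is either anchored to the true head direction,
  offset by a cue rotation scaled by a gain, or drifting (a fraction
  ``ahv_gain`` of the true angular head velocity is integrated, plus Brownian
  diffusion) — emulating a ring attractor that loses its allothetic anchor;
* HD cells firing as inhomogeneous Poisson processes with von Mises tuning to
  the internal direction, thinned by an absolute refractory period;
* non-HD cells firing as direction-independent Poisson processes with a slow
  log-normal rate envelope (a documented stand-in: their autocorrelograms
  differ from HD cells through firing statistics only, never label leakage);
* a two-chamber occupancy trace (alternating exponential dwells) for the
  odor-preference score.

Every generator is a pure function of (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._circ import unwrap_deg, wrap_deg
from .session_io import SessionRecording, TrackingTrace, UnitSpikes

__all__ = [
    "TrajectoryParams",
    "PopulationParams",
    "AnchoringParams",
    "simulate_trajectory",
    "internal_direction",
    "simulate_population",
    "simulate_two_chamber",
    "simulate_session",
    "simulate_rotation_pair",
]

# Non-HD stand-in firing statistics (documented in the methods note):
# slow log-normal rate envelope exp(OU) with these parameters.
NONHD_ENVELOPE_TAU_S = 5.0
NONHD_ENVELOPE_LOG_SD = 0.5
NONHD_MEAN_RATE_RANGE_HZ = (3.0, 15.0)

# Thalamic HD cells fire high-frequency spike bursts; the resulting short-lag
# autocorrelogram peak is their classic signature and what the ACG classifier
# keys on. Each base spike spawns Binomial(max, p) extra spikes at ~4 ms
# intervals; base intensity is scaled so the stated rates are preserved.
HD_BURST_EXTRA_MAX = 2
HD_BURST_EXTRA_P = 0.25
HD_BURST_ISI_S = 0.004
HD_BURST_ISI_JITTER_S = 0.001

# Mean neutral+aversive dwell cycle of the two-chamber process.
CHAMBER_CYCLE_S = 30.0

_POSITION_SPEED_SD_CM_S = 8.0


@dataclass
class TrajectoryParams:
    """Head-trajectory model parameters.

    Angular head velocity (AHV) follows an Ornstein–Uhlenbeck process with
    relaxation time ``ahv_relaxation_tau`` and stationary standard deviation
    ``ahv_stddev``; head direction is its integral wrapped to [0, 360).
    ``occupancy_bias_kappa`` > 0 adds a von Mises restoring drift toward one
    direction, producing the biased angular-occupancy histograms seen in
    freely moving animals.
    """

    duration: float = 600.0           # s (10-min open-field session)
    sample_rate: float = 120.0        # Hz (camera frame rate)
    ahv_relaxation_tau: float = 1.0   # s
    ahv_stddev: float = 18.0          # deg/s -> mean |AHV| ~ 14 deg/s, one
                                      # full head turn every ~25 s
    arena_radius: float = 30.0        # cm (60 cm diameter arena)
    occupancy_bias_kappa: float = 0.0
    occupancy_bias_dir: float = 0.0   # deg

    def validate(self):
        if self.duration <= 0 or self.sample_rate <= 0 or self.arena_radius <= 0:
            raise ValueError("duration, sample_rate and arena_radius must be positive")
        if self.ahv_relaxation_tau <= 0 or self.ahv_stddev < 0:
            raise ValueError("invalid AHV process parameters")
        if self.occupancy_bias_kappa < 0:
            raise ValueError("occupancy_bias_kappa must be >= 0")


@dataclass
class PopulationParams:
    """Population composition and tuning-parameter ranges."""

    n_hd_cells: int = 40
    n_non_hd_cells: int = 10
    pfd_list: list[float] | None = None     # deg; None -> uniform random
    kappa_range: tuple[float, float] = (2.0, 6.0)
    peak_rate_range: tuple[float, float] = (10.0, 30.0)   # Hz
    baseline_rate_range: tuple[float, float] = (0.1, 2.0)  # Hz
    refractory: float = 0.002                # s

    def validate(self):
        if self.n_hd_cells < 0 or self.n_non_hd_cells < 0:
            raise ValueError("cell counts must be >= 0")
        for lo, hi in (self.kappa_range, self.peak_rate_range, self.baseline_rate_range):
            if lo <= 0 or hi < lo:
                raise ValueError("parameter ranges must be positive and ordered")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass
class AnchoringParams:
    """How the internal (attractor) direction relates to the true one.

    anchored: internal == actual.
    rotated:  a cue rotation of ``rotation_offset_deg`` is followed with gain
              ``cue_gain`` from ``rotation_time_s`` onward.
    drifting: internal integrates ``ahv_gain`` x true AHV plus Gaussian
              diffusion with standard deviation ``drift_diffusion_sd`` per
              sqrt(second) — an unanchored attractor that under-signals head
              turns.
    """

    mode: str = "anchored"            # anchored | rotated | drifting
    cue_gain: float = 1.0             # [0, 2]
    ahv_gain: float = 0.7             # [0, 1]
    drift_diffusion_sd: float = 8.0   # deg / sqrt(s)
    rotation_offset_deg: float = 0.0
    rotation_time_s: float | None = None   # None -> from session start

    def validate(self):
        if self.mode not in ("anchored", "rotated", "drifting"):
            raise ValueError(f"unknown anchoring mode {self.mode!r}")
        if not (0.0 <= self.cue_gain <= 2.0):
            raise ValueError("cue_gain must be in [0, 2]")
        if not (0.0 <= self.ahv_gain <= 1.0):
            raise ValueError("ahv_gain must be in [0, 1]")
        if self.drift_diffusion_sd < 0:
            raise ValueError("drift_diffusion_sd must be >= 0")


def simulate_trajectory(params: TrajectoryParams, seed: int) -> TrackingTrace:
    """Simulate a head trajectory; deterministic given ``seed``."""
    params.validate()
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.sample_rate
    n = int(round(params.duration * params.sample_rate)) + 1
    t = np.arange(n) * dt

    # OU angular velocity: w_{k+1} = a w_k + s*sqrt(1-a^2) N
    a = np.exp(-dt / params.ahv_relaxation_tau)
    if params.ahv_stddev > 0:
        noise = rng.standard_normal(n)
        noise[0] = rng.standard_normal()  # stationary start
        w = lfilter([params.ahv_stddev * np.sqrt(1.0 - a * a)], [1.0, -a], noise)
        w[0] = params.ahv_stddev * noise[0]
    else:
        w = np.zeros(n)

    theta0 = rng.uniform(0.0, 360.0)
    if params.occupancy_bias_kappa > 0:
        # restoring drift needs feedback; integrate sample by sample
        theta = np.empty(n)
        theta[0] = theta0
        mu = np.radians(params.occupancy_bias_dir)
        c = params.occupancy_bias_kappa * 30.0  # deg/s per unit kappa
        for k in range(1, n):
            drift = -c * np.sin(np.radians(theta[k - 1]) - mu)
            theta[k] = theta[k - 1] + (w[k - 1] + drift) * dt
    else:
        theta = theta0 + np.concatenate(([0.0], np.cumsum(w[:-1]) * dt))
    hd = wrap_deg(theta)

    # reflected random walk inside the arena disc (radial fold of a free walk)
    steps = rng.normal(0.0, _POSITION_SPEED_SD_CM_S * np.sqrt(dt), size=(n, 2))
    steps[0] = rng.uniform(-params.arena_radius / 2, params.arena_radius / 2, size=2)
    raw = np.cumsum(steps, axis=0)
    r = np.hypot(raw[:, 0], raw[:, 1])
    period = 2.0 * params.arena_radius
    r_fold = np.abs((r + params.arena_radius) % period - params.arena_radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, r_fold / np.where(r > 0, r, 1.0), 0.0)
    pos = raw * scale[:, None]

    return TrackingTrace(
        timestamps=t, head_direction=hd, position_xy=pos,
        sample_rate=params.sample_rate,
    )


def internal_direction(trace: TrackingTrace, anchoring: AnchoringParams,
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Internal-direction series (deg, wrapped) and its ground-truth offset.

    The offset is returned unwrapped (internal minus actual, deg) so tests can
    check closed-form predictions, e.g. drifting with ``ahv_gain`` g and zero
    diffusion gives offset = (g - 1) x cumulative unwrapped head rotation.
    """
    anchoring.validate()
    rng = np.random.default_rng(seed)
    t = trace.timestamps
    actual_unwrapped = unwrap_deg(trace.head_direction)

    if anchoring.mode == "anchored":
        offset = np.zeros_like(t)
    elif anchoring.mode == "rotated":
        offset = np.zeros_like(t)
        t0 = anchoring.rotation_time_s if anchoring.rotation_time_s is not None else t[0]
        # a cue rotated by +x realigns the attractor so measured preferred
        # directions shift by +gain*x, i.e. the internal direction at a given
        # head direction shifts by -gain*x
        offset[t >= t0] = -anchoring.cue_gain * anchoring.rotation_offset_deg
    else:  # drifting
        rotation = actual_unwrapped - actual_unwrapped[0]
        dt = np.diff(t)
        diff_steps = rng.normal(0.0, anchoring.drift_diffusion_sd * np.sqrt(dt))
        diffusion = np.concatenate(([0.0], np.cumsum(diff_steps)))
        offset = (anchoring.ahv_gain - 1.0) * rotation + diffusion

    internal = wrap_deg(actual_unwrapped + offset)
    return internal, offset


def _enforce_refractory(times, refractory):
    """Drop any spike closer than ``refractory`` to the previous kept one."""
    if refractory <= 0 or times.size < 2:
        return times
    keep = np.ones(times.size, dtype=bool)
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last < refractory:
            keep[i] = False
        else:
            last = times[i]
    return times[keep]


def _poisson_spikes(rate_hz, t, dt, refractory, rng):
    """Inhomogeneous Poisson spikes at the tracking resolution, thinned by an
    absolute refractory period. Spikes are drawn per half-open inter-sample
    interval [t_k, t_k + dt), so none falls past the last sample."""
    rate_hz = np.asarray(rate_hz, dtype=float)[:-1]
    t = t[:-1]
    counts = rng.poisson(np.maximum(rate_hz, 0.0) * dt)
    idx = np.repeat(np.arange(t.size), counts)
    if idx.size == 0:
        return np.empty(0)
    times = t[idx] + rng.uniform(0.0, dt, size=idx.size)
    times.sort()
    return _enforce_refractory(times, refractory)


def _add_bursts(times, t_end, refractory, rng):
    """Append short high-frequency burst spikes after each base spike; the
    merged train is re-thinned so the refractory period still holds."""
    if times.size == 0:
        return times
    n_extra = rng.binomial(HD_BURST_EXTRA_MAX, HD_BURST_EXTRA_P, size=times.size)
    extras = []
    for k in range(1, HD_BURST_EXTRA_MAX + 1):
        src = times[n_extra >= k]
        if src.size:
            isi = rng.normal(k * HD_BURST_ISI_S, HD_BURST_ISI_JITTER_S, src.size)
            extras.append(src + np.abs(isi))
    if not extras:
        return times
    out = np.concatenate([times] + extras)
    out = out[out < t_end]
    out.sort()
    return _enforce_refractory(out, refractory)


def simulate_population(trace: TrackingTrace, internal_dir: np.ndarray,
                        pop: PopulationParams, seed: int
                        ) -> tuple[list[UnitSpikes], pd.DataFrame]:
    """Simulate spikes for a population of HD and non-HD cells.

    HD cells: lambda(t) = b + (peak - b) * exp(kappa * (cos(dir(t) - PFD) - 1)),
    so the stated peak rate is attained exactly at the PFD; spikes are drawn
    as a burst-augmented Poisson process (each base spike spawns a short
    ~250 Hz burst with the module-constant statistics, and the base intensity
    is divided by the mean burst size so the realized rate matches lambda).
    Non-HD cells: Poisson with a slow log-normal envelope and no bursts.
    Returns the units and a ground-truth table (unit_id, pfd_deg, kappa,
    peak_hz, baseline_hz, is_hd).
    """
    pop.validate()
    rng = np.random.default_rng(seed)
    t = trace.timestamps
    dt = float(np.median(np.diff(t)))
    ang = np.radians(np.asarray(internal_dir, dtype=float))

    if pop.pfd_list is not None:
        if len(pop.pfd_list) != pop.n_hd_cells:
            raise ValueError("pfd_list length must equal n_hd_cells")
        pfds = np.asarray(pop.pfd_list, dtype=float)
    else:
        pfds = rng.uniform(0.0, 360.0, pop.n_hd_cells)
    kappas = rng.uniform(*pop.kappa_range, pop.n_hd_cells)
    peaks = rng.uniform(*pop.peak_rate_range, pop.n_hd_cells)
    bases = rng.uniform(*pop.baseline_rate_range, pop.n_hd_cells)

    burst_mean = 1.0 + HD_BURST_EXTRA_MAX * HD_BURST_EXTRA_P
    units, rows = [], []
    for i in range(pop.n_hd_cells):
        lam = bases[i] + (peaks[i] - bases[i]) * np.exp(
            kappas[i] * (np.cos(ang - np.radians(pfds[i])) - 1.0))
        times = _poisson_spikes(lam / burst_mean, t, dt, pop.refractory, rng)
        times = _add_bursts(times, float(t[-1]), pop.refractory, rng)
        uid = f"hd{i:03d}"
        units.append(UnitSpikes(unit_id=uid, spike_times=times))
        rows.append((uid, pfds[i], kappas[i], peaks[i], bases[i], True))

    # OU in log-rate -> slow log-normal envelope
    a = np.exp(-dt / NONHD_ENVELOPE_TAU_S)
    for i in range(pop.n_non_hd_cells):
        mean_rate = rng.uniform(*NONHD_MEAN_RATE_RANGE_HZ)
        noise = rng.standard_normal(t.size)
        x = lfilter([NONHD_ENVELOPE_LOG_SD * np.sqrt(1.0 - a * a)], [1.0, -a], noise)
        x[0] = NONHD_ENVELOPE_LOG_SD * noise[0]
        lam = mean_rate * np.exp(x - 0.5 * NONHD_ENVELOPE_LOG_SD**2)
        times = _poisson_spikes(lam, t, dt, pop.refractory, rng)
        uid = f"nhd{i:03d}"
        units.append(UnitSpikes(unit_id=uid, spike_times=times))
        rows.append((uid, np.nan, np.nan, np.nan, mean_rate, False))

    truth = pd.DataFrame(
        rows, columns=["unit_id", "pfd_deg", "kappa", "peak_hz", "baseline_hz", "is_hd"])
    return units, truth


def simulate_two_chamber(p_neutral: float, duration: float, seed: int):
    """Two-chamber dwell process whose stationary neutral occupancy is
    ``p_neutral``; alternating exponential dwells, starting in the neutral
    chamber. Returns a ChamberOccupancy (t_neut, t_avers, CP)."""
    from .stats import ChamberOccupancy

    if not (0.0 <= p_neutral <= 1.0):
        raise ValueError("p_neutral must be in [0, 1]")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if p_neutral in (0.0, 1.0):
        t_neut = duration if p_neutral == 1.0 else 0.0
        return ChamberOccupancy(t_neut=t_neut, t_avers=duration - t_neut)
    mean_dwell = (CHAMBER_CYCLE_S * p_neutral, CHAMBER_CYCLE_S * (1.0 - p_neutral))
    t_acc = [0.0, 0.0]
    state, elapsed = 0, 0.0
    while elapsed < duration:
        dwell = rng.exponential(mean_dwell[state])
        dwell = min(dwell, duration - elapsed)
        t_acc[state] += dwell
        elapsed += dwell
        state = 1 - state
    return ChamberOccupancy(t_neut=t_acc[0], t_avers=t_acc[1])


def simulate_session(traj: TrajectoryParams | None = None,
                     pop: PopulationParams | None = None,
                     anchoring: AnchoringParams | None = None,
                     seed: int = 0, condition: str = "synthetic"):
    """Full synthetic session.

    Returns (SessionRecording, ground_truth DataFrame, offset array). The
    offset (internal minus actual direction, deg, unwrapped) is the drift
    ground truth.
    """
    traj = traj or TrajectoryParams()
    pop = pop or PopulationParams()
    anchoring = anchoring or AnchoringParams(mode="anchored")
    # independent sub-seeds below 2**31
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    trace = simulate_trajectory(traj, seeds[0])
    internal, offset = internal_direction(trace, anchoring, seeds[1])
    units, truth = simulate_population(trace, internal, pop, seeds[2])
    session = SessionRecording(
        tracking=trace, units=units, duration=traj.duration,
        condition=condition, seed=seed,
    )
    return session, truth, offset


def simulate_rotation_pair(rotation_deg: float, cue_gain: float,
                           traj: TrajectoryParams | None = None,
                           pop: PopulationParams | None = None,
                           seed: int = 0):
    """Pre/post cue-rotation session pair sharing one cell population.

    Mirrors the experimental protocol: a baseline exposure, then the animal is
    removed, the cue rotated by ``rotation_deg``, and a second session is
    recorded in which the internal direction follows the cue with gain
    ``cue_gain``. Returns (pre_session, post_session, truth).
    """
    traj = traj or TrajectoryParams()
    pop = pop or PopulationParams()
    rng = np.random.default_rng(seed)
    if pop.pfd_list is None:

        pop = replace(pop, pfd_list=list(rng.uniform(0, 360, pop.n_hd_cells)))
    pre, truth, _ = simulate_session(
        traj, pop, AnchoringParams(mode="anchored"), seed=int(rng.integers(2**31)))
    post, _, _ = simulate_session(
        traj, pop,
        AnchoringParams(mode="rotated", cue_gain=cue_gain,
                        rotation_offset_deg=rotation_deg),
        seed=int(rng.integers(2**31)))
    return pre, post, truth
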