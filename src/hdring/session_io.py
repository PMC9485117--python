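"""Session data model and on-disk format.

A session directory holds:

* ``manifest.json`` — duration_s, sample_rate_hz, condition, rotation_angle_deg
  (rotation sessions only), seed (synthetic provenance, optional) and the unit
  list with region labels;
* ``tracking.csv`` — columns time_s, hd_deg, x_cm, y_cm (x/y may be empty);
* ``spikes.csv`` — columns unit_id, time_s.

Times are 0-based seconds from session start; all bin intervals downstream are
half-open [t, t+dt). Head direction is stored in degrees in [0, 360) (values in
[0, 720) are accepted and normalized on load). Tracking gaps of at most two
samples are interpolated on the circle; longer gaps are an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._circ import circ_interp_deg, wrap_deg

CONDITIONS = ("control", "dark", "rotation", "post_ablation", "synthetic")

MAX_GAP_SAMPLES = 2


class SessionValidationError(ValueError):
    """Raised when a session violates a structural invariant."""


class SessionLoadError(OSError):
    """Raised when a session directory is missing a required file."""


@dataclass
class TrackingTrace:
    """Head-direction (and optional position) trace at a fixed nominal rate."""

    timestamps: np.ndarray            # s, strictly increasing
    head_direction: np.ndarray        # deg in [0, 360)
    position_xy: np.ndarray | None = None   # (n, 2) cm
    sample_rate: float = 120.0        # Hz, nominal

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.head_direction = np.asarray(self.head_direction, dtype=float)
        if self.position_xy is not None:
            self.position_xy = np.asarray(self.position_xy, dtype=float)
        self.validate()

    def validate(self):
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise SessionValidationError("tracking needs at least 2 samples")
        if np.any(np.diff(self.timestamps) <= 0):
            raise SessionValidationError("tracking timestamps must be strictly increasing")
        if self.head_direction.shape != self.timestamps.shape:
            raise SessionValidationError("head_direction length mismatch")
        finite = self.head_direction[np.isfinite(self.head_direction)]
        if finite.size and (finite.min() < 0 or finite.max() >= 720):
            raise SessionValidationError("head direction outside [0, 720) before normalization")
        if np.any(~np.isfinite(self.head_direction)):
            raise SessionValidationError("head direction contains unfilled gaps")
        self.head_direction = wrap_deg(self.head_direction)
        if self.position_xy is not None and self.position_xy.shape != (self.timestamps.size, 2):
            raise SessionValidationError("position_xy must be (n_samples, 2)")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class UnitSpikes:
    """Spike times of one sorted unit."""

    unit_id: str
    spike_times: np.ndarray           # s, sorted ascending
    region_label: str = "ADn"

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise SessionValidationError(f"unit {self.unit_id}: spike times not sorted")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class SessionRecording:
    """One recording session: tracking + simultaneously recorded units."""

    tracking: TrackingTrace
    units: list[UnitSpikes] = field(default_factory=list)
    duration: float = 0.0
    condition: str = "synthetic"
    rotation_angle: float | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.duration <= 0:
            self.duration = float(self.tracking.timestamps[-1])
        self.validate()

    def validate(self):
        if self.condition not in CONDITIONS:
            raise SessionValidationError(f"unknown condition {self.condition!r}")
        if (self.rotation_angle is not None) != (self.condition == "rotation"):
            raise SessionValidationError("rotation_angle present iff condition == 'rotation'")
        span = self.tracking.timestamps[-1]
        if not (0.95 * span <= self.duration <= 1.05 * span + 1.0):
            raise SessionValidationError("duration inconsistent with tracking span")
        for u in self.units:
            if u.n_spikes and (u.spike_times[0] < 0 or u.spike_times[-1] > self.duration + 1e-9):
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike time outside [0, {self.duration}]"
                )

    def unit(self, unit_id: str) -> UnitSpikes:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


def _fill_tracking_gaps(time_s, hd_deg):
    """Interpolate NaN gaps of <= MAX_GAP_SAMPLES circularly; longer gaps raise."""
    hd = np.asarray(hd_deg, dtype=float)
    bad = ~np.isfinite(hd)
    if not bad.any():
        return hd
    # locate runs of consecutive NaNs
    idx = np.flatnonzero(bad)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in runs:
        if run.size > MAX_GAP_SAMPLES:
            raise SessionValidationError(
                f"tracking gap of {run.size} samples at t={time_s[run[0]]:.3f}s "
                f"exceeds the {MAX_GAP_SAMPLES}-sample interpolation limit"
            )
        if run[0] == 0 or run[-1] == hd.size - 1:
            raise SessionValidationError("tracking gap at session boundary cannot be interpolated")
    good = ~bad
    hd[bad] = circ_interp_deg(time_s[bad], time_s[good], hd[good])
    return hd


def load_session(path) -> SessionRecording:
    """Load and validate a session directory.

    Raises SessionLoadError naming any missing file and SessionValidationError
    on invariant violations. Never silently drops spikes or samples.
    """
    path = Path(path)
    for name in ("manifest.json", "tracking.csv", "spikes.csv"):
        if not (path / name).exists():
            raise SessionLoadError(f"missing required file: {path / name}")
    with open(path / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)

    tr = pd.read_csv(path / "tracking.csv")
    time_s = tr["time_s"].to_numpy(dtype=float)
    raw_hd = tr["hd_deg"].to_numpy(dtype=float)
    finite = raw_hd[np.isfinite(raw_hd)]
    if finite.size and (finite.min() < 0 or finite.max() >= 720):
        raise SessionValidationError("hd_deg outside [0, 720) before normalization")
    hd = _fill_tracking_gaps(time_s, raw_hd)
    if "x_cm" in tr.columns and tr["x_cm"].notna().all():
        pos = tr[["x_cm", "y_cm"]].to_numpy(dtype=float)
    else:
        pos = None
    tracking = TrackingTrace(
        timestamps=time_s,
        head_direction=hd,
        position_xy=pos,
        sample_rate=float(manifest.get("sample_rate_hz", 120.0)),
    )

    sp = pd.read_csv(path / "spikes.csv")
    declared = manifest.get("units", [])
    units = []
    for entry in declared:
        uid = entry["unit_id"] if isinstance(entry, dict) else str(entry)
        region = entry.get("region_label", "ADn") if isinstance(entry, dict) else "ADn"
        times = np.sort(sp.loc[sp["unit_id"].astype(str) == uid, "time_s"].to_numpy(dtype=float))
        units.append(UnitSpikes(unit_id=uid, spike_times=times, region_label=region))
    n_assigned = sum(u.n_spikes for u in units)
    if n_assigned != len(sp):
        raise SessionValidationError(
            f"{len(sp) - n_assigned} spikes belong to units absent from the manifest"
        )

    seed = manifest.get("seed")
    return SessionRecording(
        tracking=tracking,
        units=units,
        duration=float(manifest["duration_s"]),
        condition=manifest.get("condition", "synthetic"),
        rotation_angle=manifest.get("rotation_angle_deg"),
        seed=int(seed) if seed is not None else None,
    )


def save_session(session: SessionRecording, path) -> None:
    """Write a session directory; save -> load round-trips to <= 1e-9."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "duration_s": session.duration,
        "sample_rate_hz": session.tracking.sample_rate,
        "condition": session.condition,
        "units": [
            {"unit_id": u.unit_id, "region_label": u.region_label} for u in session.units
        ],
    }
    if session.rotation_angle is not None:
        manifest["rotation_angle_deg"] = session.rotation_angle
    if session.seed is not None:
        manifest["seed"] = int(session.seed)
    with open(path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)

    tr = pd.DataFrame({
        "time_s": session.tracking.timestamps,
        "hd_deg": session.tracking.head_direction,
    })
    if session.tracking.position_xy is not None:
        tr["x_cm"] = session.tracking.position_xy[:, 0]
        tr["y_cm"] = session.tracking.position_xy[:, 1]
    else:
        tr["x_cm"] = np.nan
        tr["y_cm"] = np.nan
    tr.to_csv(path / "tracking.csv", index=False, float_format="%.12g")

    rows = [(u.unit_id, t) for u in session.units for t in u.spike_times]
    sp = pd.DataFrame(rows, columns=["unit_id", "time_s"])
    sp.to_csv(path / "spikes.csv", index=False, float_format="%.12g")


def validation_report(path) -> tuple[bool, str]:
    """Human-readable validation report for ``hdring validate``."""
    try:
        s = load_session(path)
    except (SessionLoadError, SessionValidationError, KeyError) as exc:
        return False, f"INVALID: {exc}"
    lines = [
        "VALID session",
        f"  condition:   {s.condition}",
        f"  duration:    {s.duration:.1f} s",
        f"  sample rate: {s.tracking.sample_rate:g} Hz",
        f"  units:       {len(s.units)} ({sum(u.n_spikes for u in s.units)} spikes)",
    ]
    if s.rotation_angle is not None:
        lines.append(f"  rotation:    {s.rotation_angle:g} deg")
    return True, "\n".join(lines)
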