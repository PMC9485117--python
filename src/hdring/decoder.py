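"""Bayesian decoding of head direction from population spike counts.

Posterior over direction bins per 200 ms window:
P(dir | spk) = P(spk | dir) P(dir) / P(spk), with P(spk | dir) an independent
Poisson likelihood per cell whose rates come from training-interval tuning
curves, and P(dir) either the training occupancy distribution (default) or
uniform. Accumulation is in log space; rates are floored at a small epsilon
so an empty tuning bin can never produce a zero likelihood for every state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._circ import signed_diff_deg
from .session_io import SessionRecording
from .tuning import compute_tuning_curve

RATE_FLOOR_HZ = 1e-3


@dataclass
class DecoderModel:
    """Fitted decoder: per-cell direction tuning and a direction prior."""

    unit_ids: list[str]
    rates: np.ndarray         # (n_cells, n_bins) Hz, floored
    prior: np.ndarray         # (n_bins,), sums to 1
    bin_centers: np.ndarray   # deg
    window: float = 0.2       # s

    def __post_init__(self):
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must sum to 1")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class DecodedTrace:
    """Per-window posterior, MAP angle and error vs the actual direction."""

    window_starts: np.ndarray   # s
    posterior: np.ndarray       # (n_windows, n_bins), rows sum to 1
    map_angle: np.ndarray       # deg in [0, 360)
    actual_angle: np.ndarray    # deg, down-sampled actual HD
    mean_abs_error: float       # deg

    def __post_init__(self):
        if not np.allclose(self.posterior.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")


def fit_decoder(session: SessionRecording,
                training_interval: tuple[float, float],
                unit_ids: list[str] | None = None,
                prior: str = "occupancy",
                window: float = 0.2,
                bin_deg: float = 6.0,
                smoothing_sd: float = 3.0) -> DecoderModel:
    """Fit tuning curves and direction prior on the training interval."""
    units = session.units if unit_ids is None else [session.unit(u) for u in unit_ids]
    if not units:
        raise ValueError("decoder needs at least one cell")
    rates, occ = [], None
    kept = []
    for u in units:
        curve = compute_tuning_curve(u, session.tracking, training_interval,
                                     bin_deg, smoothing_sd)
        if curve.n_spikes == 0:
            continue
        rates.append(np.maximum(curve.rate, RATE_FLOOR_HZ))
        occ = curve.occupancy
        centers = curve.bin_centers
        kept.append(u.unit_id)
    if not rates:
        raise ValueError("no cell has spikes in the training interval")
    if prior == "occupancy":
        pr = occ / occ.sum()
        # floor so unvisited bins are not impossible a priori
        pr = np.maximum(pr, 1e-6)
        pr = pr / pr.sum()
    elif prior == "uniform":
        pr = np.full(centers.size, 1.0 / centers.size)
    else:
        raise ValueError(f"unknown prior {prior!r}")
    return DecoderModel(unit_ids=kept, rates=np.vstack(rates), prior=pr,
                        bin_centers=centers, window=window)


def decode(model: DecoderModel, session: SessionRecording,
           test_interval: tuple[float, float]) -> DecodedTrace:
    """Decode head direction in consecutive windows tiling ``test_interval``
    (last partial window dropped)."""
    t0, t1 = test_interval
    w = model.window
    n_win = int(np.floor((t1 - t0) / w + 1e-9))
    if n_win < 1:
        raise ValueError("test interval shorter than one window")
    starts = t0 + np.arange(n_win) * w
    edges = t0 + np.arange(n_win + 1) * w

    counts = np.empty((n_win, len(model.unit_ids)))
    for c, uid in enumerate(model.unit_ids):
        st = session.unit(uid).spike_times
        counts[:, c], _ = np.histogram(st, bins=edges)

    # log posterior: sum_c [ k_c log(lambda_c,j w) - lambda_c,j w ] + log prior
    lam_w = model.rates * w                       # (cells, bins)
    log_lam = np.log(lam_w)
    logpost = counts @ log_lam - lam_w.sum(axis=0)[None, :] + np.log(model.prior)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    map_angle = model.bin_centers[np.argmax(post, axis=1)]

    # actual HD down-sampled: tracking sample nearest each window midpoint
    tt = session.tracking.timestamps
    mids = starts + w / 2.0
    idx = np.clip(np.searchsorted(tt, mids), 1, tt.size - 1)
    idx = np.where(mids - tt[idx - 1] < tt[idx] - mids, idx - 1, idx)
    actual = session.tracking.head_direction[idx]

    err = decoding_error(map_angle, actual)
    return DecodedTrace(window_starts=starts, posterior=post,
                        map_angle=map_angle, actual_angle=actual,
                        mean_abs_error=err)


def decode_session_halves(session: SessionRecording,
                          unit_ids: list[str] | None = None,
                          train_frac: float = 0.5,
                          **kwargs) -> DecodedTrace:
    """Fit on the first ``train_frac`` of the session, decode the rest."""
    t0, t1 = 0.0, session.duration
    tm = t0 + train_frac * (t1 - t0)
    model = fit_decoder(session, (t0, tm), unit_ids=unit_ids, **kwargs)
    return decode(model, session, (tm, t1))


def decoding_error(decoded_deg, actual_deg) -> float:
    """Mean absolute circular difference (deg, in [0, 180]) between aligned
    decoded and actual angle series."""
    d = np.asarray(decoded_deg, dtype=float)
    a = np.asarray(actual_deg, dtype=float)
    if d.shape != a.shape:
        raise ValueError("decoded and actual series must have equal length")
    return float(np.mean(np.abs(signed_diff_deg(d, a))))
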