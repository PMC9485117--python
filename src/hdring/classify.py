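"""HD / non-HD cell classification.

Three routes:

* the standard criterion — Rayleigh p < 1e-4, Rayleigh z > 50 and peak rate
  > 1 Hz on the occupancy-normalized tuning curve;
* a theta-modulation screen (4–8 Hz power in the Fourier transform of the
  autocorrelogram) used to restrict unit counts to thalamic ADn-like cells;
* a gradient-boosted (XGBoost, library defaults) classifier on
  autocorrelogram shape: per session half, spike-pair lags in (0, 400] ms are
  binned at 2 ms, smoothed (Gaussian s.d. = 1.5 bins), max-normalized, and the
  two halves stacked into a 400-long feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .session_io import UnitSpikes
from .tuning import HDMetrics

ACG_BIN_MS = 2.0
ACG_WINDOW_MS = 400.0
ACG_SMOOTH_SD_BINS = 1.5
N_ACG_BINS = int(round(ACG_WINDOW_MS / ACG_BIN_MS))   # 200 per half
THETA_BAND_HZ = (4.0, 8.0)
THETA_POWER_RATIO = 5.0   # band power must exceed this multiple of the
                          # median 1-50 Hz out-of-band power
THETA_ACG_WINDOW_MS = 2000.0   # the screen needs >= a few theta cycles to
                               # resolve 4-8 Hz from slower modulation


def classify_hd_standard(metrics: HDMetrics,
                         p_threshold: float = 1e-4,
                         z_threshold: float = 50.0,
                         peak_threshold: float = 1.0) -> bool:
    """Standard HD-cell criterion; monotone in each sub-criterion."""
    return (metrics.rayleigh_p < p_threshold
            and metrics.rayleigh_z > z_threshold
            and metrics.peak_rate > peak_threshold)


def autocorrelogram(spike_times, t_start: float, t_end: float,
                    bin_ms: float = ACG_BIN_MS,
                    window_ms: float = ACG_WINDOW_MS) -> np.ndarray:
    """Positive-lag spike autocorrelogram: counts of ordered spike-pair lags
    in (0, window] ms at ``bin_ms`` resolution."""
    st = np.asarray(spike_times, dtype=float)
    st = st[(st >= t_start) & (st < t_end)]
    if st.size < 2:
        raise ValueError(
            f"autocorrelogram needs >= 2 spikes in [{t_start:g}, {t_end:g})")
    w = window_ms / 1000.0
    n_bins = int(round(window_ms / bin_ms))
    counts = np.zeros(n_bins)
    hi = np.searchsorted(st, st + w, side="right")
    for i in range(st.size):
        lags = st[i + 1:hi[i]] - st[i]
        if lags.size:
            # right-inclusive bins (0,2], (2,4], ... ms, tolerant of float
            # fuzz at exact bin edges
            b = np.ceil(lags / w * n_bins - 1e-9).astype(int) - 1
            b = np.clip(b, 0, n_bins - 1)
            counts += np.bincount(b, minlength=n_bins)
    return counts


@dataclass
class ACGFeature:
    """Stacked half-session autocorrelogram feature of one unit."""

    unit_id: str
    lags_ms: np.ndarray          # positive-lag bin centers, per half
    values: np.ndarray           # 2 * N_ACG_BINS, smoothed, per-half max = 1
    smoothing_sd: float = ACG_SMOOTH_SD_BINS


def compute_acg_feature(spikes: UnitSpikes, t_start: float, t_end: float
                        ) -> ACGFeature:
    """Feature vector: the two half-session ACGs, each smoothed then
    normalized to unit maximum, concatenated (length 400)."""
    tm = 0.5 * (t_start + t_end)
    halves = []
    for name, (a, b) in (("first", (t_start, tm)), ("second", (tm, t_end))):
        try:
            acg = autocorrelogram(spikes.spike_times, a, b)
        except ValueError as exc:
            raise ValueError(f"unit {spikes.unit_id}, {name} half: {exc}") from exc
        sm = gaussian_filter1d(acg, ACG_SMOOTH_SD_BINS, mode="nearest")
        peak = sm.max()
        halves.append(sm / peak if peak > 0 else sm)
    lags = (np.arange(N_ACG_BINS) + 0.5) * ACG_BIN_MS
    return ACGFeature(unit_id=spikes.unit_id, lags_ms=lags,
                      values=np.concatenate(halves))


def theta_modulated(acg: np.ndarray, bin_ms: float = ACG_BIN_MS,
                    band: tuple[float, float] = THETA_BAND_HZ,
                    ratio: float = THETA_POWER_RATIO) -> bool:
    """Theta screen on a full (positive-lag, unstacked) autocorrelogram.

    The mean-subtracted, Hann-tapered ACG is zero-padded and Fourier
    transformed; the cell is theta-modulated iff mean power in the 4-8 Hz
    band exceeds ``ratio`` times the median power over 1-50 Hz outside the
    band. Pass an ACG spanning at least ~2 s (THETA_ACG_WINDOW_MS) so the
    band is resolvable from slower rate modulation.
    """
    acg = np.asarray(acg, dtype=float)
    x = (acg - acg.mean()) * np.hanning(acg.size)
    n_fft = max(4096, int(2 ** np.ceil(np.log2(x.size))))
    power = np.abs(np.fft.rfft(x, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=bin_ms / 1000.0)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    out_band = (freqs >= 1.0) & (freqs <= 50.0) & ~in_band
    if not in_band.any() or not out_band.any():
        raise ValueError("frequency resolution too coarse for the theta band")
    return bool(power[in_band].mean() > ratio * np.median(power[out_band]))


@dataclass
class ClassifierReport:
    """Held-out evaluation of the ACG classifier."""

    accuracy: float
    f1: float
    predictions: pd.DataFrame   # unit_id, label, predicted, score

    def __post_init__(self):
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.f1 <= 1.0):
            raise ValueError("accuracy and f1 must be in [0, 1]")


def train_acg_classifier(features: np.ndarray, labels: np.ndarray, seed: int):
    """Train the gradient-boosted ACG classifier.

    The training set is balanced by seeded down-sampling of the majority
    class; the model itself uses the library's default parameters.
    """
    from xgboost import XGBClassifier

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires both HD and non-HD examples")
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    n = min(idx0.size, idx1.size)
    keep = np.concatenate([rng.choice(idx0, n, replace=False),
                           rng.choice(idx1, n, replace=False)])
    keep.sort()
    model = XGBClassifier(random_state=seed, n_jobs=1)
    model.fit(X[keep], y[keep])
    return model


def evaluate_classifier(model, features: np.ndarray, labels: np.ndarray,
                        unit_ids=None, threshold: float = 0.5) -> ClassifierReport:
    """Evaluate on held-out features; accuracy and F1 for the HD class."""
    from sklearn.metrics import accuracy_score, f1_score

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    score = model.predict_proba(X)[:, 1]
    pred = (score >= threshold).astype(int)
    if unit_ids is None:
        unit_ids = [f"u{i}" for i in range(len(y))]
    df = pd.DataFrame({"unit_id": unit_ids, "label": y,
                       "predicted": pred, "score": score})
    return ClassifierReport(
        accuracy=float(accuracy_score(y, pred)),
        f1=float(f1_score(y, pred)),
        predictions=df,
    )


def proportion_hd(units: list[UnitSpikes], trace, classifier="standard",
                  model=None) -> tuple[float, pd.DataFrame]:
    """Fraction of (non-theta-modulated) recorded units classified as HD.

    Theta-modulated units are excluded from the denominator before computing
    the proportion. ``classifier`` is "standard" (criterion on tuning metrics)
    or "acg" (requires a trained ``model``).
    """
    from .tuning import compute_hd_metrics

    t0, t1 = float(trace.timestamps[0]), float(trace.timestamps[-1])
    rows = []
    for u in units:
        try:
            acg = autocorrelogram(u.spike_times, t0, t1,
                                  window_ms=THETA_ACG_WINDOW_MS)
            theta = theta_modulated(acg)
        except ValueError:
            rows.append((u.unit_id, True, False))
            continue
        if theta:
            rows.append((u.unit_id, True, False))
            continue
        if classifier == "standard":
            try:
                is_hd = classify_hd_standard(compute_hd_metrics(u, trace))
            except ValueError:
                is_hd = False
        elif classifier == "acg":
            if model is None:
                raise ValueError("acg classifier requires a trained model")
            feat = compute_acg_feature(u, t0, t1).values
            is_hd = bool(model.predict_proba(feat[None, :])[0, 1] >= 0.5)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        rows.append((u.unit_id, False, is_hd))
    df = pd.DataFrame(rows, columns=["unit_id", "theta_modulated", "is_hd"])
    kept = df[~df["theta_modulated"]]
    if len(kept) == 0:
        raise ValueError("no non-theta-modulated units")
    return float(kept["is_hd"].mean()), df


def z_test_proportions(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample z-test for proportions."""
    from scipy.stats import norm

    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))
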