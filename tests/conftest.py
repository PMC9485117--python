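"""Shared synthetic-session fixtures.

Heavy sessions are session-scoped so the suite simulates each condition once.
All seeds are fixed for reproducibility.
"""

import numpy as np
import pytest

import hdring as hr


@pytest.fixture(scope="session")
def anchored_session():
    """Default anchored session: 40 HD + 10 non-HD cells, 600 s."""
    session, truth, offset = hr.simulate_session(seed=1)
    return session, truth


@pytest.fixture(scope="session")
def drifting_session():
    """Drifting (unanchored attractor) session with ground-truth offset."""
    session, truth, offset = hr.simulate_session(
        anchoring=hr.AnchoringParams(mode="drifting"), seed=5)
    return session, truth, offset


@pytest.fixture(scope="session")
def sweep_trace():
    """Deterministic constant-rotation trace: 36 deg/s at 120 Hz for 600 s,
    hence exactly uniform angular occupancy (10 s per 6-degree bin)."""
    t = np.arange(0, 600.0 - 1e-9, 1 / 120.0)
    hd = (t * 36.0) % 360.0
    return hr.TrackingTrace(timestamps=t, head_direction=hd, sample_rate=120.0)


@pytest.fixture(scope="session")
def rotation_cohort():
    """Pre/post session pairs: 4 animals with cue-anchored gain 0.8 (90 deg
    rotation), 4 with gain 0, and 4 unmanipulated re-exposures for the
    shuffle null. Entries are per-animal arrays of (pfd_pre, pfd_post)."""
    pop = hr.PopulationParams(n_hd_cells=10, n_non_hd_cells=0)

    def pair_pfds(rotation, gain, seed):
        pre, post, _ = hr.simulate_rotation_pair(rotation, gain, pop=pop, seed=seed)
        out = []
        for u in pre.units:
            m1 = hr.compute_hd_metrics(u, pre.tracking)
            m2 = hr.compute_hd_metrics(post.unit(u.unit_id), post.tracking)
            out.append((m1.pfd, m2.pfd))
        return np.asarray(out)

    return {
        "gain08": [pair_pfds(90.0, 0.8, 40 + i) for i in range(4)],
        "gain0": [pair_pfds(90.0, 0.0, 50 + i) for i in range(4)],
        "reexposure": [pair_pfds(0.0, 0.0, 60 + i) for i in range(4)],
    }


def uniform_curve(rate_value=5.0, n_bins=60):
    """Flat tuning curve helper."""
    return hr.TuningCurve(
        bin_centers=(np.arange(n_bins) + 0.5) * 360.0 / n_bins,
        occupancy=np.full(n_bins, 10.0),
        raw_counts=np.full(n_bins, rate_value * 10.0),
        rate=np.full(n_bins, rate_value),
        smoothing_sd=0.0,
    )


def delta_curve(bin_index=0, rate_value=30.0, n_bins=60):
    """All spike mass in a single bin."""
    rate = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    rate[bin_index] = rate_value
    counts[bin_index] = rate_value * 10.0
    return hr.TuningCurve(
        bin_centers=(np.arange(n_bins) + 0.5) * 360.0 / n_bins,
        occupancy=np.full(n_bins, 10.0),
        raw_counts=counts,
        rate=rate,
        smoothing_sd=0.0,
    )
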