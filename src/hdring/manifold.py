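"""Ring-manifold analysis of population activity.

Spike counts of simultaneously recorded HD cells are binned (200 ms) and
square-root transformed to stabilize variance, embedded in two dimensions
with Isomap (50 neighbors), and the internal direction is read off the ring
as the arctangent of the centroid-centered embedding. A Vietoris–Rips H1
persistence barcode on the (subsampled, scale-normalized) point cloud tests
for ring topology: a single dominant bar is the signature of a circle.
Time-shift shuffles (independent circular shift of each cell's count series)
provide the null.

The H1 persistence computation is implemented here directly: the standard
boundary-matrix reduction over Z/2 with columns stored as Python integers
(bitmasks over filtration-ordered edges). It is exact, and validated in the
test suite against closed-form barcodes of regular polygons. Its cost grows
as C(n, 3), hence the default 150-point subsample.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._circ import circ_mean_deg, resultant_length, signed_diff_deg, wrap_deg
from .session_io import SessionRecording

MIN_CELLS = 10
BIN_S = 0.2


@dataclass
class PopulationMatrix:
    """Square-root-transformed spike-count matrix (windows x cells)."""

    window_starts: np.ndarray     # s
    counts_sqrt: np.ndarray       # (n_windows, n_cells)
    unit_ids: list[str]
    bin_s: float = BIN_S

    def __post_init__(self):
        if np.any(self.counts_sqrt < 0):
            raise ValueError("transformed counts must be >= 0")

    @property
    def total_spikes(self) -> float:
        return float(np.sum(self.counts_sqrt**2))


@dataclass
class RingEmbedding:
    """2-D Isomap embedding with the ring-decoded angle per window."""

    window_starts: np.ndarray
    coords: np.ndarray            # (n_windows, 2)
    decoded_angle: np.ndarray     # deg in [0, 360); NaN where undefined
    n_neighbors: int = 50

    def __post_init__(self):
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding coordinates must be finite")


@dataclass
class Barcode:
    """H1 persistence bars (birth, death) of the Rips filtration."""

    bars: np.ndarray              # (n_bars, 2)

    def __post_init__(self):
        if self.bars.size and np.any(self.bars[:, 1] < self.bars[:, 0]):
            raise ValueError("bar death must be >= birth")

    @property
    def persistences(self) -> np.ndarray:
        if self.bars.size == 0:
            return np.zeros(0)
        return self.bars[:, 1] - self.bars[:, 0]

    @property
    def top_persistence(self) -> float:
        p = self.persistences
        return float(p.max()) if p.size else 0.0

    @property
    def top_death(self) -> float:
        """Death radius of the most persistent bar."""
        if self.bars.size == 0:
            return 0.0
        return float(self.bars[np.argmax(self.persistences), 1])


def build_population_matrix(session: SessionRecording,
                            hd_cell_ids: list[str],
                            bin_s: float = BIN_S,
                            min_cells: int = MIN_CELLS) -> PopulationMatrix:
    """Bin spike counts in half-open 200 ms windows and square-root them."""
    if len(hd_cell_ids) < min_cells:
        raise ValueError(
            f"manifold analysis requires >= {min_cells} HD cells, got {len(hd_cell_ids)}")
    n_win = int(np.floor(session.duration / bin_s + 1e-9))
    edges = np.arange(n_win + 1) * bin_s
    counts = np.empty((n_win, len(hd_cell_ids)))
    for c, uid in enumerate(hd_cell_ids):
        st = session.unit(uid).spike_times
        counts[:, c], _ = np.histogram(st[st < n_win * bin_s], bins=edges)
    return PopulationMatrix(window_starts=edges[:-1],
                            counts_sqrt=np.sqrt(counts),
                            unit_ids=list(hd_cell_ids), bin_s=bin_s)


def isomap_embed(matrix: PopulationMatrix, n_neighbors: int = 50,
                 seed: int = 0) -> RingEmbedding:
    """2-component Isomap embedding of the population matrix.

    The two leading eigenvalues of a ring are nearly degenerate, so the
    embedding is only defined up to rotation/reflection and the arpack
    eigensolver seeds its start vector from the global RNG. The global RNG is
    therefore seeded with ``seed`` (and restored) around the solve, making
    the output exactly reproducible; every downstream statistic is invariant
    to the residual rotation/reflection ambiguity.
    """
    from sklearn.manifold import Isomap

    X = matrix.counts_sqrt
    if X.shape[0] <= n_neighbors:
        raise ValueError("need more windows than neighbors")
    iso = Isomap(n_neighbors=n_neighbors, n_components=2)
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31))
        coords = iso.fit_transform(X)
    finally:
        np.random.set_state(state)
    emb = RingEmbedding(window_starts=matrix.window_starts, coords=coords,
                        decoded_angle=np.zeros(len(coords)),
                        n_neighbors=n_neighbors)
    emb.decoded_angle = ring_decode(emb)[0]
    return emb


def ring_decode(embedding: RingEmbedding
                ) -> tuple[np.ndarray, np.ndarray]:
    """Angle on the ring per window and the decoded angular velocity.

    Coordinates are centered at their centroid; the angle is the element-wise
    arctangent; decoded AHV is the wrapped angle difference between
    consecutive windows divided by the bin width (deg/s). Windows that land
    exactly on the centroid get NaN angles.
    """
    xy = embedding.coords - embedding.coords.mean(axis=0, keepdims=True)
    r = np.hypot(xy[:, 0], xy[:, 1])
    ang = np.degrees(np.arctan2(xy[:, 1], xy[:, 0])) % 360.0
    ang = np.where(r > 0, ang, np.nan)
    dt = float(np.median(np.diff(embedding.window_starts)))
    dahv = signed_diff_deg(ang[1:], ang[:-1]) / dt
    return ang, dahv


def align_to_actual(decoded_deg, actual_deg):
    """Fit the global offset and reflection relating ring angles to actual HD.

    The embedding's orientation and rotation are arbitrary, so a single
    offset is chosen to maximize the resultant of (actual - s*decoded) and the
    sign s in {+1, -1} with the larger resultant wins. Returns
    (aligned_decoded, offset_deg, reflected, circular_r) with NaN windows
    dropped from the fit. circular_r is the Fisher-Lee correlation between
    aligned decoded and actual angles.
    """
    from ._circ import fisher_lee_correlation

    d = np.asarray(decoded_deg, dtype=float)
    a = np.asarray(actual_deg, dtype=float)
    ok = np.isfinite(d) & np.isfinite(a)
    best = None
    for sign in (1.0, -1.0):
        resid = a[ok] - sign * d[ok]
        rl = resultant_length(resid)
        if best is None or rl > best[0]:
            best = (rl, sign, circ_mean_deg(resid))
    _, sign, offset = best
    aligned = wrap_deg(sign * d + offset)
    # subsample pairs for the correlation if very long (O(n^2) memory)
    ia = np.flatnonzero(ok)
    if ia.size > 1500:
        ia = ia[np.linspace(0, ia.size - 1, 1500).astype(int)]
    r = fisher_lee_correlation(aligned[ia], a[ia])
    return aligned, float(offset), sign < 0, float(r)


def shuffle_population(matrix: PopulationMatrix, seed: int,
                       shifts: np.ndarray | None = None) -> PopulationMatrix:
    """Independent circular time-shift of each cell's binned counts."""
    rng = np.random.default_rng(seed)
    X = matrix.counts_sqrt
    n_win, n_cells = X.shape
    if shifts is None:
        shifts = rng.integers(0, n_win, size=n_cells)
    out = np.empty_like(X)
    for c in range(n_cells):
        out[:, c] = np.roll(X[:, c], int(shifts[c]))
    return PopulationMatrix(window_starts=matrix.window_starts,
                            counts_sqrt=out, unit_ids=list(matrix.unit_ids),
                            bin_s=matrix.bin_s)


# ---------------------------------------------------------------------------
# Vietoris-Rips H1 persistence
# ---------------------------------------------------------------------------

def rips_h1_bars(points: np.ndarray) -> np.ndarray:
    """Exact H1 persistence bars of the Rips filtration of a point cloud.

    Edges are ordered by length; triangles enter at the length of their
    longest edge. The triangle-boundary matrix over Z/2 is reduced with
    columns as bitmask integers; each new pivot pairs a cycle-creating edge
    (birth) with the triangle that fills it (death). Zero-persistence pairs
    are discarded.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 3:
        return np.zeros((0, 2))
    D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    ed = D[iu]
    order = np.argsort(ed, kind="stable")
    rank = np.empty(ed.size, dtype=np.int64)
    rank[order] = np.arange(ed.size)
    edge_rank = np.zeros((n, n), dtype=np.int64)
    edge_rank[iu] = rank
    edge_rank += edge_rank.T
    ed_sorted = ed[order]

    tri = np.fromiter(
        (v for c in combinations(range(n), 3) for v in c), dtype=np.int64
    ).reshape(-1, 3)
    e = np.stack([edge_rank[tri[:, 0], tri[:, 1]],
                  edge_rank[tri[:, 0], tri[:, 2]],
                  edge_rank[tri[:, 1], tri[:, 2]]], axis=1)
    fmax = e.max(axis=1)
    fval = ed_sorted[fmax]
    torder = np.lexsort((fmax, fval))
    e = e[torder]
    fval = fval[torder]

    pivots: dict[int, int] = {}
    bars = []
    for t in range(e.shape[0]):
        a, b, c = int(e[t, 0]), int(e[t, 1]), int(e[t, 2])
        col = (1 << a) ^ (1 << b) ^ (1 << c)
        while col:
            low = col.bit_length() - 1
            other = pivots.get(low)
            if other is None:
                pivots[low] = col
                birth = ed_sorted[low]
                death = fval[t]
                if death > birth * (1.0 + 1e-12) + 1e-15:
                    bars.append((birth, death))
                break
            col ^= other
    return np.array(bars) if bars else np.zeros((0, 2))


def betti1_barcode(embedding: RingEmbedding | np.ndarray,
                   n_subsample: int = 150, seed: int = 0) -> Barcode:
    """H1 barcode of the embedding point cloud.

    A seeded random subsample of at most ``n_subsample`` points is centered
    and scaled to unit mean radius (so persistence is comparable across
    sessions), then fed to the exact Rips reduction.
    """
    pts = embedding.coords if isinstance(embedding, RingEmbedding) else np.asarray(embedding)
    if pts.shape[0] < 50:
        raise ValueError("persistence needs at least 50 points")
    rng = np.random.default_rng(seed)
    if pts.shape[0] > n_subsample:
        idx = rng.choice(pts.shape[0], n_subsample, replace=False)
        pts = pts[idx]
    pts = pts - pts.mean(axis=0, keepdims=True)
    mean_r = float(np.mean(np.linalg.norm(pts, axis=1)))
    if mean_r > 0:
        pts = pts / mean_r
    return Barcode(bars=rips_h1_bars(pts))


def ring_persistence_test(matrix: PopulationMatrix, n_shuffles: int = 20,
                          n_neighbors: int = 50, n_subsample: int = 150,
                          seed: int = 0):
    """Top H1 persistence of the real embedding vs time-shift shuffles.

    Returns (real_top_persistence, shuffle_top_persistences array).
    """
    rng = np.random.default_rng(seed)
    emb = isomap_embed(matrix, n_neighbors=n_neighbors)
    real = betti1_barcode(emb, n_subsample=n_subsample,
                          seed=int(rng.integers(2**31))).top_persistence
    tops = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shuf = shuffle_population(matrix, seed=int(rng.integers(2**31)))
        semb = isomap_embed(shuf, n_neighbors=n_neighbors)
        tops[s] = betti1_barcode(semb, n_subsample=n_subsample,
                                 seed=int(rng.integers(2**31))).top_persistence
    return float(real), tops
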