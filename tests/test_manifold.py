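"""Population matrix, Isomap ring, ring decoding and persistent homology."""

import numpy as np
import pytest

import hdring as hr
from hdring.manifold import RingEmbedding, rips_h1_bars


def embedding_from(coords, bin_s=0.2):
    coords = np.asarray(coords, dtype=float)
    emb = RingEmbedding(window_starts=np.arange(len(coords)) * bin_s,
                        coords=coords, decoded_angle=np.zeros(len(coords)))
    emb.decoded_angle = hr.ring_decode(emb)[0]
    return emb


class TestPopulationMatrix:
    def test_sqrt_transform_and_conservation(self, anchored_session):
        session, truth = anchored_session
        hd_ids = list(truth[truth.is_hd].unit_id)
        mat = hr.build_population_matrix(session, hd_ids)
        assert mat.counts_sqrt.shape == (3000, 40)       # 600 s / 200 ms
        total = sum(session.unit(u).n_spikes for u in hd_ids)
        assert mat.total_spikes == pytest.approx(total)

    def test_four_spikes_in_a_bin_transform_to_two(self):
        t = np.linspace(0, 10, 1201)
        trace = hr.TrackingTrace(timestamps=t, head_direction=np.zeros(1201),
                                 sample_rate=120.0)
        units = [hr.UnitSpikes(unit_id=f"u{i}", spike_times=np.array([0.41, 0.45, 0.48, 0.52]))
                 for i in range(10)]
        session = hr.SessionRecording(tracking=trace, units=units, duration=10.0)
        mat = hr.build_population_matrix(session, [u.unit_id for u in units])
        assert mat.counts_sqrt[2, 0] == pytest.approx(2.0)

    def test_min_cell_threshold_cited(self, anchored_session):
        session, truth = anchored_session
        with pytest.raises(ValueError, match="10"):
            hr.build_population_matrix(session, list(truth.unit_id)[:5])


class TestRingDecode:
    def test_exact_circle_recovered_up_to_alignment(self):
        ang = np.linspace(0, 720, 400, endpoint=False) % 360.0
        coords = np.c_[np.cos(np.radians(ang)), np.sin(np.radians(ang))]
        emb = embedding_from(coords)
        aligned, offset, reflected, r = hr.align_to_actual(emb.decoded_angle, ang)
        assert np.max(np.abs(hr.angular_difference(aligned, ang))) < 1e-9
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_constant_rotation_gives_constant_ahv(self):
        step = 9.0
        ang = (np.arange(200) * step) % 360.0
        coords = np.c_[np.cos(np.radians(ang)), np.sin(np.radians(ang))]
        emb = embedding_from(coords)
        _, dahv = hr.ring_decode(emb)
        assert np.allclose(np.abs(dahv), step / 0.2, atol=1e-9)

    def test_equivariant_under_embedding_rotation(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 360, 300)
        coords = np.c_[np.cos(np.radians(ang)), np.sin(np.radians(ang))]
        phi = np.radians(73.0)
        rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        a = embedding_from(coords).decoded_angle
        b = embedding_from(coords @ rot.T).decoded_angle
        assert np.allclose(hr.angular_difference(b, a), 73.0, atol=1e-9)

    def test_centroid_point_is_missing(self):
        # square corners average to exactly (0, 0); the fifth point sits
        # exactly on the centroid and must come back as missing, not 0 deg
        coords = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0],
                           [0.0, 0.0]])
        emb = embedding_from(coords)
        assert np.isnan(emb.decoded_angle[-1])
        assert np.isfinite(emb.decoded_angle[:-1]).all()


class TestIsomap:
    @staticmethod
    def noiseless_matrix(n_cells=20, n_windows=1200):
        """Population vectors generated directly from von Mises tuning over a
        swept angle (no spiking noise)."""
        ang = np.linspace(0, 4 * 360, n_windows, endpoint=False) % 360.0
        pfds = np.linspace(0, 360, n_cells, endpoint=False)
        rates = np.exp(3.0 * (np.cos(np.radians(ang[:, None] - pfds[None, :])) - 1.0))
        return hr.PopulationMatrix(window_starts=np.arange(n_windows) * 0.2,
                                   counts_sqrt=np.sqrt(rates * 4.0),
                                   unit_ids=[f"u{i}" for i in range(n_cells)]), ang

    def test_noiseless_tuning_embeds_on_a_closed_curve(self):
        mat, ang = self.noiseless_matrix()
        emb = hr.isomap_embed(mat, n_neighbors=50)
        xy = emb.coords - emb.coords.mean(axis=0)
        radius = np.linalg.norm(xy, axis=1)
        assert radius.std() / radius.mean() < 0.1
        assert np.max(np.abs(radius - radius.mean())) < 0.35 * radius.mean()

    def test_embedding_distances_track_circular_distances(self, anchored_session):
        session, truth = anchored_session
        hd_ids = list(truth[truth.is_hd].unit_id)
        mat = hr.build_population_matrix(session, hd_ids)
        emb = hr.isomap_embed(mat)
        tt = session.tracking.timestamps
        idx = np.clip(np.searchsorted(tt, emb.window_starts + 0.1), 0, tt.size - 1)
        actual = session.tracking.head_direction[idx]
        rng = np.random.default_rng(0)
        i = rng.integers(0, len(actual), 4000)
        j = rng.integers(0, len(actual), 4000)
        d_emb = np.linalg.norm(emb.coords[i] - emb.coords[j], axis=1)
        d_circ = np.abs(hr.angular_difference(actual[i], actual[j]))
        r = np.corrcoef(d_emb, d_circ)[0, 1]
        assert r > 0.7

    def test_duplicate_rows_do_not_error(self):
        mat, _ = self.noiseless_matrix(n_windows=300)
        dup = hr.PopulationMatrix(
            window_starts=np.arange(600) * 0.2,
            counts_sqrt=np.vstack([mat.counts_sqrt, mat.counts_sqrt]),
            unit_ids=mat.unit_ids)
        hr.isomap_embed(dup, n_neighbors=50)

    def test_deterministic_given_seed(self):
        mat, _ = self.noiseless_matrix(n_windows=300)
        a = hr.isomap_embed(mat, n_neighbors=50, seed=3)
        b = hr.isomap_embed(mat, n_neighbors=50, seed=3)
        assert np.array_equal(a.coords, b.coords)


class TestPersistence:
    def test_unit_square_exact_barcode(self):
        """Four corners of a unit square: one H1 bar born at side length 1,
        killed at the diagonal sqrt(2)."""
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        bars = rips_h1_bars(pts)
        assert bars.shape == (1, 2)
        assert bars[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert bars[0, 1] == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_regular_hexagon_exact_barcode(self):
        """Unit-circumradius hexagon: bar (1, sqrt(3)) — the loop forms at the
        side length and fills at the sqrt(3) chord."""
        ang = np.radians(np.arange(6) * 60.0)
        pts = np.c_[np.cos(ang), np.sin(ang)]
        bars = rips_h1_bars(pts)
        top = bars[np.argmax(bars[:, 1] - bars[:, 0])]
        assert top[0] == pytest.approx(1.0, abs=1e-9)
        assert top[1] == pytest.approx(np.sqrt(3.0), abs=1e-9)

    def test_circle_has_one_dominant_bar(self):
        rng = np.random.default_rng(0)
        ang = rng.uniform(0, 2 * np.pi, 500)
        pts = np.c_[np.cos(ang), np.sin(ang)]
        bc = hr.betti1_barcode(pts, n_subsample=120, seed=1)
        p = np.sort(bc.persistences)
        assert p[-1] > 5 * (p[-2] if p.size > 1 else 0.0)

    def test_blob_less_persistent_than_circle(self):
        rng = np.random.default_rng(2)
        ang = rng.uniform(0, 2 * np.pi, 500)
        circle = np.c_[np.cos(ang), np.sin(ang)] + rng.normal(0, 0.05, (500, 2))
        blob = rng.normal(0, 1.0, (500, 2))
        top_c = hr.betti1_barcode(circle, n_subsample=120, seed=3).top_persistence
        top_b = hr.betti1_barcode(blob, n_subsample=120, seed=3).top_persistence
        assert top_c > top_b

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (400, 2))
        a = hr.betti1_barcode(pts, n_subsample=100, seed=5).bars
        b = hr.betti1_barcode(pts, n_subsample=100, seed=5).bars
        assert np.array_equal(a, b)

    def test_death_at_least_birth(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(-1, 1, (150, 2))
        bars = rips_h1_bars(pts)
        if bars.size:
            assert np.all(bars[:, 1] >= bars[:, 0])


class TestShuffle:
    def test_totals_preserved_exactly(self, anchored_session):
        session, truth = anchored_session
        hd_ids = list(truth[truth.is_hd].unit_id)
        mat = hr.build_population_matrix(session, hd_ids)
        shuf = hr.shuffle_population(mat, seed=0)
        assert np.allclose(np.sort(shuf.counts_sqrt, axis=0),
                           np.sort(mat.counts_sqrt, axis=0))

    def test_zero_shift_is_identity(self, anchored_session):
        session, truth = anchored_session
        hd_ids = list(truth[truth.is_hd].unit_id)
        mat = hr.build_population_matrix(session, hd_ids)
        shuf = hr.shuffle_population(mat, seed=0,
                                     shifts=np.zeros(len(hd_ids), dtype=int))
        assert np.array_equal(shuf.counts_sqrt, mat.counts_sqrt)
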