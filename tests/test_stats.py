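"""Rotation gain, head-turn epochs, chamber preference, ICC, circular r."""

import numpy as np
import pytest
from scipy.stats import binomtest

import hdring as hr


class TestRotationGain:
    def test_full_shift_gain_one(self):
        assert hr.rotation_gain(10.0, 100.0, 90.0).gain == pytest.approx(1.0)

    def test_no_shift_gain_zero(self):
        assert hr.rotation_gain(123.0, 123.0, 180.0).gain == 0.0

    def test_wrap_arithmetic(self):
        res = hr.rotation_gain(350.0, 80.0, 90.0)
        assert res.delta_pfd == pytest.approx(90.0)
        assert res.gain == pytest.approx(1.0)

    def test_invalid_cue_rejected(self):
        with pytest.raises(ValueError):
            hr.rotation_gain(0.0, 10.0, 45.0)

    def test_gain_invariant_to_rotation_sign(self):
        a = hr.rotation_gain(30.0, 100.0, 90.0).gain
        b = hr.rotation_gain(100.0, 30.0, -90.0).gain
        assert a == pytest.approx(b)


class TestRotationShuffle:
    def test_stable_reexposure_null_concentrates_at_zero(self):
        pairs = [(10.0, 10.0), (200.0, 200.0), (355.0, 355.0)]
        null = hr.rotation_shuffle_null(pairs, [90.0, 180.0], n=1000, seed=0)
        assert np.all(null == 0.0)

    def test_deterministic(self):
        pairs = [(10.0, 30.0), (200.0, 190.0)]
        a = hr.rotation_shuffle_null(pairs, [90.0], n=500, seed=7)
        b = hr.rotation_shuffle_null(pairs, [90.0], n=500, seed=7)
        assert np.array_equal(a, b)

    def test_cohorts_separate_from_null(self, rotation_cohort):
        """Cue-following cells exceed the re-exposure shuffle null; cells that
        ignore the cue do not."""
        null_pairs = np.vstack(rotation_cohort["reexposure"])
        null = hr.rotation_shuffle_null(null_pairs, [90.0], n=10000, seed=0)
        cut = np.percentile(null, 97.5)

        def median_gain(pairs_list):
            gains = [hr.rotation_gain(a, b, 90.0).gain
                     for pairs in pairs_list for a, b in pairs]
            return np.median(gains)

        assert median_gain(rotation_cohort["gain08"]) > cut
        assert median_gain(rotation_cohort["gain0"]) <= cut


class TestExpectedVsObserved:
    def test_perfect_following(self):
        deltas = [[88.0, 92.0, 90.0], [178.0, 182.0], [91.0, 89.0], [179.0, 181.0]]
        rotations = [90.0, 180.0, 90.0, 180.0]
        observed, r = hr.expected_vs_observed_shift(deltas, rotations)
        assert observed[0] == pytest.approx(90.0, abs=2.0)
        assert r > 0.9

    def test_floor_anchored_cohort_recovery(self, rotation_cohort):
        """Gain-0.8 animals under 90 deg rotations shift coherently; the
        observed shifts correlate with the expected ones across a mixed
        cohort that also contains non-following animals."""
        deltas, rotations = [], []
        for pairs, rot in zip(rotation_cohort["gain08"], [90.0] * 4):
            deltas.append([float(hr.angular_difference(b, a)) for a, b in pairs])
            rotations.append(rot * 0.8)
        for pairs in rotation_cohort["gain0"]:
            deltas.append([float(hr.angular_difference(b, a)) for a, b in pairs])
            rotations.append(0.0)
        observed, r = hr.expected_vs_observed_shift(deltas, rotations)
        assert r > 0.9


class TestHeadTurnEpochs:
    def test_constant_rotation_exact_epochs(self):
        t = np.arange(0, 60, 1 / 120.0)
        trace = hr.TrackingTrace(timestamps=t, head_direction=(t * 36.0) % 360.0,
                                 sample_rate=120.0)
        es = hr.head_turn_epochs(trace)
        assert len(es.intervals) == 5        # 60 s / 10 s per full turn
        assert es.mean_duration == pytest.approx(10.0, abs=0.05)

    def test_alternating_half_cycles_use_absolute_convention(self):
        # +-18 deg/s alternating every 10 s: net rotation ~0, absolute 180/10 s
        t = np.arange(0, 80, 1 / 120.0)
        sign = np.where((t // 10).astype(int) % 2 == 0, 1.0, -1.0)
        hd = np.cumsum(sign * 18.0 / 120.0) % 360.0
        trace = hr.TrackingTrace(timestamps=t, head_direction=hd, sample_rate=120.0)
        es = hr.head_turn_epochs(trace)
        assert es.mean_duration == pytest.approx(20.0, abs=0.2)
        net = hr.head_turn_epochs(trace, cumulative_abs=False)
        assert len(net.intervals) == 0       # net rotation never reaches 360

    def test_stationary_head_no_epochs(self):
        t = np.arange(0, 60, 1 / 120.0)
        trace = hr.TrackingTrace(timestamps=t, head_direction=np.full(t.size, 5.0),
                                 sample_rate=120.0)
        assert hr.head_turn_epochs(trace).intervals == []

    def test_epochs_tile_the_session(self, anchored_session):
        session, _ = anchored_session
        es = hr.head_turn_epochs(session.tracking)
        assert len(es.intervals) >= 2
        for (a0, a1), (b0, b1) in zip(es.intervals, es.intervals[1:]):
            assert a1 <= b0 + 1e-9           # ordered, non-overlapping


class TestEpochVectorLength:
    def test_anchored_epoch_vl_matches_spike_matched_control(self, anchored_session):
        """Without drift, per-epoch tuning equals spike-count-matched
        full-session tuning up to single-epoch sampling bias (a ~0.1 resultant
        inflation at ~25 s epochs that count matching cannot remove because it
        does not match the epoch's occupancy structure)."""
        session, truth = anchored_session
        es = hr.head_turn_epochs(session.tracking)
        diffs = []
        for u in session.units[:8]:
            _, mean_vl, ctrl = hr.epoch_vector_length(u, session.tracking, es,
                                                      seed=0)
            diffs.append(mean_vl - ctrl)
        assert abs(np.mean(diffs)) < 0.2

    def test_drifting_epoch_vl_exceeds_session_vl(self, drifting_session):
        """The tuning that drift destroys at the session scale survives
        within single head turns."""
        session, truth, _ = drifting_session
        es = hr.head_turn_epochs(session.tracking)
        hd_units = [u for u in session.units if u.unit_id.startswith("hd")][:12]
        epoch_minus_full, epoch_minus_ctrl = [], []
        for u in hd_units:
            _, mean_vl, ctrl = hr.epoch_vector_length(u, session.tracking, es,
                                                      seed=0)
            full = hr.vector_length(
                hr.compute_tuning_curve(u, session.tracking, smoothing_sd=0.0))
            epoch_minus_full.append(mean_vl - full)
            epoch_minus_ctrl.append(mean_vl - ctrl)
        assert np.mean(epoch_minus_full) > 0.3
        # paired sign test: control VL below epoch VL across cells
        n_pos = sum(d > 0 for d in epoch_minus_ctrl)
        assert binomtest(n_pos, len(epoch_minus_ctrl), 0.5,
                         alternative="greater").pvalue < 0.05


class TestChamberPreference:
    @pytest.mark.parametrize("t_neut, t_avers, expected", [
        (600.0, 0.0, 1.0),
        (0.0, 600.0, -1.0),
        (300.0, 300.0, 0.0),
    ])
    def test_score_extremes_and_symmetry(self, t_neut, t_avers, expected):
        occ = hr.ChamberOccupancy(t_neut=t_neut, t_avers=t_avers)
        assert hr.chamber_preference(occ) == pytest.approx(expected)

    def test_antisymmetric_under_chamber_swap(self):
        a = hr.ChamberOccupancy(t_neut=432.0, t_avers=168.0)
        b = hr.ChamberOccupancy(t_neut=168.0, t_avers=432.0)
        assert hr.chamber_preference(a) == pytest.approx(-hr.chamber_preference(b))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            hr.ChamberOccupancy(t_neut=0.0, t_avers=0.0)


class TestICC:
    def test_hand_anova_arithmetic(self):
        # A={0,2}, B={1,3}: MSB=1, MSW=2 -> sigma_b truncated to 0 -> ICC 0
        res = hr.icc([0.0, 2.0, 1.0, 3.0], ["A", "A", "B", "B"])
        assert res.sigma_b_sq == 0.0
        assert res.icc == 0.0

    def test_zero_within_variance_gives_one(self):
        res = hr.icc([1.0, 1.0, 3.0, 3.0], ["A", "A", "B", "B"])
        assert res.icc == pytest.approx(1.0)

    def test_direct_variance_limits(self):
        assert hr.icc_from_variances(0.0, 1.0).icc == 0.0
        assert hr.icc_from_variances(1.0, 0.0).icc == 1.0

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(m, 1.0, 8) for m in (0, 2, 5)])
        groups = np.repeat(["a", "b", "c"], 8)
        r1 = hr.icc(values, groups).icc
        r2 = hr.icc(values * 3.7 - 11.0, groups).icc
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_matches_pingouin_icc1_balanced(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        k, n = 6, 10
        values = np.concatenate([rng.normal(m, 1.0, n)
                                 for m in rng.normal(0, 1.5, k)])
        groups = np.repeat([f"g{i}" for i in range(k)], n)
        ours = hr.icc(values, groups).icc
        df = pd.DataFrame({"targets": groups,
                           "raters": np.tile(np.arange(n), k),
                           "score": values})
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="score").set_index("Type")
        assert ours == pytest.approx(float(ref.loc["ICC(1,1)", "ICC"]), abs=1e-6)

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError):
            hr.icc([1.0, 2.0], ["A", "A"])


class TestCircularCorrelation:
    def test_identity_and_reflection(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 360, 60)
        assert hr.circular_correlation(a, a) == pytest.approx(1.0)
        assert hr.circular_correlation(a, (-a) % 360) == pytest.approx(-1.0)

    def test_independent_null_small(self):
        rng = np.random.default_rng(2)
        small = sum(
            abs(hr.circular_correlation(rng.uniform(0, 360, 100),
                                        rng.uniform(0, 360, 100))) < 0.2
            for _ in range(40))
        assert small >= 38
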