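"""Shoal metrics: neighbor distances, path length, trajectory-matrix PCA."""

from dataclasses import replace

import numpy as np
import pytest

from shoalkit import (
    SharedMotionParams,
    TrajectorySet,
    assemble_trajectory_matrix,
    cumulative_shoal_distance,
    mixed_shoal_control,
    neighbor_distances,
    shoal_metrics,
    simulate_shared_motion_shoal,
    variance_explained,
)
from shoalkit.geometry import CircularArena
from shoalkit.errors import ConfigurationError, UndefinedStatisticError


def make_shoal(positions, frame_rate=30.0, arena=None):
    positions = np.asarray(positions, dtype=float)
    return TrajectorySet(
        fish_ids=[f"f{i}" for i in range(positions.shape[0])],
        positions=positions,
        frame_rate_hz=frame_rate,
        arena=arena or CircularArena(),
        source_id="test",
    )


class TestNeighborDistances:
    def test_three_four_five_worked_example(self, triangle_shoal):
        nd = neighbor_distances(triangle_shoal)
        np.testing.assert_allclose(nd.per_fish_nnd, [5, 5, 5])
        np.testing.assert_allclose(nd.per_fish_fnd, [10, 5, 10])
        np.testing.assert_allclose(nd.per_fish_iid, [7.5, 5, 7.5])
        assert nd.shoal_nnd == pytest.approx(5.0)
        assert nd.shoal_iid == pytest.approx(20 / 3)
        assert nd.shoal_fnd == pytest.approx(25 / 3)
        assert nd.pairwise_iid == pytest.approx(20 / 3)

    def test_two_fish_degenerate(self):
        pos = np.zeros((2, 4, 2))
        pos[1, :, 0] = 7.0
        nd = neighbor_distances(make_shoal(pos))
        assert nd.shoal_nnd == nd.shoal_iid == nd.shoal_fnd == pytest.approx(7.0)

    def test_single_fish_rejected(self):
        with pytest.raises(ConfigurationError):
            neighbor_distances(make_shoal(np.zeros((1, 3, 2))))

    def test_missing_pairs_dropped_pairwise(self):
        pos = np.zeros((3, 2, 2))
        pos[1, :, 0] = 3.0
        pos[2, :, 0] = 10.0
        pos[2, 1] = np.nan  # frame 1: only fish 0 and 1 remain
        nd = neighbor_distances(make_shoal(pos))
        # fish0: frame0 nnd=3 (to f1), frame1 nnd=3 -> mean 3
        assert nd.per_fish_nnd[0] == pytest.approx(3.0)
        # fish2 only counted at frame 0: nnd = 7 (to f1)
        assert nd.per_fish_nnd[2] == pytest.approx(7.0)

    def test_never_cotracked_fish_undefined(self):
        pos = np.zeros((2, 2, 2))
        pos[0, 0] = np.nan
        pos[1, 1] = np.nan
        with pytest.raises(UndefinedStatisticError):
            neighbor_distances(make_shoal(pos))

    def test_nnd_iid_fnd_ordering(self, small_shoal):
        nd = neighbor_distances(small_shoal)
        assert np.all(nd.per_fish_nnd <= nd.per_fish_iid + 1e-12)
        assert np.all(nd.per_fish_iid <= nd.per_fish_fnd + 1e-12)

    def test_translation_invariance_and_scaling(self, small_shoal):
        nd = neighbor_distances(small_shoal)
        moved = small_shoal.copy()
        moved.positions += np.array([40.0, -25.0])
        nd_t = neighbor_distances(moved)
        assert nd_t.shoal_iid == pytest.approx(nd.shoal_iid)
        scaled = replace(
            small_shoal,
            positions=small_shoal.positions * 0.5,
            fish_ids=list(small_shoal.fish_ids),
        )
        nd_s = neighbor_distances(scaled)
        assert nd_s.shoal_iid == pytest.approx(0.5 * nd.shoal_iid)
        assert nd_s.shoal_fnd == pytest.approx(0.5 * nd.shoal_fnd)


class TestCumulativeDistance:
    def test_stationary_zero(self, triangle_shoal):
        assert cumulative_shoal_distance(triangle_shoal) == 0.0

    def test_additivity(self):
        # each of 4 fish travels 100 mm -> 400 mm total
        pos = np.zeros((4, 101, 2))
        pos[:, :, 0] = np.arange(101)
        pos[:, :, 1] = 10.0 * np.arange(4)[:, None]
        assert cumulative_shoal_distance(make_shoal(pos)) == pytest.approx(400.0)

    def test_rigid_translation_counts_each_fish(self):
        # whole 20-fish shoal shifted by d=2 mm over one step -> 20 * 2 mm
        pos = np.zeros((20, 2, 2))
        pos[:, :, 1] = 5.0 * np.arange(20)[:, None]
        pos[:, 1, 0] = 2.0
        assert cumulative_shoal_distance(make_shoal(pos)) == pytest.approx(40.0)

    def test_centroid_mode(self):
        pos = np.zeros((2, 3, 2))
        pos[:, 1, 0] = 3.0
        pos[:, 2, 0] = 6.0
        assert cumulative_shoal_distance(make_shoal(pos), mode="centroid") == pytest.approx(6.0)

    def test_gap_steps_skipped(self):
        pos = np.zeros((1, 4, 2))
        pos[0, :, 0] = [0.0, 1.0, 0.0, 5.0]
        pos[0, 2] = np.nan
        assert cumulative_shoal_distance(make_shoal(pos)) == pytest.approx(1.0)


class TestAssembleMatrix:
    def test_2n_rule(self, triangle_shoal):
        m = assemble_trajectory_matrix(triangle_shoal)
        assert m.data.shape == (6, 10)
        assert m.row_labels[:3] == ["a_x", "a_y", "b_x"]

    def test_incomplete_frames_dropped_with_mask(self):
        pos = np.random.default_rng(0).uniform(10, 600, (3, 10, 2))
        pos[1, 3] = np.nan
        pos[2, 7] = np.nan
        m = assemble_trajectory_matrix(make_shoal(pos))
        assert m.data.shape == (6, 8)
        assert not m.frames_retained[3] and not m.frames_retained[7]
        assert m.frames_retained.sum() == 8

    def test_row_order_fish_major(self):
        pos = np.zeros((2, 3, 2))
        pos[0, :, 0] = [1.0, 2.0, 3.0]
        pos[0, :, 1] = [4.0, 5.0, 6.0]
        pos[1, :, 0] = [7.0, 8.0, 9.0]
        m = assemble_trajectory_matrix(make_shoal(pos))
        np.testing.assert_allclose(m.data[0], [1, 2, 3])
        np.testing.assert_allclose(m.data[1], [4, 5, 6])
        np.testing.assert_allclose(m.data[2], [7, 8, 9])

    def test_all_frames_missing_rejected(self):
        pos = np.full((2, 3, 2), np.nan)
        pos[0, :] = 1.0  # fish 1 never tracked -> no complete frame
        with pytest.raises(ConfigurationError):
            assemble_trajectory_matrix(make_shoal(pos))


class TestVarianceExplained:
    def test_identical_fish_give_exactly_one(self):
        rng = np.random.default_rng(5)
        track = rng.uniform(100, 500, (50, 2))
        pos = np.repeat(track[None, :, :], 20, axis=0)
        ve = variance_explained(assemble_trajectory_matrix(make_shoal(pos)))
        assert ve.variance_explained == pytest.approx(1.0, abs=1e-12)
        assert np.all(ve.eigenvalues >= -1e-9)

    def test_rank_two_after_centering_gives_one(self):
        # fish move along individual lines spanned by two shared signals
        rng = np.random.default_rng(8)
        a, b = rng.standard_normal((2, 200))
        pos = np.empty((5, 200, 2))
        for i in range(5):
            pos[i, :, 0] = 300 + i * 10 + 3.0 * a
            pos[i, :, 1] = 300 - i * 10 + 2.0 * b
        ve = variance_explained(assemble_trajectory_matrix(make_shoal(pos)))
        assert ve.variance_explained == pytest.approx(1.0, abs=1e-10)

    def test_stationary_shoal_undefined(self, triangle_shoal):
        with pytest.raises(UndefinedStatisticError):
            variance_explained(assemble_trajectory_matrix(triangle_shoal))

    def test_bounded_below_by_one_over_n(self, small_shoal):
        ve = variance_explained(assemble_trajectory_matrix(small_shoal))
        assert 1 / small_shoal.n_fish <= ve.variance_explained <= 1.0

    def test_svd_route_agrees_with_eigendecomposition(self):
        """Independent oracle: singular values of the centered matrix."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            data = rng.standard_normal((6, 50)) * rng.uniform(0.5, 3.0, (6, 1))
            m = assemble_trajectory_matrix(make_shoal(
                data.reshape(3, 2, 50).transpose(0, 2, 1) + 350.0))
            res = variance_explained(m)
            centered = m.data - m.data.mean(axis=1, keepdims=True)
            s = np.linalg.svd(centered, compute_uv=False)
            lam = s**2 / (m.data.shape[1] - 1)
            np.testing.assert_allclose(res.eigenvalues, lam, rtol=1e-8, atol=1e-10)
            assert res.variance_explained == pytest.approx(
                lam[:2].sum() / lam.sum(), rel=1e-8)

    def test_invariance_translation_and_uniform_scaling(self, small_shoal):
        base = variance_explained(assemble_trajectory_matrix(small_shoal)).variance_explained
        moved = small_shoal.copy()
        moved.positions += np.array([30.0, 60.0])
        assert variance_explained(
            assemble_trajectory_matrix(moved)).variance_explained == pytest.approx(base)
        scaled = replace(small_shoal, positions=small_shoal.positions * 0.3,
                         fish_ids=list(small_shoal.fish_ids))
        assert variance_explained(
            assemble_trajectory_matrix(scaled)).variance_explained == pytest.approx(base)

    def test_components_track_centroid(self):
        p = SharedMotionParams.from_rho(0.9, n_fish=10, duration_s=120, seed=3)
        ts = simulate_shared_motion_shoal(p)
        m = assemble_trajectory_matrix(ts)
        res = variance_explained(m, k=2, return_components=True)
        centroid = ts.positions.mean(axis=0)  # (T, 2)
        scores = res.components @ (m.data - m.data.mean(axis=1, keepdims=True))
        cx = centroid[:, 0] - centroid[:, 0].mean()
        cy = centroid[:, 1] - centroid[:, 1].mean()
        # the top-2 PC score subspace contains the centroid x/y motion
        r = np.abs(np.corrcoef(np.vstack([scores, cx, cy])))
        assert max(r[2, 0], r[2, 1]) > 0.97 or max(r[3, 0], r[3, 1]) > 0.97


class TestMixedControl:
    def test_k_same_equal_n_total_recovers_true_shoal(self):
        p = SharedMotionParams.from_rho(0.8, n_fish=6, duration_s=60, seed=1)
        recs = [simulate_shared_motion_shoal(replace_seed(p, s)) for s in (1, 2, 3)]
        true_ve = variance_explained(
            assemble_trajectory_matrix(recs[0])).variance_explained
        curve = mixed_shoal_control(recs, k_same_values=[6], n_total=6,
                                    replicates=4, seed=9)
        # every replicate draws all 6 fish of one recording; with equal
        # durations each value equals that recording's own VE
        all_ves = [variance_explained(
            assemble_trajectory_matrix(r)).variance_explained for r in recs]
        assert min(all_ves) - 1e-9 <= curve["mean_ve"].iloc[0] <= max(all_ves) + 1e-9
        assert true_ve == pytest.approx(all_ves[0])

    def test_insufficient_recordings_rejected(self):
        p = SharedMotionParams.from_rho(0.5, n_fish=4, duration_s=10, seed=0)
        recs = [simulate_shared_motion_shoal(p)]
        with pytest.raises(ConfigurationError):
            mixed_shoal_control(recs, k_same_values=[0], n_total=4)

    def test_seeded_reproducibility(self):
        p = SharedMotionParams.from_rho(0.7, n_fish=5, duration_s=30, seed=4)
        recs = [simulate_shared_motion_shoal(replace_seed(p, s)) for s in range(6)]
        a = mixed_shoal_control(recs, k_same_values=[0, 2, 5], n_total=5,
                                replicates=3, seed=7)
        b = mixed_shoal_control(recs, k_same_values=[0, 2, 5], n_total=5,
                                replicates=3, seed=7)
        assert a.equals(b)


class TestShoalMetricsAggregate:
    def test_rigid_translation_shoal(self):
        # whole shoal translating rigidly: distances constant, VE = 1
        base = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
        drift = np.linspace(0, 50, 40)
        pos = base[:, None, :] + np.stack([drift, 0.3 * drift], axis=1)[None, :, :]
        pos += 100.0
        m = shoal_metrics(make_shoal(pos))
        assert m.variance_explained_2 == pytest.approx(1.0, abs=1e-10)
        assert m.nnd_mm == pytest.approx(5.0)
        assert m.cumulative_distance_mm > 0

    def test_coordination_raises_ve_not_activity(self):
        lo = simulate_shared_motion_shoal(
            SharedMotionParams.from_rho(0.0, n_fish=10, duration_s=120, seed=6))
        hi = simulate_shared_motion_shoal(
            SharedMotionParams.from_rho(0.9, n_fish=10, duration_s=120, seed=6))
        m_lo, m_hi = shoal_metrics(lo), shoal_metrics(hi)
        assert m_hi.variance_explained_2 > m_lo.variance_explained_2 + 0.3
        # equal total sigma -> comparable swim activity (within 20%)
        ratio = m_hi.cumulative_distance_mm / m_lo.cumulative_distance_mm
        assert 0.8 < ratio < 1.2

    def test_frozen_record_of_reference_shoal(self, small_shoal):
        """Regression guard: metrics of the deterministic fixture shoal."""
        m = shoal_metrics(small_shoal)
        assert m.n_fish == 5 and m.frames_used == 600
        assert m.nnd_mm == pytest.approx(35.6604667991, rel=1e-9)
        assert m.iid_mm == pytest.approx(64.2282096542, rel=1e-9)
        assert m.fnd_mm == pytest.approx(95.1018626286, rel=1e-9)
        assert m.variance_explained_2 == pytest.approx(0.5649812581, rel=1e-9)


def replace_seed(p: SharedMotionParams, seed: int) -> SharedMotionParams:
    return replace(p, seed=seed)
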