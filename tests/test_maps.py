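"""Contact-map analysis: pairwise maps, P(s), fold change, triplets."""

import numpy as np
import pytest

from chrom4d.maps import (
    ContactMap,
    average_submatrices,
    contact_map,
    contact_probability,
    log2_fold_change,
    triplet_matrix,
    triplet_significance,
)
from conftest import brute_contact_map, brute_triplet_matrix


class TestContactMap:
    def test_straight_rod_nearest_neighbours_only(self, rod20):
        # d(i, j) = |i - j|; threshold 2 means contact iff |i - j| <= 1
        cm = contact_map(rod20[None], threshold=2.0)
        expected = (np.abs(np.subtract.outer(np.arange(20), np.arange(20))) <= 1)
        np.testing.assert_array_equal(cm.matrix, expected.astype(float))

    def test_coincident_beads_all_ones(self):
        x = np.zeros((1, 5, 3))
        cm = contact_map(x, threshold=1.0)
        np.testing.assert_array_equal(cm.matrix, np.ones((5, 5)))

    def test_single_conformation_is_binary(self, cloud_frames):
        cm = contact_map(cloud_frames[:1], threshold=2.5)
        assert set(np.unique(cm.matrix)) <= {0.0, 1.0}

    def test_matches_brute_force_oracle(self, cloud_frames):
        cm = contact_map(cloud_frames, threshold=2.5)
        ref = brute_contact_map(cloud_frames, 2.5)
        np.testing.assert_allclose(cm.matrix, ref, atol=1e-12)

    def test_monotone_in_threshold(self, cloud_frames):
        m1 = contact_map(cloud_frames, threshold=1.5).matrix
        m2 = contact_map(cloud_frames, threshold=3.0).matrix
        assert np.all(m2 >= m1)

    def test_invalid_threshold(self, cloud_frames):
        with pytest.raises(ValueError):
            contact_map(cloud_frames, threshold=0.0)

    def test_symmetry_validated(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ValueError):
            ContactMap(matrix=bad)


class TestContactProbability:
    def test_diagonal_is_one(self, cloud_frames):
        cm = contact_map(cloud_frames, threshold=2.5)
        assert contact_probability(cm)[0] == 1.0

    def test_constant_matrix(self):
        ps = contact_probability(np.full((6, 6), 0.3))
        np.testing.assert_allclose(ps, 0.3)

    def test_hand_computed_three_by_three(self):
        m = np.array([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]])
        np.testing.assert_allclose(contact_probability(m), [1.0, 0.45, 0.2])

    def test_global_scale(self):
        m = np.full((4, 4), 0.5)
        np.testing.assert_allclose(contact_probability(m, scale=2.0), 1.0)


class TestAverageSubmatrices:
    def _cmap(self, m):
        return ContactMap(matrix=m)

    def test_identity_at_k_one(self, cloud_frames):
        cm = contact_map(cloud_frames, threshold=2.5)
        np.testing.assert_array_equal(average_submatrices(cm, 1).matrix, cm.matrix)

    def test_identical_blocks_collapse_to_one(self):
        block = np.array([[1.0, 0.3], [0.3, 1.0]])
        big = np.kron(np.eye(3), block) + 0.1
        big = self._cmap(np.clip((big + big.T) / 2, 0, 1))
        out = average_submatrices(big, 3)
        np.testing.assert_allclose(out.matrix, big.matrix[:2, :2])

    def test_mean_of_two_blocks_hand_computed(self):
        m = np.zeros((4, 4))
        m[:2, :2] = [[1.0, 0.2], [0.2, 1.0]]
        m[2:, 2:] = [[1.0, 0.6], [0.6, 1.0]]
        out = average_submatrices(self._cmap(m), 2)
        np.testing.assert_allclose(out.matrix, [[1.0, 0.4], [0.4, 1.0]])

    def test_invalid_k(self, cloud_frames):
        cm = contact_map(cloud_frames, threshold=2.5)
        with pytest.raises(ValueError):
            average_submatrices(cm, 0)


class TestLog2FoldChange:
    def test_equal_maps_all_zero(self, cloud_frames):
        cm = contact_map(cloud_frames, threshold=2.5)
        np.testing.assert_allclose(log2_fold_change(cm, cm), 0.0)

    def test_doubling_gives_one(self):
        b = np.full((4, 4), 0.2)
        np.testing.assert_allclose(log2_fold_change(2 * b, b, pseudocount=0.0), 1.0)

    def test_zero_cells_stay_finite(self):
        a = np.zeros((3, 3))
        b = np.full((3, 3), 0.5)
        fc = log2_fold_change(a, b, pseudocount=1e-6)
        assert np.all(np.isfinite(fc))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            log2_fold_change(np.ones((3, 3)), np.ones((4, 4)))


class TestTriplets:
    def test_coincident_beads_all_ones(self):
        x = np.zeros((2, 6, 3))
        tm = triplet_matrix(x, viewpoint=2, threshold=5.0)
        np.testing.assert_array_equal(tm.matrix, np.ones((6, 6)))

    def test_rod_viewpoint_zero_confined_region(self, rod20):
        tm = triplet_matrix(rod20[None], viewpoint=0, threshold=5.0)
        nz = np.nonzero(tm.matrix)
        assert nz[0].max() <= 4 and nz[1].max() <= 4

    def test_symmetric_in_j_k(self, cloud_frames):
        tm = triplet_matrix(cloud_frames, viewpoint=3, threshold=3.0)
        np.testing.assert_allclose(tm.matrix, tm.matrix.T, atol=1e-12)

    def test_matches_brute_force_oracle(self, cloud_frames):
        tm = triplet_matrix(cloud_frames, viewpoint=5, threshold=3.0)
        ref = brute_triplet_matrix(cloud_frames, 5, 3.0)
        np.testing.assert_allclose(tm.matrix, ref, atol=1e-12)

    def test_triplet_bounded_by_pairwise(self, cloud_frames):
        thr = 3.0
        tm = triplet_matrix(cloud_frames, viewpoint=5, threshold=thr).matrix
        cm = contact_map(cloud_frames, threshold=thr).matrix
        n = cm.shape[0]
        for j in range(n):
            for k in range(n):
                if j == k or 5 in (j, k):
                    continue
                bound = min(cm[5, j], cm[j, k], cm[k, 5])
                assert tm[j, k] <= bound + 1e-12

    def test_viewpoint_out_of_range(self, cloud_frames):
        with pytest.raises(ValueError):
            triplet_matrix(cloud_frames, viewpoint=99)


class TestTripletSignificance:
    def test_zero_offset_is_never_significant(self, cloud_frames):
        p = triplet_significance(cloud_frames, (1, 3, 5), control_offset_bp=0.0,
                                 bin_bp=500.0)
        assert p == pytest.approx(0.5)

    def test_planted_colocalisation_detected(self):
        """Target triple pinned together in most frames, control diffuse:
        one-sided Mann-Whitney flags the target at p < 0.01."""
        rng = np.random.default_rng(8)
        n_frames, n = 500, 40
        pos = rng.normal(scale=8.0, size=(n_frames, n, 3))
        tight = rng.random(n_frames) < 0.6
        for b in (2, 5, 9):
            pos[tight, b] = pos[tight, 2] + rng.normal(scale=0.5,
                                                       size=(tight.sum(), 3))
        p = triplet_significance(pos, (2, 5, 9), control_offset_bp=10_000.0,
                                 bin_bp=500.0)
        assert p < 0.01

    def test_offset_outside_polymer(self, cloud_frames):
        with pytest.raises(ValueError):
            triplet_significance(cloud_frames, (1, 3, 5),
                                 control_offset_bp=1e9, bin_bp=500.0)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            triplet_significance(np.empty((0, 10, 3)), (1, 2, 3))
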