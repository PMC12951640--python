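"""Confidence-map fusion against brute-force and flood-fill oracles."""

import numpy as np
import pytest
from scipy import ndimage

from lesionseg.fusion import (
    ConfidenceMap,
    FusionParams,
    confidence_map,
    connected_growth,
    fuse,
    majority_vote,
    threshold_mask,
)


def random_masks(rng, n=24, shape=(8, 8, 8), p=0.3):
    return [(rng.random(shape) < p).astype(np.uint8) for _ in range(n)]


def bfs_flood_fill(m1, m2):
    """Independent oracle: BFS over 26-neighbourhoods from every m1 voxel."""
    m1 = m1.astype(bool)
    m2 = m2.astype(bool)
    out = np.zeros_like(m2)
    visited = np.zeros_like(m2)
    stack = list(map(tuple, np.argwhere(m1)))
    shape = m2.shape
    while stack:
        v = stack.pop()
        if visited[v]:
            continue
        visited[v] = True
        if not m2[v]:
            continue
        out[v] = True
        x, y, z = v
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                        if m2[nx, ny, nz] and not visited[nx, ny, nz]:
                            stack.append((nx, ny, nz))
    return out.astype(np.uint8)


class TestConfidenceMap:
    def test_matches_per_voxel_popcount(self):
        rng = np.random.default_rng(0)
        masks = random_masks(rng)
        cmap = confidence_map(masks)
        oracle = np.zeros(masks[0].shape, dtype=int)
        for m in masks:
            oracle += m
        np.testing.assert_array_equal(cmap.C, oracle)
        assert cmap.n_models == 24

    def test_identical_masks_sum_to_n_times_mask(self):
        rng = np.random.default_rng(1)
        m = (rng.random((6, 6, 6)) < 0.4).astype(np.uint8)
        cmap = confidence_map([m] * 24)
        np.testing.assert_array_equal(cmap.C, 24 * m)

    def test_range_is_integer_zero_to_n(self):
        rng = np.random.default_rng(2)
        cmap = confidence_map(random_masks(rng))
        assert np.issubdtype(cmap.C.dtype, np.integer)
        assert cmap.C.min() >= 0 and cmap.C.max() <= 24

    def test_all_zero_masks(self):
        cmap = confidence_map([np.zeros((4, 4, 4), dtype=np.uint8)] * 24)
        assert (cmap.C == 0).all()

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confidence_map([np.full((3, 3, 3), 2)])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confidence_map([np.zeros((3, 3, 3), np.uint8), np.zeros((4, 3, 3), np.uint8)])

    def test_non_integer_confidence_rejected(self):
        with pytest.raises(ValueError):
            ConfidenceMap(np.zeros((2, 2, 2)), 24)


class TestThreshold:
    def test_tau_equal_n_gives_empty(self):
        rng = np.random.default_rng(3)
        cmap = confidence_map(random_masks(rng))
        assert threshold_mask(cmap, 24).sum() == 0

    def test_tau_zero_is_union_support(self):
        rng = np.random.default_rng(4)
        masks = random_masks(rng, n=1)
        cmap = confidence_map(masks)
        np.testing.assert_array_equal(threshold_mask(cmap, 0), masks[0])

    def test_strict_inequality(self):
        cmap = ConfidenceMap(np.array([[[5]]], dtype=np.int32), 24)
        assert threshold_mask(cmap, 5)[0, 0, 0] == 0
        assert threshold_mask(cmap, 4)[0, 0, 0] == 1

    def test_monotone_in_tau(self):
        rng = np.random.default_rng(5)
        cmap = confidence_map(random_masks(rng))
        prev = threshold_mask(cmap, 0)
        for tau in range(1, 25):
            cur = threshold_mask(cmap, tau)
            assert (cur <= prev).all()
            prev = cur


class TestConnectedGrowth:
    def test_matches_bfs_oracle_on_500_random_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            m2 = (rng.random((16, 16, 16)) < rng.uniform(0.05, 0.4)).astype(np.uint8)
            m1 = (m2 & (rng.random((16, 16, 16)) < 0.15)).astype(np.uint8)
            np.testing.assert_array_equal(connected_growth(m1, m2), bfs_flood_fill(m1, m2))

    def test_empty_detection_gives_empty_output(self):
        m2 = np.ones((5, 5, 5), dtype=np.uint8)
        assert connected_growth(np.zeros_like(m2), m2).sum() == 0

    def test_equal_masks_reduce_to_single_threshold(self):
        rng = np.random.default_rng(7)
        m = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        np.testing.assert_array_equal(connected_growth(m, m), m)

    def test_subset_violation_rejected(self):
        m1 = np.ones((3, 3, 3), dtype=np.uint8)
        m2 = np.zeros_like(m1)
        with pytest.raises(ValueError):
            connected_growth(m1, m2)

    def test_diagonal_voxels_grow(self):
        """26-connectivity: corner-touching voxels belong to one lesion."""
        m2 = np.zeros((4, 4, 4), dtype=np.uint8)
        m2[0, 0, 0] = m2[1, 1, 1] = 1
        m1 = np.zeros_like(m2)
        m1[0, 0, 0] = 1
        out = connected_growth(m1, m2)
        assert out[1, 1, 1] == 1


class TestFuse:
    def test_identical_masks_recovered(self):
        rng = np.random.default_rng(8)
        m = (rng.random((8, 8, 8)) < 0.3).astype(np.uint8)
        np.testing.assert_array_equal(fuse([m] * 24, FusionParams(16, 7)), m)

    def test_everything_below_tau2_gives_empty(self):
        masks = [np.zeros((4, 4, 4), dtype=np.uint8) for _ in range(24)]
        masks[0][:] = 1  # C = 1 everywhere < tau2
        assert fuse(masks, FusionParams(16, 7)).sum() == 0

    def test_composition_equals_primitives(self):
        rng = np.random.default_rng(9)
        masks = random_masks(rng, shape=(10, 10, 10))
        params = FusionParams(14, 6)
        cmap = confidence_map(masks)
        expected = connected_growth(threshold_mask(cmap, 14), threshold_mask(cmap, 6))
        np.testing.assert_array_equal(fuse(masks, params), expected)

    def test_sandwich_property(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            masks = random_masks(rng)
            t2 = int(rng.integers(0, 24))
            t1 = int(rng.integers(t2, 25))
            cmap = confidence_map(masks)
            m1, m2 = threshold_mask(cmap, t1), threshold_mask(cmap, t2)
            m = fuse(masks, FusionParams(t1, t2))
            assert ((m1 <= m) & (m <= m2)).all()

    def test_anti_monotone_in_taus(self):
        rng = np.random.default_rng(11)
        masks = random_masks(rng)
        base = fuse(masks, FusionParams(10, 5))
        assert (fuse(masks, FusionParams(12, 5)) <= base).all()
        assert (fuse(masks, FusionParams(10, 7)) <= base).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        masks = random_masks(rng)
        perm = list(rng.permutation(24))
        np.testing.assert_array_equal(
            fuse(masks, FusionParams(16, 7)), fuse([masks[i] for i in perm], FusionParams(16, 7))
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FusionParams(5, 7)
        with pytest.raises(ValueError):
            FusionParams(-1, -2)


class TestMajorityVote:
    def test_13_of_24_is_positive_under_default_rule(self):
        masks = [np.ones((2, 2, 2), np.uint8)] * 13 + [np.zeros((2, 2, 2), np.uint8)] * 11
        assert majority_vote(masks).all()

    def test_12_of_24_is_negative_under_default_rule(self):
        masks = [np.ones((2, 2, 2), np.uint8)] * 12 + [np.zeros((2, 2, 2), np.uint8)] * 12
        assert majority_vote(masks).sum() == 0

    def test_unanimous_positive(self):
        masks = [np.ones((2, 2, 2), np.uint8)] * 24
        assert majority_vote(masks).all()

    def test_equivalent_to_fuse_with_equal_taus(self):
        rng = np.random.default_rng(13)
        masks = random_masks(rng)
        for t in (10, 12, 13):
            np.testing.assert_array_equal(
                majority_vote(masks, threshold=t), fuse(masks, FusionParams(t, t))
            )
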