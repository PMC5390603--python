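"""Region covariance descriptors, pencil similarity, patch search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrupsample import (
    SliceIndex,
    Volume3D,
    collect_training_pairs,
    covariance_weight,
    feature_maps,
    find_reference_patch,
    make_phantom,
    patch_from_slice,
    region_covariance,
)
from mrupsample.features import COV_EPS


def eq6_covariance(maps, center, r):
    """Direct summation oracle: C = (1/P) sum (f_i - mu)(f_i - mu)^T."""
    row, col = center
    pts = []
    for i in range(row - r, row + r + 1):
        for j in range(col - r, col + r + 1):
            pts.append([m[i, j] for m in maps])
    pts = np.array(pts)
    mu = pts.mean(axis=0)
    return sum(np.outer(f - mu, f - mu) for f in pts) / len(pts)


class TestFeatureMaps:
    def test_constant_slice_zero_gradients(self):
        I, gx, gy = feature_maps(np.full((6, 6), 3.2))
        assert np.all(gx == 0) and np.all(gy == 0)

    def test_horizontal_ramp(self):
        img = np.tile(np.arange(7.0), (5, 1))
        _, gx, gy = feature_maps(img)
        assert np.allclose(gx, 1.0)
        assert np.allclose(gy, 0.0)

    def test_matches_explicit_finite_differences(self, rng):
        img = rng.random((5, 5))
        _, gx, gy = feature_maps(img)
        for i in range(5):
            for j in range(5):
                if j == 0:
                    ex = img[i, 1] - img[i, 0]
                elif j == 4:
                    ex = img[i, 4] - img[i, 3]
                else:
                    ex = (img[i, j + 1] - img[i, j - 1]) / 2
                assert abs(gx[i, j] - ex) < 1e-14
                if i == 0:
                    ey = img[1, j] - img[0, j]
                elif i == 4:
                    ey = img[4, j] - img[3, j]
                else:
                    ey = (img[i + 1, j] - img[i - 1, j]) / 2
                assert abs(gy[i, j] - ey) < 1e-14

    def test_degenerate_slice_rejected(self):
        with pytest.raises(ValueError):
            feature_maps(np.ones((2, 5)))


class TestRegionCovariance:
    def test_constant_patch_gives_eps_identity(self):
        maps = feature_maps(np.full((7, 7), 0.5))
        C = region_covariance(maps, (3, 3), 2)
        assert np.allclose(C.C, COV_EPS * np.eye(3), atol=1e-15)

    def test_symmetric_positive_definite(self, rng):
        maps = feature_maps(rng.random((9, 9)))
        C = region_covariance(maps, (4, 4), 2).C
        assert np.allclose(C, C.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_matches_direct_summation(self):
        img = np.arange(1.0, 10.0).reshape(3, 3)
        maps = feature_maps(img)
        C = region_covariance(maps, (1, 1), 1, eps=0.0)
        expected = eq6_covariance(maps, (1, 1), 1)
        assert np.max(np.abs(C.C - expected)) < 1e-12

    def test_out_of_bounds_window_rejected(self):
        maps = feature_maps(np.ones((5, 5)))
        with pytest.raises(IndexError):
            region_covariance(maps, (0, 2), 2)


class TestCovarianceWeight:
    def test_identical_descriptors_give_one(self, rng):
        A = rng.standard_normal((3, 3))
        C = A @ A.T + 0.1 * np.eye(3)
        assert covariance_weight(C, C) == 1.0

    def test_known_generalized_eigenvalues(self):
        w = covariance_weight(np.diag([np.e, 1.0, 1.0]), np.eye(3))
        assert abs(w - np.exp(-1.0)) < 1e-10

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            covariance_weight(np.diag([1.0, -1.0, 1.0]), np.eye(3))

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        A = r.standard_normal((3, 3))
        B = r.standard_normal((3, 3))
        C1 = A @ A.T + 0.01 * np.eye(3)
        C2 = B @ B.T + 0.01 * np.eye(3)
        w12 = covariance_weight(C1, C2)
        w21 = covariance_weight(C2, C1)
        assert abs(w12 - w21) < 1e-10
        assert 0 < w12 <= 1

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6), st.floats(0.01, 100.0))
    def test_intensity_scale_invariance(self, seed, c):
        # scaling a slice by c scales raw descriptors by c^2; the pencil
        # eigenvalues, hence the weight, must not move
        r = np.random.default_rng(seed)
        img = r.random((9, 9))
        m1 = feature_maps(img)
        m2 = feature_maps(c * img)
        C1a = region_covariance(m1, (3, 3), 2, eps=0.0)
        C1b = region_covariance(m1, (5, 5), 2, eps=0.0)
        C2a = region_covariance(m2, (3, 3), 2, eps=0.0)
        C2b = region_covariance(m2, (5, 5), 2, eps=0.0)
        assert np.allclose(C2a.C, c**2 * C1a.C, rtol=1e-10, atol=1e-12)
        w1 = covariance_weight(C1a, C1b)
        w2 = covariance_weight(C2a, C2b)
        assert abs(w1 - w2) < 1e-10


class TestSliceIndex:
    def test_descriptor_grid_matches_direct_summation(self, rng):
        img = rng.random((20, 20))
        idx = SliceIndex(img, 2)
        padded = np.pad(img, 2, mode="reflect")
        maps = feature_maps(padded)
        for center in [(0, 0), (7, 3), (19, 19), (10, 0)]:
            direct = region_covariance(maps, (center[0] + 2, center[1] + 2), 2).C
            assert np.max(np.abs(idx.covs[center] - direct)) < 1e-12

    def test_patch_grid_matches_patch_from_slice(self, rng):
        img = rng.random((15, 15))
        idx = SliceIndex(img, 2)
        for center in [(0, 0), (7, 3), (14, 14)]:
            direct = patch_from_slice(img, center, 2)
            assert np.array_equal(idx.patches[center].ravel(), direct.values)


class TestFindReferencePatch:
    def test_verbatim_content_found_with_weight_one(self, rng):
        img = rng.random((30, 30))
        idx = SliceIndex(img, 2)
        target = (17, 23)
        q_s = patch_from_slice(img, target, 2, slice_index=0, source="Z_s")
        p_s, w = find_reference_patch(
            q_s, idx, target, v=5, r=2, q_cov=idx.covs[target]
        )
        assert p_s.center == target
        assert w == 1.0

    def test_exact_ties_break_lexicographically(self):
        # constant slice: every candidate descriptor is identical
        img = np.full((20, 20), 0.4)
        q_s = patch_from_slice(img, (10, 10), 2)
        p_s, w = find_reference_patch(q_s, img, (10, 10), v=4, r=2)
        assert p_s.center == (6, 6)
        assert w == 1.0

    def test_agrees_with_exhaustive_scan_oracle(self, rng):
        img = rng.random((25, 25))
        idx = SliceIndex(img, 2)
        center, v = (12, 8), 6
        q_cov = rng.standard_normal((3, 3))
        q_cov = q_cov @ q_cov.T + 0.05 * np.eye(3)
        q_s = patch_from_slice(img, center, 2)
        p_s, w = find_reference_patch(q_s, idx, center, v=v, r=2, q_cov=q_cov)

        padded_maps = feature_maps(np.pad(img, 2, mode="reflect"))
        best, best_w = None, -1.0
        for row in range(max(0, center[0] - v), min(25, center[0] + v + 1)):
            for col in range(max(0, center[1] - v), min(25, center[1] + v + 1)):
                cand = region_covariance(padded_maps, (row + 2, col + 2), 2)
                cw = covariance_weight(cand, q_cov)
                if cw > best_w:
                    best, best_w = (row, col), cw
        assert p_s.center == best
        assert abs(w - best_w) < 1e-8

    def test_search_is_deterministic(self, rng):
        img = rng.random((20, 20))
        q_s = patch_from_slice(img, (10, 10), 2)
        results = {
            find_reference_patch(q_s, img, (10, 10), v=5, r=2)[0].center
            for _ in range(3)
        }
        assert len(results) == 1


class TestCollectTrainingPairs:
    @pytest.fixture(scope="class")
    @staticmethod
    def volumes():
        hr = make_phantom((24, 40, 40), seed=9)
        smooth = Volume3D(hr.data * 0.9 + 0.05)  # stand-in smoothed version
        return hr, smooth

    def test_count_and_weight_ordering(self, volumes):
        hr, smooth = volumes
        p_s = patch_from_slice(smooth.data[10], (20, 20), 2, slice_index=10)
        pairs = collect_training_pairs(p_s, hr, smooth, v=11, p_slices=5, J=11, r=2)
        assert len(pairs) == 55
        weights = [t.weight for t in pairs]
        assert all(a >= b for a, b in zip(weights, weights[1:]))
        assert all(0 < t.weight <= 1 for t in pairs)

    def test_pairs_share_center_and_slice(self, volumes):
        hr, smooth = volumes
        p_s = patch_from_slice(smooth.data[4], (7, 31), 2, slice_index=4)
        pairs = collect_training_pairs(p_s, hr, smooth, v=8, p_slices=3, J=5, r=2)
        for t in pairs:
            assert t.lr_patch.center == t.hr_patch.center
            assert t.lr_patch.slice_index == t.hr_patch.slice_index

    def test_slice_range_clipped_at_volume_ends(self, volumes):
        hr, smooth = volumes
        p_s = patch_from_slice(smooth.data[0], (20, 20), 2, slice_index=0)
        pairs = collect_training_pairs(p_s, hr, smooth, v=6, p_slices=5, J=4, r=2)
        assert {t.lr_patch.slice_index for t in pairs} == {0, 1, 2}

    def test_stored_weights_reproducible(self, volumes):
        hr, smooth = volumes
        center = (20, 20)
        p_s = patch_from_slice(smooth.data[10], center, 2, slice_index=10)
        pairs = collect_training_pairs(p_s, hr, smooth, v=11, p_slices=3, J=7, r=2)
        ref_cov = SliceIndex(smooth.data[10], 2).covs[center]
        for t in pairs[::5]:
            idx = SliceIndex(smooth.data[t.lr_patch.slice_index], 2)
            w = covariance_weight(idx.covs[t.lr_patch.center], ref_cov)
            assert abs(w - t.weight) < 1e-8
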