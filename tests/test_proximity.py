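"""Ring construction and the stacked R*K proximity feature."""

import numpy as np
import pytest
from scipy import ndimage

from glandring.core_maps import ProbabilityMapStack
from glandring.proximity import (
    ExtractConfig,
    extract_image_features,
    make_rings,
    proximity_feature,
    ring_proportions,
)
from glandring.synthetic import TissueSimConfig, simulate_image
from conftest import random_blob, random_stack


def brute_force_rings(region: np.ndarray, R: int) -> list[np.ndarray]:
    """Oracle: successive 3x3 dilations and set differences."""
    se = np.ones((3, 3), bool)
    rings, prev = [], region.copy()
    for _ in range(R):
        cur = ndimage.binary_dilation(prev, se)
        rings.append(cur & ~prev)
        prev = cur
    return rings


class TestMakeRings:
    def test_single_pixel_areas(self):
        m = np.zeros((11, 11), bool)
        m[5, 5] = True
        rs = make_rings(m, 2)
        # pixel-set arithmetic: 3x3 minus 1, then 5x5 minus 3x3
        assert rs.ring_areas.tolist() == [8, 16]

    def test_corner_clipping_shrinks_ring(self):
        corner = np.zeros((20, 20), bool)
        corner[0, 0] = True
        interior = np.zeros((20, 20), bool)
        interior[10, 10] = True
        assert (
            make_rings(corner, 1).ring_areas[0]
            < make_rings(interior, 1).ring_areas[0]
        )

    def test_union_and_disjointness_on_random_blobs(self, rng):
        for _ in range(5):
            blob = random_blob(rng, 40)
            R = 4
            rs = make_rings(blob, R)
            oracle = brute_force_rings(blob, R)
            for got, want in zip(rs.rings, oracle):
                assert np.array_equal(got, want)
            union = blob.copy()
            coverage = blob.astype(int)
            for ring in rs.rings:
                union |= ring
                coverage += ring
            assert coverage.max() == 1  # pairwise disjoint, region excluded
            rfold = ndimage.binary_dilation(blob, np.ones((3, 3)), iterations=R)
            assert np.array_equal(union, rfold)

    def test_inward_rings_are_erosion_shells(self, rng):
        blob = random_blob(rng, 40)
        rs = make_rings(blob, 3, direction="inward")
        prev = blob
        for ring in rs.rings:
            eroded = ndimage.binary_erosion(prev, np.ones((3, 3)))
            assert np.array_equal(ring, prev & ~eroded)
            prev = eroded
        # inward rings may empty out once erosion exhausts the region
        assert all(not (r & ~blob).any() for r in rs.rings)

    def test_both_direction_doubles_ring_count(self, rng):
        blob = random_blob(rng, 40)
        assert make_rings(blob, 3, direction="both").R == 6

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            make_rings(np.zeros((5, 5), bool), 2)

    def test_zero_rings_degenerate(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert make_rings(m, 0).R == 0


class TestRingProportions:
    def test_worked_fractions(self):
        # ring over 10 pixels whose posterior mass splits 20/40/10/30%
        vals = np.tile(np.array([0.2, 0.4, 0.1, 0.3]), (1, 10, 1))
        stack = ProbabilityMapStack(vals)
        ring = np.ones((1, 10), bool)
        assert np.allclose(ring_proportions(ring, stack), [0.2, 0.4, 0.1, 0.3])

    def test_pure_class_delta(self):
        vals = np.zeros((4, 4, 4))
        vals[:, :, 2] = 1.0
        stack = ProbabilityMapStack(vals)
        ring = np.zeros((4, 4), bool)
        ring[1:3, 1:3] = True
        assert np.allclose(ring_proportions(ring, stack), [0, 0, 1, 0])

    def test_matches_pixel_accumulation_oracle(self, rng):
        stack = random_stack(rng, (16, 16))
        ring = random_blob(rng, 16)
        got = ring_proportions(ring, stack)
        acc = np.zeros(4)
        for i in range(16):
            for j in range(16):
                if ring[i, j]:
                    acc += stack.values[i, j]
        assert np.allclose(got, acc / ring.sum(), atol=1e-12)

    def test_empty_ring_all_zero(self, rng):
        stack = random_stack(rng, (8, 8))
        assert np.array_equal(
            ring_proportions(np.zeros((8, 8), bool), stack), np.zeros(4)
        )

    def test_nonempty_rings_sum_to_one(self, rng):
        stack = random_stack(rng, (40, 40))
        blob = random_blob(rng, 40)
        rs = make_rings(blob, 6)
        for ring in rs.rings:
            if ring.any():
                assert abs(ring_proportions(ring, stack).sum() - 1.0) < 1e-6


class TestProximityFeature:
    def test_length_r_times_k(self, rng):
        stack = random_stack(rng, (64, 64))
        m = np.zeros((64, 64), bool)
        m[30:34, 30:34] = True
        f = proximity_feature(1, make_rings(m, 10), stack)
        assert f.vector.shape == (40,)
        assert np.all((f.vector >= 0) & (f.vector <= 1))

    def test_layered_annuli_blocks(self):
        # lumen core wrapped by 3 px pure epithelium then pure stroma
        size = 41
        yy, xx = np.mgrid[:size, :size]
        d = np.hypot(yy - 20, xx - 20)
        lumen = d <= 5
        vals = np.zeros((size, size, 4))
        vals[:, :, 3] = 1.0
        vals[lumen] = [1, 0, 0, 0]
        # Chebyshev-distance shells match 3x3 square dilation geometry
        cheb = np.maximum(np.abs(yy - 20), np.abs(xx - 20))
        lum_cheb = np.where(lumen, cheb, -1).max()
        epi = (~lumen) & (cheb <= lum_cheb + 3)
        vals[epi] = [0, 1, 0, 0]
        stack = ProbabilityMapStack(vals)
        f = proximity_feature(1, make_rings(lumen, 5), stack)
        prof = f.profile()
        # epithelium dominates the first rings, stroma the outer ones
        assert prof[0, 1] > 0.99
        assert prof[4, 3] > 0.5
        assert np.all(prof[:, 0] < 1e-9)  # no neighboring lumen
        assert np.all(prof[:, 2] < 1e-9)

    def test_homogeneous_background_block(self):
        vals = np.zeros((21, 21, 4))
        vals[:, :, 2] = 1.0
        m = np.zeros((21, 21), bool)
        m[10, 10] = True
        vals[m] = [1, 0, 0, 0]
        f = proximity_feature(1, make_rings(m, 3), ProbabilityMapStack(vals))
        prof = f.profile()
        assert np.allclose(prof[:, 2], 1.0)
        assert np.allclose(prof[:, [0, 1, 3]], 0.0)

    def test_class_major_layout(self, rng):
        stack = random_stack(rng, (32, 32))
        m = np.zeros((32, 32), bool)
        m[15:17, 15:17] = True
        rings = make_rings(m, 4)
        f = proximity_feature(1, rings, stack)
        props = np.array([ring_proportions(r, stack) for r in rings.rings])
        # first R entries = class-0 fractions over rings 1..R
        assert np.allclose(f.vector[:4], props[:, 0])
        assert np.allclose(f.vector[4:8], props[:, 1])


class TestExtractPipeline:
    def test_one_feature_per_gland(self):
        cfg = TissueSimConfig(n_glands=3, dirichlet_concentration=None, seed=5)
        stack, _, _ = simulate_image(cfg)
        feats = extract_image_features(stack, ExtractConfig(order_channels=False))
        assert len(feats) == 3

    def test_deterministic(self):
        cfg = TissueSimConfig(n_glands=2, seed=9)
        stack, _, _ = simulate_image(cfg)
        a = extract_image_features(stack, ExtractConfig(order_channels=False))
        b = extract_image_features(stack, ExtractConfig(order_channels=False))
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.vector, fb.vector)

    def test_no_lumen_returns_empty(self):
        vals = np.zeros((16, 16, 4))
        vals[:, :, 3] = 1.0
        feats = extract_image_features(
            ProbabilityMapStack(vals), ExtractConfig(order_channels=False)
        )
        assert feats == []

    def test_coarse_rings_are_area_weighted_average_of_fine(self, rng):
        # merging adjacent unit rings pairwise (a step-2 dilation) equals
        # the area-weighted mean of the two fine rings' proportions
        stack = random_stack(rng, (48, 48))
        blob = random_blob(rng, 48)
        rs = make_rings(blob, 6)
        for r in range(0, 6, 2):
            a, b = rs.rings[r], rs.rings[r + 1]
            merged = a | b
            pa, pb = ring_proportions(a, stack), ring_proportions(b, stack)
            wa, wb = a.sum(), b.sum()
            want = (pa * wa + pb * wb) / (wa + wb)
            assert np.allclose(ring_proportions(merged, stack), want, atol=1e-12)


class TestGeometricInvariance:
    def test_translation_equivariance(self, rng):
        stack = random_stack(rng, (40, 40))
        m = np.zeros((40, 40), bool)
        m[10:14, 10:13] = True
        f1 = proximity_feature(1, make_rings(m, 3), stack)
        shifted_stack = ProbabilityMapStack(np.roll(stack.values, (7, 5), axis=(0, 1)))
        m2 = np.roll(m, (7, 5), axis=(0, 1))
        f2 = proximity_feature(1, make_rings(m2, 3), shifted_stack)
        assert np.allclose(f1.vector, f2.vector, atol=1e-12)

    def test_rot90_invariance(self, rng):
        stack = random_stack(rng, (40, 40))
        m = np.zeros((40, 40), bool)
        m[10:14, 10:13] = True
        f1 = proximity_feature(1, make_rings(m, 3), stack)
        rot_stack = ProbabilityMapStack(np.rot90(stack.values, axes=(0, 1)).copy())
        f2 = proximity_feature(1, make_rings(np.rot90(m).copy(), 3), rot_stack)
        assert np.allclose(f1.vector, f2.vector, atol=1e-12)

    def test_neighboring_lumen_visible_in_lumen_block(self):
        # a second lumen 4 steps away should light up the lumen block
        vals = np.zeros((31, 31, 4))
        vals[:, :, 3] = 1.0
        a = np.zeros((31, 31), bool)
        a[15, 10:13] = True
        b = np.zeros((31, 31), bool)
        b[15, 17:20] = True
        vals[a] = [1, 0, 0, 0]
        vals[b] = [1, 0, 0, 0]
        f = proximity_feature(1, make_rings(a, 6), ProbabilityMapStack(vals))
        lumen_block = f.profile()[:, 0]
        assert lumen_block[:3].max() < 1e-9
        assert lumen_block[4] > 0  # ring 5 reaches the neighbor
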