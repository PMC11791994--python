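"""Thinning postconditions, spur pruning, and polyline ordering."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.morphology import skeletonize as sk_skeletonize

from rootgrain import ScaleModel, gen_root
from rootgrain.skeletonize import (
    CyclicSkeletonError,
    MultiComponentError,
    Skeleton,
    prune_spurs,
    thin,
    to_polyline,
)
from rootgrain.synthetic_roots import RootParams


def has_2x2_square(mask):
    return bool((mask[:-1, :-1] & mask[1:, :-1] & mask[:-1, 1:] & mask[1:, 1:]).any())


def n_components(mask):
    _, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
    return n


def assert_thin_postconditions(skel, source):
    assert not has_2x2_square(skel.mask)
    assert not (skel.mask & ~source).any()  # subset of foreground
    assert n_components(skel.mask) == n_components(source)


@pytest.mark.parametrize("method", ["k3m", "fallback"])
class TestThin:
    def test_one_pixel_line_is_fixpoint(self, method):
        m = np.zeros((5, 20), bool)
        m[2, 3:17] = True
        out = thin(m, method=method)
        assert np.array_equal(out.mask, m)

    def test_empty_mask_gives_empty_skeleton(self, method):
        out = thin(np.zeros((5, 5), bool), method=method)
        assert out.n_pixels == 0

    def test_filled_rectangle_reduces_to_medial_line(self, method):
        m = np.zeros((9, 24), bool)
        m[2:7, 2:22] = True  # 20 x 5 rectangle
        out = thin(m, method=method)
        assert_thin_postconditions(out, m)
        assert len(out.endpoints) == 2
        # medial path of a 20x5 rectangle is 16-20 px long
        assert 16 <= out.n_pixels <= 20
        # cross-check against an independent thinning oracle
        oracle = sk_skeletonize(m)
        assert abs(int(oracle.sum()) - out.n_pixels) <= 4

    def test_idempotence(self, method):
        rng = np.random.default_rng(5)
        for seed in range(4):
            p = RootParams(curve=("arc", 12.0 + seed), length_mm=6.0,
                           diameter_mm=0.8)
            mask, _ = gen_root(p, ScaleModel(300), angle=rng.uniform(0, 6.28))
            once = thin(mask, method=method)
            twice = thin(once.mask, method=method)
            assert np.array_equal(once.mask, twice.mask)

    def test_holes_are_preserved(self, method):
        m = np.zeros((30, 30), bool)
        m[5:25, 5:25] = True
        m[12:18, 12:18] = False  # one hole
        out = thin(m, method=method)
        assert_thin_postconditions(out, m)
        # the skeleton must still enclose the hole: once the corner spurs
        # are pruned a closed loop remains
        ring = prune_spurs(out, 15)
        with pytest.raises(CyclicSkeletonError):
            to_polyline(ring)

    def test_multi_component_mask_rejected(self, method):
        m = np.zeros((10, 10), bool)
        m[1, 1] = m[8, 8] = True
        with pytest.raises(MultiComponentError, match="largest_component"):
            thin(m, method=method)


def test_k3m_and_fallback_agree_on_synthetic_roots():
    for seed in range(3):
        p = RootParams(curve=("arc", 15.0), length_mm=7.0, diameter_mm=0.7,
                       seed=seed)
        mask, _ = gen_root(p, ScaleModel(300), angle=0.4 * seed)
        a = thin(mask, method="k3m")
        b = thin(mask, method="fallback")
        # same postconditions, similar lengths (different algorithms)
        assert abs(a.n_pixels - b.n_pixels) / max(a.n_pixels, 1) < 0.12


def test_skeleton_tracks_true_medial_curve_within_one_pixel():
    p = RootParams(curve=("arc", 18.0), length_mm=9.0, diameter_mm=0.8)
    mask, truth = gen_root(p, ScaleModel(300), angle=0.7)
    skel = prune_spurs(thin(mask), 10)
    pts = np.array(sorted(skel.pixels))
    dists = np.min(
        np.linalg.norm(pts[:, None, :] - truth.medial_px[None, :, :], axis=2),
        axis=1,
    )
    assert dists.mean() <= 1.0


class TestPruneSpurs:
    def test_spur_free_path_unchanged(self):
        m = np.zeros((5, 20), bool)
        m[2, 3:17] = True
        out = prune_spurs(Skeleton(m), 10)
        assert np.array_equal(out.mask, m)

    def test_zero_threshold_is_identity(self):
        m = np.zeros((10, 10), bool)
        m[5, 1:9] = True
        m[2:5, 4] = True  # 3 px stub
        out = prune_spurs(Skeleton(m), 0)
        assert np.array_equal(out.mask, m)

    def test_three_pixel_stub_removed_below_threshold(self):
        m = np.zeros((10, 12), bool)
        m[5, 1:11] = True  # main path
        m[2:5, 4] = True  # 3 px stub ending at a branchpoint
        out = prune_spurs(Skeleton(m), 5)
        assert len(out.endpoints) == 2
        assert not out.mask[2:5, 4].any()
        assert out.mask[5, 1:11].all()

    def test_long_branch_survives(self):
        m = np.zeros((12, 12), bool)
        m[5, 1:11] = True
        m[0:5, 4] = True  # 5 px branch, threshold 5 keeps it
        out = prune_spurs(Skeleton(m), 5)
        assert out.mask[0:5, 4].all()

    def test_pruning_never_increases_pixel_count(self, rng):
        for _ in range(5):
            p = RootParams(curve=("arc", 10.0), length_mm=6.0, diameter_mm=0.9)
            mask, _ = gen_root(p, ScaleModel(300), angle=rng.uniform(0, 6.28))
            skel = thin(mask)
            assert prune_spurs(skel, 10).n_pixels <= skel.n_pixels


class TestToPolyline:
    def test_straight_line_ordered_and_monotone(self):
        m = np.zeros((3, 14), bool)
        m[1, 2:12] = True
        poly = to_polyline(Skeleton(m))
        assert len(poly) == 10
        xs = [p[0] for p in poly.points]
        assert xs == sorted(xs) or xs == sorted(xs, reverse=True)

    def test_l_shaped_path_fully_traversed(self):
        m = np.zeros((12, 12), bool)
        m[1, 1:9] = True  # 8 px horizontal
        m[2:9, 8] = True  # 7 px vertical
        poly = to_polyline(Skeleton(m))
        assert len(poly) == 15
        for (x0, y0), (x1, y1) in zip(poly.points, poly.points[1:]):
            assert max(abs(x1 - x0), abs(y1 - y0)) == 1  # 8-adjacent steps
        assert len(set(poly.points)) == len(poly.points)  # no repeats

    def test_y_shape_path_covers_the_two_long_arms(self):
        # brute-force oracle: the longest endpoint-to-endpoint path uses the
        # 30 px arms; the 5 px arm is ignored once pruned at threshold 4
        m = np.zeros((40, 70), bool)
        m[20, 2:32] = True  # arm A (30)
        m[20, 32:62] = True  # arm B (30)
        m[15:20, 32] = True  # 5 px side arm at the junction
        skel = prune_spurs(Skeleton(m), 4)
        poly = to_polyline(skel)
        assert len(poly) >= 59
        assert (2, 20) in poly.points and (61, 20) in poly.points

    def test_empty_skeleton_rejected(self):
        with pytest.raises(ValueError):
            to_polyline(Skeleton(np.zeros((4, 4), bool)))

    def test_closed_ring_raises_cyclic_error(self):
        m = np.zeros((12, 12), bool)
        m[2, 2:10] = m[9, 2:10] = True
        m[2:10, 2] = m[2:10, 9] = True
        with pytest.raises(CyclicSkeletonError):
            to_polyline(Skeleton(m))

    def test_point_count_never_exceeds_skeleton_size(self, rng):
        p = RootParams(curve=("quadratic", 0.05, 0.1, 0.0), length_mm=6.0,
                       diameter_mm=0.7)
        mask, _ = gen_root(p, ScaleModel(300), angle=1.1)
        skel = prune_spurs(thin(mask), 10)
        assert len(to_polyline(skel)) <= skel.n_pixels
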