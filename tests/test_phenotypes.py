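"""Trait measurement: lengths, diameters, areas, quadratic fits, curvature."""

import math

import numpy as np
import pytest
from scipy import ndimage

from rootgrain import ScaleModel, gen_root, phenotype_batch, phenotype_instance
from rootgrain.instance_postprocess import InstanceMask
from rootgrain.phenotypes import (
    QuadraticFit,
    curvature,
    fit_quadratic,
    root_areas,
    root_diameters,
    root_length,
    TRAIT_COLUMNS,
)
from rootgrain.skeletonize import Polyline, Skeleton
from rootgrain.synthetic_roots import RootParams

SCALE_1200 = ScaleModel(1200)


class TestRootLength:
    def test_horizontal_run_of_101_pixels(self):
        poly = Polyline([(i, 5) for i in range(101)])
        expected = 100 * 25.4 / 1200
        assert root_length(poly, SCALE_1200) == pytest.approx(expected)
        # chord resampling is exact on straight lines too
        assert root_length(poly, SCALE_1200, resample_px=7) == pytest.approx(expected)

    def test_pure_diagonal_run(self):
        poly = Polyline([(i, i) for i in range(11)])
        expected = 10 * math.sqrt(2) * 25.4 / 1200
        assert root_length(poly, SCALE_1200) == pytest.approx(expected)
        assert root_length(poly, SCALE_1200, resample_px=5) == pytest.approx(expected)

    def test_single_point_polyline_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert root_length(Polyline([(3, 3)]), SCALE_1200) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parabolic_root_length_matches_arc_length_integral(self, seed):
        # generator ground truth carries the closed-form arc length
        rng = np.random.default_rng(seed)
        p = RootParams(
            curve=("quadratic", float(rng.uniform(0.01, 0.04)), 0.1, 0.0),
            length_mm=10.0,
            diameter_mm=0.8,
        )
        mask, truth = gen_root(p, SCALE_1200, angle=float(rng.uniform(0, 6.28)))
        row = phenotype_instance(mask, SCALE_1200)
        assert row.length_mm == pytest.approx(truth.length_mm, rel=0.02)


class TestRootDiameters:
    def test_interior_of_height5_strip_measures_5px(self):
        m = np.zeros((9, 60), bool)
        m[2:7, :] = True
        skel = np.zeros_like(m)
        skel[4, 10:50] = True  # interior skeleton pixels only
        avg, dmax, dmin = root_diameters(m, Skeleton(skel), SCALE_1200)
        # brute-force nearest-background oracle at an interior pixel (4, 30)
        padded = np.pad(m, 1)
        bg = np.argwhere(~padded)
        edt_oracle = np.min(np.linalg.norm(bg - np.array([5, 31]), axis=1))
        assert 2 * edt_oracle - 1 == 5
        assert avg == pytest.approx(5 * SCALE_1200.mm_per_px)
        assert dmin == pytest.approx(dmax)

    def test_width1_line_measures_1px(self):
        m = np.zeros((5, 30), bool)
        m[2, :] = True
        skel = Skeleton(m.copy())
        avg, dmax, dmin = root_diameters(m, skel, SCALE_1200)
        assert avg == pytest.approx(1 * SCALE_1200.mm_per_px)

    def test_empty_skeleton_raises(self):
        with pytest.raises(ValueError):
            root_diameters(np.ones((5, 5), bool), Skeleton(np.zeros((5, 5), bool)),
                           SCALE_1200)

    def test_dilation_never_decreases_avg_diameter(self, rng):
        for seed in range(5):
            p = RootParams(curve=("arc", 14.0), length_mm=6.0, diameter_mm=0.7)
            mask, _ = gen_root(p, ScaleModel(300), angle=float(rng.uniform(0, 6.28)))
            row = phenotype_instance(mask, ScaleModel(300))
            dilated = InstanceMask(
                pixels=ndimage.binary_dilation(mask.pixels, np.ones((3, 3), bool))
            )
            row2 = phenotype_instance(dilated, ScaleModel(300))
            assert row2.avg_diameter_mm >= row.avg_diameter_mm


class TestRootAreas:
    def test_square_projected_area(self):
        scale = ScaleModel(25.4)  # 1 mm per px
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        projected, _ = root_areas(m, 1.0, 1.0, scale)
        assert projected == pytest.approx(100.0)

    def test_cylindrical_surface_closed_form(self):
        _, cyl = root_areas(np.zeros((2, 2), bool), 10.0, 1.0, SCALE_1200)
        assert cyl == pytest.approx(math.pi * 10.0)

    def test_generated_root_area_close_to_length_times_diameter(self):
        p = RootParams(curve=("straight",), length_mm=10.0, diameter_mm=1.0)
        mask, truth = gen_root(p, SCALE_1200)
        projected = mask.pixels.sum() * SCALE_1200.mm_per_px**2
        assert projected == pytest.approx(truth.length_mm * truth.diameter_mm,
                                          rel=0.03)


def normal_equations_fit(x, y):
    """Independent quadratic least-squares oracle via the normal equations."""
    V = np.stack([x**2, x, np.ones_like(x)], axis=1)
    return np.linalg.solve(V.T @ V, V.T @ y)


class TestFitQuadratic:
    def test_exact_recovery_of_axis_aligned_parabola(self):
        x = np.linspace(-3, 4, 40)
        pts = np.stack([x, 2 * x**2 + 3 * x + 1], axis=1)
        fit = fit_quadratic(pts, rotation="none")
        assert (fit.a, fit.b, fit.c) == pytest.approx((2.0, 3.0, 1.0), abs=1e-9)
        assert fit.rms < 1e-9

    def test_collinear_points_give_zero_curvature_coefficient(self):
        x = np.linspace(0, 10, 25)
        pts = np.stack([x, 0.5 * x + 2], axis=1)
        fit = fit_quadratic(pts, rotation="none")
        assert fit.a == pytest.approx(0.0, abs=1e-10)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        x = np.linspace(-5, 5, 200)
        y = 1.5 * x**2 - 0.7 * x + 3 + rng.normal(0, 0.5, 200)
        fit = fit_quadratic(np.stack([x, y], axis=1), rotation="none")
        a, b, c = normal_equations_fit(x, y)
        assert (fit.a, fit.b, fit.c) == pytest.approx((a, b, c), abs=1e-9)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic(np.ones((10, 2)))

    def test_pca_rotation_makes_vertical_roots_fittable(self):
        y = np.linspace(0, 30, 60)
        pts = np.stack([0.002 * y**2, y], axis=1)  # near-vertical
        fit = fit_quadratic(pts, rotation="pca")
        assert np.isfinite(fit.a)
        assert abs(abs(fit.rotation) - math.pi / 2) < 0.2


class TestCurvature:
    def test_straight_root_flagged_with_infinite_radius(self):
        fit = QuadraticFit(a=0.0, b=0.0, c=5.0, domain=(0, 10))
        res = curvature(fit)
        assert res.K == 0.0
        assert math.isinf(res.rho)
        assert res.straight

    def test_vertex_curvature_equals_2a_for_symmetric_parabola(self):
        fit = QuadraticFit(a=0.5, b=0.0, c=0.0, domain=(-1, 1))
        res = curvature(fit, where="vertex")
        assert res.K == pytest.approx(1.0)
        assert res.rho == pytest.approx(1.0)

    def test_circle_arc_recovers_inverse_radius_within_5_percent(self):
        # exact circle curvature as oracle: R = 50 px, 30 degree arc
        R = 50.0
        theta = np.linspace(-math.radians(15), math.radians(15), 200)
        pts = np.stack([R * np.sin(theta), R * (1 - np.cos(theta))], axis=1)
        fit = fit_quadratic(pts, rotation="pca")
        res = curvature(fit, where="midpoint")
        assert res.K == pytest.approx(1.0 / R, rel=0.05)

    def test_rho_times_k_is_exactly_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            fit = QuadraticFit(a=float(rng.uniform(0.01, 2)),
                               b=float(rng.uniform(-1, 1)), c=0.0,
                               domain=(-2, 3), x_arc_mid=0.4)
            res = curvature(fit, where="midpoint")
            # exact up to one ulp of the floating-point reciprocal
            assert math.isclose(res.rho * res.K, 1.0, rel_tol=1e-15)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(9)
        x = np.linspace(-10, 14, 300)
        base = np.stack([x, 0.03 * x**2 + 0.2 * x], axis=1)
        ref = curvature(fit_quadratic(base, rotation="pca"), where="midpoint")
        for _ in range(10):
            ang = float(rng.uniform(0, 2 * math.pi))
            c, s = math.cos(ang), math.sin(ang)
            moved = base @ np.array([[c, -s], [s, c]]).T + rng.uniform(-50, 50, 2)
            res = curvature(fit_quadratic(moved, rotation="pca"), where="midpoint")
            assert res.K == pytest.approx(ref.K, rel=1e-6)

    def test_mean_abs_matches_numeric_integration(self):
        fit = QuadraticFit(a=0.1, b=0.3, c=0.0, domain=(-4.0, 6.0))
        res = curvature(fit, where="mean_abs")
        xs = np.linspace(-4.0, 6.0, 20001)
        k = np.abs(2 * fit.a) / (1 + (2 * fit.a * xs + fit.b) ** 2) ** 1.5
        assert res.K_mean_abs == pytest.approx(np.trapezoid(k, xs) / 10.0, rel=1e-6)

    def test_negative_log_transform_and_base(self):
        fit = QuadraticFit(a=0.5, b=0.0, c=0.0, domain=(-1, 1), x_arc_mid=0.0)
        res_e = curvature(fit, where="vertex")
        assert res_e.neg_log_K == pytest.approx(-math.log(1.0), abs=1e-12)
        res_10 = curvature(fit, where="vertex", log_base=10.0)
        assert res_10.neg_log_K == pytest.approx(0.0, abs=1e-12)

    def test_scaling_to_physical_units(self):
        # K in 1/px divided by mm-per-px gives 1/mm
        fit = QuadraticFit(a=0.01, b=0.0, c=0.0, domain=(-1, 1), x_arc_mid=0.0)
        px = curvature(fit, where="vertex")
        mm = curvature(fit, where="vertex", scale=SCALE_1200)
        assert mm.K == pytest.approx(px.K / SCALE_1200.mm_per_px)
        assert mm.units == "1/mm" and px.units == "1/px"


class TestBatch:
    def test_empty_batch_has_stable_headers(self):
        df = phenotype_batch([])
        assert list(df.columns) == TRAIT_COLUMNS
        assert len(df) == 0

    def test_scene_batch_has_one_row_per_instance(self, small_scene):
        df = phenotype_batch(small_scene.masks, ScaleModel(small_scene.dpi))
        assert len(df) == 12
        assert list(df.columns) == TRAIT_COLUMNS

    def test_degenerate_instance_recorded_as_failed_row(self):
        tiny = np.zeros((6, 6), bool)
        tiny[2, 2] = True
        good = np.zeros((40, 120), bool)
        good[15:24, 10:110] = True
        df = phenotype_batch([
            InstanceMask(pixels=good, instance_id=0),
            InstanceMask(pixels=tiny, instance_id=1),
        ])
        assert len(df) == 2
        assert df.loc[df.instance_id == 0, "status"].item() == "ok"
        assert df.loc[df.instance_id == 1, "status"].item() == "failed"
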