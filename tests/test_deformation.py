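"""Radial tumour mass-effect model: distances, decay, warp, inverse, caching."""

import numpy as np
import pytest

import oracles
from tractfinder.deformation import (
    DeformationParams,
    ParameterError,
    RadialGeometry,
    decay_constant,
    deform_image,
    forward_warp,
    inverse_warp,
    k_factor,
    lambda_max,
)
from tractfinder.image import Volume, voxel_to_world
from tractfinder.synthetic import PhantomSpec, make_grid_image, make_phantom_masks


class TestDistanceTables:
    def test_concentric_spheres_have_constant_distances(self, sphere_phantom):
        spec, brain, tumour, geom = sphere_phantom
        inside = np.isfinite(geom.D_t)
        half_voxel = spec.voxel_size / 2.0
        assert np.abs(geom.D_t[inside] - 20.0).max() < half_voxel
        assert np.abs(geom.D_b[inside] - 100.0).max() < half_voxel
        np.testing.assert_allclose(geom.S, [0.0, 0.0, 0.0], atol=1e-9)

    def test_centre_point_has_zero_distance(self, sphere_phantom):
        spec, _, _, geom = sphere_phantom
        inside = np.isfinite(geom.D_p)
        # nearest voxel centre to S is within half a voxel diagonal
        assert geom.D_p[inside].min() <= spec.voxel_size * np.sqrt(3) / 2 + 1e-6
        assert np.all(geom.D_p[inside] >= 0)

    def test_off_centre_tumour_matches_analytic_ray_intersections(self, ellipsoid_phantom):
        spec, brain, tumour, geom = ellipsoid_phantom
        inside = brain.data > 0
        ijk = np.argwhere(inside)
        P = voxel_to_world(brain.affine, ijk)
        v = P - geom.S
        dp = np.linalg.norm(v, axis=1)
        keep = dp > 1e-9
        dirs = v[keep] / dp[keep, None]
        Db_true = oracles.ray_quadric_exit(geom.S, dirs, spec.brain_centre, spec.brain_semiaxes)
        Dt_true = oracles.ray_quadric_exit(
            geom.S, dirs, spec.tumour_centre, [spec.tumour_radius] * 3
        )
        assert np.abs(geom.D_t[inside][keep] - Dt_true).max() < spec.voxel_size / 2
        assert np.abs(geom.D_b[inside][keep] - Db_true).max() < spec.voxel_size / 2
        assert np.all(geom.D_t[inside] <= geom.D_b[inside] + 1e-6)

    def test_empty_tumour_rejected(self):
        spec = PhantomSpec()
        brain, tumour = make_phantom_masks(spec)
        with pytest.raises(ValueError, match="empty"):
            RadialGeometry(brain, Volume(np.zeros_like(tumour.data), tumour.affine))

    def test_tumour_outside_brain_rejected(self):
        spec = PhantomSpec()
        brain, tumour = make_phantom_masks(spec)
        with pytest.raises(ValueError, match="outside"):
            RadialGeometry(tumour, brain)  # roles swapped: "tumour" sticks out


class TestDecayFactor:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 2.0, 6.0, 8.0])
    def test_boundary_identities(self, lam):
        assert k_factor(0.0, 100.0, lam) == pytest.approx(1.0, abs=1e-12)
        assert k_factor(100.0, 100.0, lam) == pytest.approx(0.0, abs=1e-12)

    def test_halfway_value_matches_scalar_evaluation(self):
        # independent arithmetic: c = e^-2/(e^-2 - 1), k = (1-c)e^-1 + c
        import math

        c = math.exp(-2) / (math.exp(-2) - 1)
        assert c == pytest.approx(-0.15652, abs=1e-5)
        expected = (1 - c) * math.exp(-1.0) + c
        assert k_factor(50.0, 100.0, 2.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.26894, abs=1e-5)

    def test_strictly_decreasing_and_bounded(self):
        dp = np.linspace(0, 100, 400)
        for lam in [0.5, 2.0, 8.0]:
            k = k_factor(dp, 100.0, lam)
            assert np.all(np.diff(k) < 0)
            assert k.min() >= 0.0 and k.max() <= 1.0

    def test_clamped_beyond_brain_surface(self):
        assert k_factor(150.0, 100.0, 2.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            k_factor(10.0, 0.0, 2.0)
        with pytest.raises(ParameterError):
            k_factor(10.0, 100.0, -1.0)


class TestLambdaMax:
    @pytest.mark.parametrize("ratio", [1.5, 3.0, 10.0, 100.0])
    def test_solves_implicit_equation(self, ratio):
        lam = lambda_max(1.0, ratio)
        residual = lam * (1.0 - decay_constant(lam)) - ratio
        assert abs(residual) < 1e-10 * ratio

    @pytest.mark.parametrize("ratio", [1.5, 3.0, 10.0, 100.0])
    def test_cross_checked_by_bisection(self, ratio):
        lo, hi = 1e-8, 10.0 * ratio
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if mid * (1.0 - decay_constant(mid)) < ratio:
                lo = mid
            else:
                hi = mid
        assert lambda_max(1.0, ratio) == pytest.approx(0.5 * (lo + hi), rel=1e-9)

    def test_known_value_ratio_three(self):
        assert lambda_max(1.0, 3.0) == pytest.approx(2.8214, abs=2e-4)

    def test_asymptotic_identity(self):
        ratio = 1000.0
        assert lambda_max(1.0, ratio) / ratio == pytest.approx(1.0, abs=1e-6)

    def test_non_infiltrative_inequality_on_dense_grid(self):
        # k(D_p) >= 1 - D_p/D_t for all D_p in [0, D_t] at lambda = lambda_max
        D_t, D_b = 20.0, 100.0
        lam = lambda_max(D_t, D_b)
        dp = np.linspace(0, D_t, 2000)
        k = k_factor(dp, D_b, lam)
        assert np.all(k >= 1.0 - dp / D_t - 1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            lambda_max(-1.0, 10.0)
        with pytest.raises(ValueError):
            lambda_max(10.0, 5.0)


class TestForwardWarp:
    def test_brain_boundary_is_fixed(self, sphere_phantom):
        _, _, _, geom = sphere_phantom
        dirs = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0.6, 0.8]])
        _, D_b = geom.ray_distances(dirs)
        P = geom.S + dirs * D_b[:, None]
        out = forward_warp(P, geom, DeformationParams(2.0))
        assert np.abs(out - P).max() < 1e-9

    def test_s_zero_is_identity(self, sphere_phantom, rng):
        _, _, _, geom = sphere_phantom
        pts = rng.uniform(-80, 80, size=(200, 3))
        out = forward_warp(pts, geom, DeformationParams(2.0, s=0.0))
        np.testing.assert_array_equal(out, pts)

    def test_concentric_sphere_midpoint_displacement(self, sphere_phantom):
        # D_p = 50, lambda = 2, D_t = 20, D_b = 100: k ~ 0.26894 so
        # D_p' ~ 50 + 0.26894 * 20 = 55.379
        _, _, _, geom = sphere_phantom
        out = forward_warp(np.array([0.0, 50.0, 0.0]), geom, DeformationParams(2.0))
        assert np.linalg.norm(out - geom.S) == pytest.approx(55.379, abs=0.05)

    def test_displacement_is_purely_radial(self, ellipsoid_phantom, rng):
        _, brain, _, geom = ellipsoid_phantom
        pts = rng.uniform(-35, 35, size=(500, 3)) * [1.0, 0.8, 0.8]
        pts = pts[geom.inside_brain(pts)]
        out = forward_warp(pts, geom, DeformationParams("auto"))
        v = pts - geom.S
        w = out - geom.S
        cross = np.linalg.norm(np.cross(v, w), axis=1)
        assert np.all(cross <= 1e-8 * np.linalg.norm(v, axis=1) * np.linalg.norm(w, axis=1) + 1e-12)

    def test_monotone_along_rays(self, ellipsoid_phantom):
        _, _, _, geom = ellipsoid_phantom
        for d in ([1.0, 0, 0], [0, 1, 0], [0.36, 0.48, 0.8], [-0.6, 0.64, -0.48]):
            d = np.asarray(d) / np.linalg.norm(d)
            _, D_b = geom.ray_distances(d[None])
            dp = np.linspace(1e-3, float(D_b[0]) - 1e-3, 300)
            pts = geom.S + dp[:, None] * d
            for params in (DeformationParams("auto"), DeformationParams(2.0, s=0.8)):
                out = forward_warp(pts, geom, params)
                r = np.linalg.norm(out - geom.S, axis=1)
                assert np.all(np.diff(r) > 0)

    def test_outside_brain_unchanged(self, ellipsoid_phantom):
        _, _, _, geom = ellipsoid_phantom
        pts = np.array([[60.0, 0.0, 0.0], [0.0, -50.0, 10.0]])
        np.testing.assert_array_equal(forward_warp(pts, geom, DeformationParams(2.0)), pts)

    def test_tumour_centre_unchanged(self, ellipsoid_phantom):
        _, _, _, geom = ellipsoid_phantom
        np.testing.assert_array_equal(forward_warp(geom.S, geom, DeformationParams(2.0)), geom.S)


class TestInverseWarp:
    def test_round_trip_small_sample(self, ellipsoid_phantom, rng):
        _, _, _, geom = ellipsoid_phantom
        pts = rng.uniform(-38, 38, size=(800, 3))
        pts = pts[geom.inside_brain(pts)]
        for params in (DeformationParams(2.0), DeformationParams("auto", s=0.8)):
            out = inverse_warp(forward_warp(pts, geom, params), geom, params)
            assert np.linalg.norm(out - pts, axis=1).max() < 1e-6

    def test_boundary_point_fixed(self, sphere_phantom):
        _, _, _, geom = sphere_phantom
        d = np.array([0.0, 0.0, 1.0])
        _, D_b = geom.ray_distances(d[None])
        P = geom.S + d * D_b[0]
        out = inverse_warp(P, geom, DeformationParams(2.0))
        assert np.linalg.norm(out - P) < 1e-9

    def test_concentric_sphere_inverse_of_forward_example(self, sphere_phantom):
        _, _, _, geom = sphere_phantom
        params = DeformationParams(2.0)
        fwd = forward_warp(np.array([0.0, 50.0, 0.0]), geom, params)
        back = inverse_warp(fwd, geom, params)
        assert np.linalg.norm(back - geom.S) == pytest.approx(50.0, abs=1e-6)

    def test_strict_lambda_above_ceiling_raises_naming_lambda_max(self, ellipsoid_phantom):
        _, _, _, geom = ellipsoid_phantom
        params = DeformationParams(50.0, lambda_policy="strict")
        # an over-aggressive lambda folds the warp near the centre, where
        # the Lambert argument leaves the principal-branch domain
        target = geom.S + np.array([1.5, 0.0, 0.0])
        with pytest.raises(ParameterError, match="lambda_max"):
            inverse_warp(target, geom, params)


class TestDeformImage:
    def test_s_zero_returns_input_exactly(self, ellipsoid_phantom):
        spec, _, _, geom = ellipsoid_phantom
        img = make_grid_image(spec)
        out = deform_image(img, geom, DeformationParams(2.0, s=0.0))
        np.testing.assert_array_equal(out.data, img.data)

    def test_brain_boundary_pixels_essentially_unchanged(self, ellipsoid_phantom):
        # displacement vanishes at the brain surface, so the outermost
        # voxel shell moves by well under a voxel and its values change
        # only by residual interpolation (image contrast is 0.75)
        from scipy.ndimage import binary_erosion

        spec, brain, _, geom = ellipsoid_phantom
        img = make_grid_image(spec)
        out = deform_image(img, geom, DeformationParams(2.0))
        shell = (brain.data > 0) & ~binary_erosion(brain.data > 0)
        assert shell.sum() > 1000
        change = np.abs(out.data - img.data)[shell]
        assert change.max() < 0.15
        assert change.mean() < 0.02

    def test_interior_mass_expelled_at_lambda_max(self, ellipsoid_phantom):
        spec, brain, tumour, geom = ellipsoid_phantom
        indicator = Volume(tumour.data.astype(float), tumour.affine)
        out = deform_image(indicator, geom, DeformationParams("auto"))
        # strictly interior voxels (more than one voxel from the surface)
        inside = np.isfinite(geom.D_p) & (geom.D_p < geom.D_t - spec.voxel_size)
        assert inside.sum() > 50
        assert np.abs(out.data[inside]).max() < 0.2  # interpolation blur only

    def test_grid_mismatch_rejected(self, ellipsoid_phantom):
        spec, _, _, geom = ellipsoid_phantom
        other = PhantomSpec(shape=(32, 32, 32), voxel_size=4.0)
        img = make_grid_image(other)
        with pytest.raises(Exception, match="grid"):
            deform_image(img, geom, DeformationParams(2.0))

    def test_localisation_increases_with_lambda(self, ellipsoid_phantom):
        # larger lambda concentrates displacement near the tumour, so
        # mid-radius displacement is strictly smaller
        _, _, _, geom = ellipsoid_phantom
        d = np.array([0.0, -1.0, 0.0])
        D_t, D_b = geom.ray_distances(d[None])
        P = geom.S + d * 0.5 * (D_t[0] + D_b[0])
        disp = {}
        for lam in (2.0, 6.0):
            out = forward_warp(P, geom, DeformationParams(lam))
            disp[lam] = np.linalg.norm(out - P)
        assert disp[6.0] < disp[2.0]


class TestCaching:
    def test_warm_cache_is_bit_identical(self, tmp_path, rng):
        spec = PhantomSpec(shape=(32, 32, 32), voxel_size=4.0)
        brain, tumour = make_phantom_masks(spec)
        cold = RadialGeometry.from_masks(brain, tumour, cache_dir=tmp_path / "c")
        img = Volume(rng.random(spec.shape), spec.affine)
        params = DeformationParams(3.0, s=0.8)
        out_cold = deform_image(img, cold, params)

        warm = RadialGeometry.from_masks(brain, tumour, cache_dir=tmp_path / "c")
        assert warm.load_tables(tmp_path / "c")  # really came from disk
        out_warm = deform_image(img, warm, params)
        np.testing.assert_array_equal(out_cold.data, out_warm.data)
        for name in ("D_p", "D_t", "D_b"):
            np.testing.assert_array_equal(getattr(cold, name), getattr(warm, name))

    def test_cache_invalidated_when_masks_change(self, tmp_path):
        spec = PhantomSpec(shape=(32, 32, 32), voxel_size=4.0)
        brain, tumour = make_phantom_masks(spec)
        RadialGeometry.from_masks(brain, tumour, cache_dir=tmp_path / "c")
        bigger = PhantomSpec(shape=(32, 32, 32), voxel_size=4.0, tumour_radius=14.0)
        _, tumour2 = make_phantom_masks(bigger)
        geom2 = RadialGeometry(brain, tumour2)
        assert not geom2.load_tables(tmp_path / "c")
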