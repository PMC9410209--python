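"""Registration stages: resampling, rigid recovery, FFD evaluation."""

import numpy as np
import pytest

from spinedeform.grid import ImageVolume, world_meshgrid
from spinedeform.registration import (
    BSplineTransform,
    RegistrationParams,
    RigidTransform,
    register_bspline,
    register_rigid,
    resample_isotropic,
    resample_with_transform,
    transform_to_field,
)

from conftest import two_stage


class TestResampleIsotropic:
    def test_constant_volume_stays_constant(self):
        vol = ImageVolume(np.full((10, 8, 6), 3.5), (2.0, 1.5, 3.0))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.data, 3.5, atol=1e-12)
        np.testing.assert_allclose(out.spacing, 1.0)

    def test_volume_at_target_spacing_is_unchanged(self):
        rng = np.random.default_rng(1)
        vol = ImageVolume(rng.random((8, 8, 8)), (1.0, 1.0, 1.0))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_linear_ramp_reproduced_exactly(self):
        # trilinear interpolation is exact on affine intensity profiles
        vol = ImageVolume(np.zeros((12, 10, 8)), (2.0, 2.0, 2.0))
        pts = world_meshgrid(vol)
        vol.data[:] = 1.0 + 0.5 * pts[..., 0] - 0.25 * pts[..., 1] + pts[..., 2]
        out = resample_isotropic(vol, 1.0)
        opts = world_meshgrid(out)
        expect = 1.0 + 0.5 * opts[..., 0] - 0.25 * opts[..., 1] + opts[..., 2]
        interior = (slice(2, -2),) * 3
        np.testing.assert_allclose(out.data[interior], expect[interior], atol=1e-10)

    def test_world_extent_preserved(self):
        vol = ImageVolume(np.zeros((10, 8, 6)), (2.0, 1.5, 3.0), (5.0, -2.0, 1.0))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.world_extent()[0], vol.world_extent()[0])
        np.testing.assert_allclose(
            out.world_extent()[1], vol.world_extent()[1], atol=0.51
        )

    def test_invalid_target_rejected(self):
        vol = ImageVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError, match="positive"):
            resample_isotropic(vol, 0.0)


class TestRigidRegistration:
    def test_identity_recovered_on_self_registration(self, small_phantom_clean):
        _, unloaded, _, _, _ = small_phantom_clean
        tr = register_rigid(unloaded, unloaded)
        assert np.abs(tr.translation).max() < 0.1
        assert np.degrees(np.abs(tr.angles)).max() < 0.1

    def test_known_translation_recovered(self, small_phantom_clean):
        _, unloaded, _, _, _ = small_phantom_clean
        shift = np.array([3.0, -2.0, 1.0])
        moved = ImageVolume(
            unloaded.sample_world(
                world_meshgrid(unloaded) + shift, order=1, mode="nearest"
            ),
            unloaded.spacing,
            unloaded.origin,
        )
        tr = register_rigid(unloaded, moved)
        # moved(x) = unloaded(x + shift), so the fixed->moving map is -shift
        np.testing.assert_allclose(tr.translation, -shift, atol=0.2)

    def test_known_rotation_recovered(self, small_phantom_clean):
        _, unloaded, _, _, _ = small_phantom_clean
        center = unloaded.origin + (np.array(unloaded.shape) - 1) * unloaded.spacing / 2
        rot = RigidTransform(
            np.array([0.0, 0.0, np.deg2rad(5.0)]), np.zeros(3), center
        )
        moved = ImageVolume(
            unloaded.sample_world(
                rot.apply(world_meshgrid(unloaded)), order=1, mode="nearest"
            ),
            unloaded.spacing,
            unloaded.origin,
        )
        tr = register_rigid(unloaded, moved)
        assert np.degrees(tr.angles[2]) == pytest.approx(-5.0, abs=0.5)

    def test_disjoint_extents_rejected(self):
        a = ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0))
        b = ImageVolume(np.zeros((8, 8, 8)), (1.0, 1.0, 1.0), (100.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="overlap"):
            register_rigid(a, b)


class TestTransformEvaluation:
    def _small_bspline(self):
        rigid = RigidTransform.identity()
        coeffs = np.zeros((3, 7, 7, 7))
        return BSplineTransform(
            grid_origin=np.full(3, -10.0),
            grid_spacing=np.full(3, 10.0),
            coeffs=coeffs,
            rigid=rigid,
            domain_low=np.zeros(3),
            domain_high=np.full(3, 40.0),
        )

    def test_identity_transform_yields_zero_field(self):
        grid = ImageVolume(np.zeros((8, 8, 8)), np.full(3, 5.0))
        field = transform_to_field(self._small_bspline(), grid)
        np.testing.assert_allclose(field, 0.0, atol=1e-14)

    def test_pure_translation_yields_constant_field(self):
        grid = ImageVolume(np.zeros((8, 8, 8)), np.full(3, 5.0))
        tr = RigidTransform(np.zeros(3), np.array([2.0, -1.0, 0.5]), np.zeros(3))
        field = transform_to_field(tr, grid)
        np.testing.assert_allclose(
            field, np.broadcast_to([2.0, -1.0, 0.5], field.shape), atol=1e-12
        )

    def test_perturbed_control_point_matches_basis_summation_oracle(self):
        tr = self._small_bspline()
        tr.coeffs[2, 3, 3, 3] = 4.0  # one displaced control point
        rng = np.random.default_rng(2)
        pts = rng.uniform(5, 35, size=(40, 3))
        got = tr.displacement(pts)

        def basis(t):
            return np.array(
                [
                    (1 - t) ** 3 / 6,
                    (3 * t**3 - 6 * t**2 + 4) / 6,
                    (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6,
                    t**3 / 6,
                ]
            )

        # brute-force tensor-product summation over the full lattice
        expect = np.zeros((40, 3))
        for p, pt in enumerate(pts):
            tf = (pt - tr.grid_origin) / tr.grid_spacing
            i = np.floor(tf).astype(int)
            t = tf - i
            bx, by, bz = basis(t[0]), basis(t[1]), basis(t[2])
            for l in range(4):
                for m in range(4):
                    for k in range(4):
                        w = bx[l] * by[m] * bz[k]
                        expect[p] += w * tr.coeffs[
                            :, i[0] - 1 + l, i[1] - 1 + m, i[2] - 1 + k
                        ]
        np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_grid_and_scattered_evaluation_agree(self):
        tr = self._small_bspline()
        rng = np.random.default_rng(4)
        tr.coeffs[:] = rng.normal(0, 1.5, size=tr.coeffs.shape)
        grid = ImageVolume(np.zeros((9, 9, 9)), np.full(3, 4.0))
        fast = tr.displacement_on_grid(grid)
        slow = tr.displacement(world_meshgrid(grid))
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_out_of_domain_grid_rejected(self):
        tr = self._small_bspline()
        grid = ImageVolume(np.zeros((8, 8, 8)), np.full(3, 10.0))
        with pytest.raises(ValueError, match="domain"):
            transform_to_field(tr, grid)


class TestResampleWithTransform:
    def test_identity_returns_input(self):
        rng = np.random.default_rng(0)
        vol = ImageVolume(rng.random((8, 8, 8)), np.ones(3))
        out = resample_with_transform(vol, RigidTransform.identity(), vol)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_integer_translation_shifts_block_exactly(self):
        vol = ImageVolume(np.zeros((10, 10, 10)), np.ones(3))
        vol.data[4:7, 4:7, 4:7] = 1.0
        tr = RigidTransform(np.zeros(3), np.array([0.0, 0.0, 3.0]), np.zeros(3))
        out = resample_with_transform(vol, tr, vol)
        np.testing.assert_array_equal(out.data[4:7, 4:7, 1:4], 1.0)
        assert out.data.sum() == vol.data.sum()


class TestBSplineRegistration:
    def test_self_registration_recovers_near_zero_field(self, small_phantom):
        _, unloaded, _, _, _ = small_phantom
        params = RegistrationParams(max_iterations=50)
        tr = register_bspline(unloaded, unloaded, params=params)
        field = transform_to_field(tr, unloaded)
        assert np.abs(field).max() < 0.2

    def test_registration_is_deterministic(self, small_phantom):
        _, unloaded, loaded, _, _ = small_phantom
        params = RegistrationParams(max_iterations=30)
        a = register_bspline(unloaded, loaded, params=params)
        b = register_bspline(unloaded, loaded, params=params)
        np.testing.assert_array_equal(a.coeffs, b.coeffs)

    def test_accepted_cost_log_is_monotone(self, small_phantom):
        _, unloaded, loaded, _, _ = small_phantom
        tr = register_bspline(
            unloaded, loaded, params=RegistrationParams(max_iterations=50)
        )
        assert all(h["monotone"] for h in tr.info["history"])

    def test_mutual_information_unsupported_for_ffd(self, small_phantom):
        _, unloaded, loaded, _, _ = small_phantom
        with pytest.raises(NotImplementedError, match="mean-squared"):
            register_bspline(
                unloaded, loaded, params=RegistrationParams(metric="mi")
            )

    def test_warped_image_correlates_with_fixed(self, small_phantom):
        _, unloaded, loaded, truth, _ = small_phantom
        tr = two_stage(unloaded, loaded)
        warped = resample_with_transform(loaded, tr, unloaded)
        body = unloaded.data > 40  # tissue only; air is pure noise
        ncc = np.corrcoef(unloaded.data[body], warped.data[body])[0, 1]
        assert ncc >= 0.95

    def test_inverse_consistency_smoke(self, small_phantom):
        # forward then backward registration should compose to near
        # identity wherever the images carry signal (air is unconstrained
        # by any intensity metric, so it is excluded)
        _, unloaded, loaded, _, _ = small_phantom
        fwd = two_stage(unloaded, loaded)
        bwd = two_stage(loaded, unloaded)
        pts = world_meshgrid(unloaded)[::2, ::2, ::2].reshape(-1, 3)
        body = (unloaded.data[::2, ::2, ::2] > 40).reshape(-1)
        composed = bwd.apply(fwd.apply(pts)) - pts
        assert np.linalg.norm(composed[body], axis=-1).mean() < 1.0


class TestCubicImageModel:
    """The fused sampler must agree with scipy's spline interpolation."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fused_kernel_matches_map_coordinates(self, seed):
        from scipy import ndimage

        from spinedeform.registration import _cubic_value_grad

        rng = np.random.default_rng(seed)
        coef = ndimage.spline_filter(rng.standard_normal((9, 8, 10)))
        pts = rng.uniform(1.0, 6.0, size=(50, 3))
        out = _cubic_value_grad(coef, pts)
        expect = ndimage.map_coordinates(coef, pts.T, order=3, prefilter=False)
        np.testing.assert_allclose(out[:, 0], expect, atol=1e-12)
        # analytic derivative vs central differences of the same spline
        h = 1e-6
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            num = (
                ndimage.map_coordinates(coef, (pts + e).T, order=3, prefilter=False)
                - ndimage.map_coordinates(coef, (pts - e).T, order=3, prefilter=False)
            ) / (2 * h)
            np.testing.assert_allclose(out[:, 1 + ax], num, atol=1e-5)


class TestSerialization:
    def test_rigid_roundtrip(self, tmp_path):
        tr = RigidTransform(
            np.array([0.01, -0.02, 0.03]), np.array([1.0, 2.0, -3.0]),
            np.array([10.0, 20.0, 30.0]),
        )
        tr.save(tmp_path / "rigid.json")
        back = RigidTransform.load(tmp_path / "rigid.json")
        np.testing.assert_allclose(back.angles, tr.angles)
        np.testing.assert_allclose(back.translation, tr.translation)
        np.testing.assert_allclose(back.center, tr.center)

    def test_bspline_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        tr = BSplineTransform(
            grid_origin=np.full(3, -16.0),
            grid_spacing=np.full(3, 16.0),
            coeffs=rng.normal(size=(3, 6, 5, 8)),
            rigid=RigidTransform.identity((1.0, 2.0, 3.0)),
            domain_low=np.zeros(3),
            domain_high=np.array([48.0, 32.0, 80.0]),
        )
        tr.save(tmp_path / "ffd")
        back = BSplineTransform.load(tmp_path / "ffd")
        np.testing.assert_allclose(back.coeffs, tr.coeffs, atol=1e-6)
        pts = rng.uniform(5, 30, size=(10, 3))
        np.testing.assert_allclose(back.apply(pts), tr.apply(pts), atol=1e-5)
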