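"""Regional decomposition, morphometrics and overlap QC."""

import numpy as np
import pandas as pd
import pytest

from spinedeform.disc_analysis import (
    dice_jaccard,
    disc_angle,
    disc_height,
    mid_sagittal_slices,
    propagate_mask,
    region_diff_vs_angle_change,
    subregion_partition,
    tilt_angle,
)
from spinedeform.grid import ImageVolume
from spinedeform.registration import RigidTransform

SPACING = np.array([1.0, 1.0, 1.0])


def _random_blob(rng, shape=(24, 24, 16)):
    """Connected random mask: an ellipsoid with jittered radii."""
    c = np.array(shape) / 2 + rng.uniform(-2, 2, size=3)
    radii = rng.uniform(4, min(shape) / 2 - 1, size=3)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    )
    return (np.sum(((idx - c) / radii) ** 2, axis=-1) <= 1.0), idx


class TestMidSagittalSlices:
    def test_centered_window_in_odd_span(self):
        mask = np.zeros((30, 8, 8), dtype=bool)
        mask[10:21] = True  # spans slices 10..20
        np.testing.assert_array_equal(
            mid_sagittal_slices(mask, 3), [14, 15, 16]
        )

    def test_full_span_returns_all_slices(self):
        mask = np.zeros((12, 4, 4), dtype=bool)
        mask[3:9] = True
        np.testing.assert_array_equal(mid_sagittal_slices(mask, 6), range(3, 9))

    def test_matches_enumeration_oracle_with_low_tie_break(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            mask = np.zeros((20, 6, 6), dtype=bool)
            lo = rng.integers(0, 8)
            hi = rng.integers(lo + 4, 18)
            mask[lo : hi + 1] = True
            n = int(rng.integers(1, hi - lo + 1))
            got = mid_sagittal_slices(mask, n)
            counts = mask.sum(axis=(1, 2)).astype(float)
            centroid = np.average(np.arange(20), weights=counts)
            # enumerate all windows; pick min distance, ties toward lower
            best = min(
                range(lo, hi - n + 2),
                key=lambda s: (abs(s + (n - 1) / 2 - centroid), s),
            )
            np.testing.assert_array_equal(got, np.arange(best, best + n))

    def test_narrow_mask_raises(self):
        mask = np.zeros((10, 4, 4), dtype=bool)
        mask[4:6] = True
        with pytest.raises(ValueError, match="spans 2"):
            mid_sagittal_slices(mask, 3)


class TestSubregionPartition:
    def test_rectangular_mask_splits_into_equal_fifths(self):
        mask = np.zeros((9, 20, 6), dtype=bool)
        mask[2:7, 0:20, 1:5] = True  # 20 voxels deep along y (the AP axis)
        regions = subregion_partition(mask, SPACING, 5)
        for r in range(1, 6):
            cols = np.unique(np.nonzero(regions == r)[1])
            np.testing.assert_array_equal(cols, np.arange((r - 1) * 4, r * 4))

    def test_partition_property_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            mask, _ = _random_blob(rng)
            regions = subregion_partition(mask, SPACING, 5)
            assert ((regions > 0) == mask).all()  # union covers exactly
            assert set(np.unique(regions[mask])) <= {1, 2, 3, 4, 5}

    def test_l_shaped_mask_matches_brute_force_projection_oracle(self):
        mask = np.zeros((7, 18, 12), dtype=bool)
        mask[2:5, 0:18, 2:5] = True
        mask[2:5, 0:6, 5:10] = True  # the L's vertical bar, anterior side
        spacing = np.array([1.0, 1.5, 2.0])
        regions = subregion_partition(mask, spacing, 5)
        # oracle: project voxels on the dominant sagittal-plane axis and
        # cut the extent into equal fifths
        from spinedeform.disc_analysis import _sagittal_pca_axis

        axis = _sagittal_pca_axis(mask, spacing)
        ii, jj, kk = np.nonzero(mask)
        proj = jj * spacing[1] * axis[0] + kk * spacing[2] * axis[1]
        edges = np.linspace(proj.min(), proj.max(), 6)
        expect = np.minimum(np.searchsorted(edges, proj, side="right"), 5)
        expect[proj == proj.min()] = 1
        np.testing.assert_array_equal(regions[ii, jj, kk], expect)

    def test_thin_mask_raises(self):
        mask = np.zeros((6, 4, 4), dtype=bool)
        mask[2, 1:3, 1:3] = True
        with pytest.raises(ValueError, match="thinner"):
            subregion_partition(mask, SPACING, 5)


class TestDiscHeight:
    def test_axis_aligned_slab(self):
        mask = np.zeros((20, 20, 12), dtype=bool)
        mask[2:18, 2:18, 2:10] = True  # 8 voxels thick along z
        assert disc_height(mask, SPACING) == pytest.approx(8.0, abs=1.0)

    def test_rotated_slab_measured_along_normal(self):
        # slab of thickness 8 mm whose plane is tilted 20 degrees about x
        n = np.array([0.0, -np.sin(np.deg2rad(20)), np.cos(np.deg2rad(20))])
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in (24, 40, 40)], indexing="ij"),
            axis=-1,
        )
        d = (idx - np.array([12, 20, 20])) @ n
        mask = (np.abs(d) <= 4.0) & (np.abs(idx[..., 1] - 20) < 15)
        assert disc_height(mask, SPACING) == pytest.approx(8.0, abs=0.75)

    def test_ellipsoid_minor_axis(self):
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in (40, 40, 24)], indexing="ij"),
            axis=-1,
        )
        radii = np.array([15.0, 11.0, 5.0])
        mask = np.sum(((idx - [20, 20, 12]) / radii) ** 2, axis=-1) <= 1.0
        assert disc_height(mask, SPACING) == pytest.approx(10.0, abs=0.75)

    def test_single_layer_mask_warns(self):
        mask = np.zeros((10, 10, 5), dtype=bool)
        mask[2:8, 2:8, 2] = True
        with pytest.warns(UserWarning, match="single-voxel"):
            h = disc_height(mask, SPACING)
        assert h == pytest.approx(1.0)


class TestAngles:
    def test_known_angles(self):
        horiz = [[0, 0, 0], [0, 10, 0]]
        assert tilt_angle(horiz, [[0, 0, 0], [0, 10, 10 * np.tan(np.deg2rad(12))]]) == pytest.approx(12.0, abs=1e-9)
        assert tilt_angle(horiz, horiz) == pytest.approx(0.0)
        assert disc_angle([[0, 0, 0], [0, 1, 0]], [[0, 0, 0], [0, 0.866, 0.5]]) == pytest.approx(30.0, abs=0.01)

    def test_angle_is_unsigned_and_acute(self):
        a = [[0, 0, 0], [0, 1, 0]]
        b = [[0, 0, 0], [0, -1, 0.2]]  # opposite direction
        assert tilt_angle(a, b) == pytest.approx(
            np.degrees(np.arctan(0.2)), abs=1e-9
        )

    def test_zero_length_segment_raises(self):
        with pytest.raises(ValueError, match="zero-length"):
            tilt_angle([[0, 0, 0], [0, 0, 0]], [[0, 0, 0], [0, 1, 0]])


class TestRigidInvariance:
    def test_height_invariant_under_global_rotation(self):
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in (32, 32, 32)], indexing="ij"),
            axis=-1,
        )
        base = (np.abs(idx[..., 2] - 16) <= 4) & (
            np.sum((idx[..., :2] - 16) ** 2, axis=-1) < 100
        )
        h0 = disc_height(base, SPACING)
        rot = RigidTransform(
            np.array([np.deg2rad(15), 0, 0]), np.zeros(3), np.full(3, 16.0)
        )
        # voxelize the rotated mask by pulling back through the inverse
        back = (idx - 16.0) @ rot.matrix() + 16.0  # R^T = inverse rotation
        d = np.abs(back[..., 2] - 16)
        r = np.sum((back[..., :2] - 16) ** 2, axis=-1)
        rotated = (d <= 4) & (r < 100)
        assert disc_height(rotated, SPACING) == pytest.approx(h0, abs=0.75)


class TestOverlap:
    def test_trivial_cases(self):
        a = np.zeros((6, 6, 6), dtype=int)
        a[1:4, 1:4, 1:4] = 1
        same = dice_jaccard(a, a.copy())
        assert same.mean_dice == 1.0 and same.mean_jaccard == 1.0
        b = np.zeros_like(a)
        b[4:6, 4:6, 4:6] = 1
        disjoint = dice_jaccard(a, b)
        assert disjoint.mean_dice == 0.0 and disjoint.mean_jaccard == 0.0

    def test_hand_counted_overlap(self):
        a = np.zeros((8, 1, 1), dtype=int)
        b = np.zeros((8, 1, 1), dtype=int)
        a[0:4] = 1
        b[2:6] = 1  # |A|=|B|=4, intersection 2
        res = dice_jaccard(a, b)
        assert res.mean_dice == pytest.approx(0.5)
        assert res.mean_jaccard == pytest.approx(1 / 3)

    def test_dice_jaccard_identity_on_random_masks(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            a = rng.random((10, 10, 10)) > 0.6
            b = rng.random((10, 10, 10)) > 0.6
            if not (a.any() and b.any()):
                continue
            res = dice_jaccard(a.astype(int), b.astype(int))
            d, j = res.mean_dice, res.mean_jaccard
            assert d >= j
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_empty_masks_raise(self):
        z = np.zeros((4, 4, 4), dtype=int)
        with pytest.raises(ValueError, match="empty"):
            dice_jaccard(z, z)


class TestMaskPropagation:
    def test_identity_returns_same_labels(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels[2:5, 3:6, 4:7] = 3
        vol = ImageVolume(labels, SPACING)
        out = propagate_mask(vol, RigidTransform.identity())
        np.testing.assert_array_equal(out.data, labels)

    def test_integer_translation_shifts_exactly(self):
        labels = np.zeros((12, 12, 12), dtype=np.int16)
        labels[4:7, 4:7, 4:7] = 2
        vol = ImageVolume(labels, SPACING)
        # T maps fixed coords to moving coords; shifting by +2 along x
        # pulls the block 2 voxels toward lower x in fixed space
        t = RigidTransform(np.zeros(3), np.array([2.0, 0, 0]), np.zeros(3))
        out = propagate_mask(vol, t)
        np.testing.assert_array_equal(out.data[2:5, 4:7, 4:7], 2)
        assert out.data.sum() == labels.sum()

    def test_phantom_warp_matches_brute_force_oracle(self, small_phantom_clean):
        _, unloaded, _, truth, _ = small_phantom_clean

        class _Warp:  # forward analytic map as a transform object
            def apply(self, pts):
                return truth.field.forward_points(pts)

        out = propagate_mask(truth.masks_loaded, _Warp(), unloaded)
        from spinedeform.grid import world_meshgrid

        pts = truth.field.forward_points(world_meshgrid(unloaded))
        expect = truth.masks_loaded.sample_world(pts, order=0)
        np.testing.assert_array_equal(out.data, expect.astype(out.data.dtype))


class TestRegionMeanConsistency:
    def test_weighted_region_means_equal_mid_slice_disc_mean(self):
        """The voxel-count-weighted mean of the five subregion means must
        reproduce the mid-sagittal-slice disc mean exactly."""
        from spinedeform.deformation import JacobianMap, deformation_in_mask

        rng = np.random.default_rng(14)
        shape = (15, 20, 10)
        d = rng.uniform(0.9, 1.2, size=shape)
        jmap = JacobianMap(
            jacobian=np.empty(shape + (3, 3)), det=1.0 / d, d=d,
            spacing=SPACING,
        )
        mask = np.zeros(shape, dtype=bool)
        mask[3:12, 2:18, 2:8] = True
        regions = subregion_partition(mask, SPACING, 5)
        mid3 = mid_sagittal_slices(mask, 3)
        sel3 = np.zeros_like(mask)
        sel3[mid3] = mask[mid3]
        total = 0.0
        count = 0
        for r in range(1, 6):
            rmask = (regions == r) & sel3
            res = deformation_in_mask(jmap, rmask)
            total += res.mean * res.count
            count += res.count
        disc_mean = deformation_in_mask(jmap, sel3).mean
        assert total / count == pytest.approx(disc_mean, abs=1e-12)


class TestRegionAngleSubanalysis:
    def test_rejects_small_and_degenerate_tables(self):
        df = pd.DataFrame(
            {"disc_angle_change": [1.0, 2.0], "region_diff_1_5": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="at least 3"):
            region_diff_vs_angle_change(df)
        same = pd.DataFrame(
            {"disc_angle_change": [1.0, 1.0, 1.0], "region_diff_1_5": [0.1, 0.1, 0.1]}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            region_diff_vs_angle_change(same)

    def test_recovers_positive_association(self):
        rng = np.random.default_rng(13)
        angle = np.linspace(0, 5, 12)
        df = pd.DataFrame(
            {
                "disc_angle_change": angle,
                "region_diff_1_5": 0.02 * angle + rng.normal(0, 0.005, 12),
            }
        )
        _, res = region_diff_vs_angle_change(df)
        assert res.r > 0.8
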