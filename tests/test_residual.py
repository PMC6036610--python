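"""The residual-volume metric: boolean identities, descriptors, resampling."""

import math

import numpy as np
import pytest

from residualstl import (
    GeometryError,
    ImageVolume,
    ParameterError,
    TriangleMesh,
    compare_meshes,
    extract_surface,
    mask_volume,
    rasterize_mesh,
    resample_to_reference,
    residual_report,
    symmetric_difference,
)

from conftest import make_mask, random_blob


def random_mask(rng, shape=(12, 12, 12), p=0.5):
    return make_mask(rng.random(shape) < p)


class TestSymmetricDifference:
    def test_identical_masks_give_empty_residual(self, rng):
        mask = random_mask(rng)
        assert symmetric_difference(mask, mask).count == 0

    def test_dilated_cube_matches_brute_force_xor(self):
        a = np.zeros((9, 9, 9), bool)
        a[3:6, 3:6, 3:6] = True       # 3^3
        b = np.zeros((9, 9, 9), bool)
        b[2:7, 2:7, 2:7] = True       # 5^3
        out = symmetric_difference(make_mask(a), make_mask(b))
        brute = int(np.sum(a ^ b))
        assert out.count == brute == 125 - 27

    def test_symmetry_under_argument_swap(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert np.array_equal(symmetric_difference(a, b).data,
                              symmetric_difference(b, a).data)

    def test_grid_mismatch_rejected_without_resampling(self, rng):
        a = random_mask(rng)
        b = make_mask(a.data, spacing=(0.5, 0.5, 0.5))
        with pytest.raises(GeometryError):
            symmetric_difference(a, b)

    def test_inclusion_exclusion_exact_on_voxel_counts(self, rng):
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            union = int(np.sum(a.data | b.data))
            inter = int(np.sum(a.data & b.data))
            assert union + inter == a.count + b.count
            assert symmetric_difference(a, b).count == union - inter

    def test_triangle_inequality_on_voxel_counts(self, rng):
        for _ in range(20):
            a, b, c = (random_mask(rng) for _ in range(3))
            d_ac = symmetric_difference(a, c).count
            d_ab = symmetric_difference(a, b).count
            d_bc = symmetric_difference(b, c).count
            assert d_ac <= d_ab + d_bc


class TestResidualReport:
    def test_fraction_is_percent_of_reference(self):
        # 50 cm^3 reference; alt adds a separate 1 cm^3 block
        ref = np.zeros((60, 60, 60), bool)
        ref[5:55, 5:55, 5:25] = True           # 50*50*20 = 50000 voxels @ 1 mm
        alt = ref.copy()
        alt[5:15, 5:15, 40:50] = True          # +1000 voxels
        report = residual_report(make_mask(ref), make_mask(alt))
        assert report.v_ref == pytest.approx(50.0)
        assert report.v_residual == pytest.approx(1.0)
        assert report.fraction == pytest.approx(2.0)

    def test_slab_thickening_thickness_reads_half_layer(self):
        # plate 20 voxels thick; alt thickened by one 0.5 mm layer on both
        # large faces; laterally wide, so volume/area -> t/2 = 0.25 mm
        ref = np.zeros((30, 80, 80), bool)
        ref[5:25, :, :] = True
        alt = np.zeros_like(ref)
        alt[4:26, :, :] = True
        report = residual_report(make_mask(ref, spacing=(0.5, 0.5, 0.5)),
                                 make_mask(alt, spacing=(0.5, 0.5, 0.5)))
        assert report.thickness == pytest.approx(0.25, rel=0.15)

    def test_self_comparison_is_zero_with_nan_thickness(self, rng):
        mask = random_blob(rng, min_voxels=200)
        report = residual_report(mask, mask)
        assert report.v_residual == 0.0
        assert report.fraction == 0.0
        assert math.isnan(report.thickness)

    def test_inclusion_exclusion_at_mesh_level(self, rng):
        a = random_blob(rng, min_voxels=500)
        shifted = np.roll(a.data, 2, axis=0)
        b = make_mask(shifted)
        report = residual_report(a, b)
        # voxel-exact meshing: union + intersection == ref + alt identically
        assert report.v_union + report.v_intersection == pytest.approx(
            report.v_ref + report.v_alt, rel=1e-9)
        assert report.v_residual == pytest.approx(
            report.v_union - report.v_intersection, rel=1e-9)
        assert report.v_residual >= 0

    def test_residual_volume_is_symmetric_fraction_is_not(self, rng):
        a = random_blob(rng, min_voxels=300)
        b = make_mask(np.roll(a.data, 1, axis=1))
        ab = residual_report(a, b)
        ba = residual_report(b, a)
        assert ab.v_residual == pytest.approx(ba.v_residual, rel=1e-9)
        assert ab.fraction * ab.v_ref == pytest.approx(ba.fraction * ba.v_ref, rel=1e-9)

    def test_mesh_residual_agrees_with_voxel_oracle(self, rng):
        a = random_blob(rng, min_voxels=500)
        b = make_mask(np.roll(a.data, 3, axis=2))
        report = residual_report(a, b)
        voxel_xor = mask_volume(symmetric_difference(a, b))
        assert report.v_residual == pytest.approx(voxel_xor, rel=0.05)

    def test_empty_reference_rejected(self, rng):
        empty = make_mask(np.zeros((5, 5, 5)))
        with pytest.raises(ParameterError):
            residual_report(empty, random_mask(rng, (5, 5, 5)))


class TestResample:
    def test_identity_resample_is_bitwise_equal(self):
        vol = ImageVolume(data=np.arange(27, dtype=float).reshape(3, 3, 3),
                          spacing=(1, 1, 1))
        out = resample_to_reference(vol, vol, method="nearest")
        assert np.array_equal(out.data, vol.data)

    def test_nearest_upsampling_replicates_blocks(self):
        vol = ImageVolume(data=np.arange(8, dtype=float).reshape(2, 2, 2),
                          spacing=(1, 1, 1))
        target = ImageVolume(data=np.zeros((4, 4, 4)), spacing=(0.5, 0.5, 0.5),
                             origin=(-0.25, -0.25, -0.25))
        out = resample_to_reference(vol, target, method="nearest")
        for axis_block in ((0, 0, 0), (1, 1, 1)):
            i, j, k = axis_block
            block = out.data[2 * i:2 * i + 2, 2 * j:2 * j + 2, 2 * k:2 * k + 2]
            assert np.all(block == vol.data[i, j, k])

    def test_disjoint_extents_rejected(self):
        a = ImageVolume(data=np.zeros((3, 3, 3)), spacing=(1, 1, 1))
        b = ImageVolume(data=np.zeros((3, 3, 3)), spacing=(1, 1, 1),
                        origin=(100.0, 100.0, 100.0))
        with pytest.raises(GeometryError):
            resample_to_reference(a, b)


class TestMeshComparison:
    def test_rasterized_cube_volume_matches_solid(self):
        from conftest import solid_block

        cube = extract_surface(solid_block((4, 4, 4)))  # 4 mm cube
        mask = rasterize_mesh(cube, pitch=0.5)
        assert mask_volume(mask) == pytest.approx(0.064, rel=0.02)

    def test_identical_stls_have_zero_residual(self):
        from conftest import solid_block

        cube = extract_surface(solid_block((4, 4, 4)))
        report = compare_meshes(cube, cube, pitch=0.5)
        assert report.v_residual == 0.0

    def test_shifted_cube_residual_is_swept_volume(self):
        from conftest import solid_block

        cube = extract_surface(solid_block((4, 4, 4)))
        shifted = TriangleMesh(cube.vertices + np.array([1.0, 0.0, 0.0]), cube.faces)
        report = compare_meshes(cube, shifted, pitch=0.25)
        # symmetric difference of a 4 mm cube and its 1 mm translate:
        # 2 * (1 x 4 x 4) mm^3 = 0.032 cm^3
        assert report.v_residual == pytest.approx(0.032, rel=0.05)
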