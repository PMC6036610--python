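"""Thresholding, cropping and connected-component selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from residualstl import (
    CropBox,
    ImageVolume,
    ParameterError,
    connected_component,
    crop,
    threshold_mask,
)

from conftest import make_mask


def hu_volume(values, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(data=np.asarray(values, float), spacing=spacing)


class TestThreshold:
    def test_bone_window_is_inclusive_on_both_bounds(self):
        vol = hu_volume(np.array([-1000, 225, 226, 500, 3071, 3072], float).reshape(1, 1, 6))
        mask = threshold_mask(vol, 226, 3071)
        assert mask.data.ravel().tolist() == [False, False, True, True, True, False]

    def test_open_upper_bound_includes_everything(self):
        vol = hu_volume(np.array([[-1024.0, 5000.0], [0.0, 99.0]]).reshape(1, 2, 2))
        assert threshold_mask(vol, -1024, np.inf).count == 4

    def test_uniform_volume_below_threshold_is_empty(self):
        assert threshold_mask(hu_volume(np.zeros((3, 3, 3))), 226, 3071).count == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ParameterError):
            threshold_mask(hu_volume(np.zeros((2, 2, 2))), 100, 50)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(hnp.arrays(float, (4, 4, 4), elements=st.floats(-1100, 3200)),
           st.floats(-1000, 1000), st.floats(0, 1000), st.floats(0, 1000))
    def test_monotone_in_the_window(self, data, lo, widen_lo, widen_hi):
        """Enlarging [lo, hi] never removes a voxel."""
        vol = hu_volume(data)
        hi = lo + 500.0
        narrow = threshold_mask(vol, lo, hi)
        wide = threshold_mask(vol, lo - widen_lo, hi + widen_hi)
        assert np.all(wide.data[narrow.data])


class TestCrop:
    def test_full_extent_is_identity(self, rng):
        mask = make_mask(rng.random((6, 7, 8)) > 0.5)
        box = CropBox(lo=(0, 0, 0), hi=(5, 6, 7))
        out = crop(mask, box)
        assert np.array_equal(out.data, mask.data)
        assert np.array_equal(out.origin, mask.origin)

    def test_octant_crop_matches_brute_force_recount(self, rng):
        mask = make_mask(rng.random((10, 10, 10)) > 0.5, spacing=(0.5, 0.5, 0.5))
        box = CropBox(lo=(0, 0, 0), hi=(4, 4, 4))
        out = crop(mask, box)
        brute = sum(
            bool(mask.data[i, j, k])
            for i in range(5) for j in range(5) for k in range(5)
        )
        assert out.count == brute
        assert out.shape == (5, 5, 5)

    def test_origin_shifts_by_low_corner(self):
        mask = make_mask(np.ones((4, 4, 4)), spacing=(0.5, 1.0, 2.0))
        out = crop(mask, CropBox(lo=(1, 2, 3), hi=(3, 3, 3)))
        assert np.allclose(out.origin, (0.5, 2.0, 6.0))

    def test_identical_geometry_for_two_masks_on_same_grid(self, rng):
        a = make_mask(rng.random((8, 8, 8)) > 0.5)
        b = make_mask(rng.random((8, 8, 8)) > 0.5)
        box = CropBox(lo=(2, 1, 0), hi=(6, 5, 4))
        ca, cb = crop(a, box), crop(b, box)
        assert ca.shape == cb.shape
        assert np.array_equal(ca.origin, cb.origin)

    def test_out_of_bounds_box_rejected(self):
        mask = make_mask(np.ones((4, 4, 4)))
        with pytest.raises(ParameterError):
            crop(mask, CropBox(lo=(0, 0, 0), hi=(4, 3, 3)))
        with pytest.raises(ParameterError):
            CropBox(lo=(2, 0, 0), hi=(1, 3, 3))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(hnp.arrays(float, (6, 6, 6), elements=st.floats(-1000, 2000)))
    def test_crop_commutes_with_threshold(self, data):
        vol = ImageVolume(data=data, spacing=(1, 1, 1))
        box = CropBox(lo=(1, 0, 2), hi=(4, 5, 5))
        a = crop(threshold_mask(vol, 200, 1500), box)
        from residualstl import crop_volume

        b = threshold_mask(crop_volume(vol, box), 200, 1500)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.origin, b.origin)


class TestConnectedComponent:
    @staticmethod
    def two_blocks():
        data = np.zeros((10, 10, 10), bool)
        data[1:4, 1:4, 1:4] = True   # 27 voxels
        data[6:8, 6:8, 6:8] = True   # 8 voxels
        return make_mask(data)

    def test_seed_selects_its_component(self):
        out = connected_component(self.two_blocks(), seed=(2, 2, 2))
        assert out.count == 27

    def test_largest_selects_biggest_component(self):
        out = connected_component(self.two_blocks(), seed="largest")
        assert out.count == 27

    def test_single_block_unchanged(self):
        mask = make_mask(np.ones((3, 4, 5)))
        out = connected_component(mask)
        assert np.array_equal(out.data, mask.data)

    def test_corner_contact_is_not_face_adjacency(self):
        data = np.zeros((4, 4, 4), bool)
        data[0:2, 0:2, 0:2] = True
        data[2:4, 2:4, 2:4] = True  # touches only at the corner voxel vertex
        out6 = connected_component(make_mask(data), connectivity=6, seed="largest")
        assert out6.count == 8
        out26 = connected_component(make_mask(data), connectivity=26, seed="largest")
        assert out26.count == 16

    def test_output_is_subset_and_idempotent(self, rng):
        mask = make_mask(rng.random((12, 12, 12)) > 0.6)
        out = connected_component(mask, seed="largest")
        assert np.all(mask.data[out.data])
        again = connected_component(out, seed="largest")
        assert np.array_equal(again.data, out.data)

    def test_tie_break_prefers_smallest_linear_index(self):
        data = np.zeros((5, 5, 5), bool)
        data[4, 4, 4] = True  # later in flat order
        data[0, 0, 0] = True  # earlier in flat order
        out = connected_component(make_mask(data), seed="largest")
        assert out.data[0, 0, 0] and not out.data[4, 4, 4]

    def test_false_seed_rejected(self):
        with pytest.raises(ParameterError):
            connected_component(self.two_blocks(), seed=(0, 0, 0))

    def test_bad_connectivity_rejected(self):
        with pytest.raises(ParameterError):
            connected_component(self.two_blocks(), connectivity=4)
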