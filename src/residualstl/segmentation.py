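"""Bone segmentation on the voxel grid: threshold, crop, connected component.

The segmentation pipeline mirrors the standard semi-automatic workflow of
medical 3D-printing software: include every voxel inside an HU window
(defaults 226..3071 HU, the conventional bone window), crop to the anatomy
of interest, then keep a single connected component under face adjacency
("region growing" with 6-connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .io_formats import ImageVolume

#: Default HU window for bone.
BONE_HU_LO = 226.0
BONE_HU_HI = 3071.0


@dataclass
class BinaryMask:
    """A boolean voxel grid sharing an :class:`ImageVolume`'s geometry."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ParameterError(f"mask must be rank 3, got shape {self.data.shape}")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def count(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "BinaryMask | ImageVolume") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.spacing, other.spacing)
            and np.array_equal(self.origin, other.origin)
        )


@dataclass(frozen=True)
class CropBox:
    """Per-axis inclusive low/high voxel indices."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.lo) != 3 or len(self.hi) != 3:
            raise ParameterError("crop box needs 3 low and 3 high indices")
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise ParameterError(f"crop box low > high: {self.lo} vs {self.hi}")

    def validate_within(self, shape: tuple[int, int, int]) -> None:
        if any(l < 0 for l in self.lo) or any(h >= s for h, s in zip(self.hi, shape)):
            raise ParameterError(f"crop box {self.lo}..{self.hi} outside volume of shape {shape}")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))  # type: ignore[return-value]


def threshold_mask(vol: ImageVolume, lo: float = BONE_HU_LO, hi: float = BONE_HU_HI) -> BinaryMask:
    """Voxels with ``lo <= HU <= hi`` (both bounds inclusive).

    ``hi`` may be ``numpy.inf`` for an open-ended upper window.
    """
    if lo > hi:
        raise ParameterError(f"threshold lower bound {lo} exceeds upper bound {hi}")
    data = (vol.data >= lo) & (vol.data <= hi)
    return BinaryMask(data=data, spacing=vol.spacing.copy(), origin=vol.origin.copy())


def crop(mask: BinaryMask, box: CropBox) -> BinaryMask:
    """Restrict a mask to a voxel-index box; the origin shifts accordingly."""
    box.validate_within(mask.shape)
    data = mask.data[box.slices].copy()
    origin = mask.origin + np.asarray(box.lo) * mask.spacing
    return BinaryMask(data=data, spacing=mask.spacing.copy(), origin=origin)


def crop_volume(vol: ImageVolume, box: CropBox) -> ImageVolume:
    """Crop an HU volume with the same index/geometry semantics as :func:`crop`."""
    box.validate_within(vol.shape)
    data = vol.data[box.slices].copy()
    origin = vol.origin + np.asarray(box.lo) * vol.spacing
    return ImageVolume(data=data, spacing=vol.spacing.copy(), origin=origin)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def connected_component(
    mask: BinaryMask,
    connectivity: int = 6,
    seed: tuple[int, int, int] | str = "largest",
) -> BinaryMask:
    """Keep the voxels reachable from a seed under the given adjacency.

    Parameters
    ----------
    connectivity : {6, 18, 26}
        6 = face adjacency (the "region growing" default), 18 adds edge,
        26 adds corner adjacency.
    seed : (i, j, k) voxel index, or "largest"
        With "largest", the component of maximal voxel count is kept; ties
        are broken by the smallest minimum linear (C-order) index.
    """
    if connectivity not in _STRUCTURES:
        raise ParameterError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    if n == 0:
        if isinstance(seed, str):
            return BinaryMask(np.zeros_like(mask.data), mask.spacing.copy(), mask.origin.copy())
        raise ParameterError("seed voxel is not inside the mask (mask is empty)")
    if isinstance(seed, str):
        if seed != "largest":
            raise ParameterError(f"seed must be a voxel index or 'largest', got {seed!r}")
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        best = counts.max()
        candidates = set(np.flatnonzero(counts == best).tolist())
        if len(candidates) == 1:
            label = candidates.pop()
        else:  # tie: first candidate label encountered in flat scan order
            flat = labels.ravel()
            hit = np.flatnonzero(np.isin(flat, list(candidates)))[0]
            label = int(flat[hit])
    else:
        seed = tuple(int(s) for s in seed)
        if not mask.data[seed]:
            raise ParameterError(f"seed voxel {seed} is not inside the mask")
        label = int(labels[seed])
    return BinaryMask(data=labels == label, spacing=mask.spacing.copy(), origin=mask.origin.copy())
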