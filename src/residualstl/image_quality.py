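"""ROI-based HU and SNR assessment, replicated identically across datasets.

Image quality is summarised per disk-shaped region of interest (ROI) as the
mean and sample standard deviation of HU, and SNR = mean / SD.  The same
voxel index set — determined once per ROI from the grid geometry — is
applied to every dose/reconstruction configuration so that SNR differences
reflect the images, never the ROI placement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .io_formats import ImageVolume

log = logging.getLogger(__name__)

#: Default ROI radius in mm (a disk of ~7.5 mm diameter, the conventional
#: muscle-ROI size for head/neck SNR measurements).
DEFAULT_ROI_RADIUS_MM = 3.75


@dataclass(frozen=True)
class DiskROI:
    """A circular in-plane region of interest.

    ``slice_index`` selects the plane along ``axis`` (default axis 0, the
    slice axis); ``center_mm`` is the physical (row, column) centre within
    that plane; ``radius_mm`` the disk radius.
    """

    slice_index: int
    center_mm: tuple[float, float]
    radius_mm: float = DEFAULT_ROI_RADIUS_MM
    axis: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ParameterError(f"ROI radius must be positive, got {self.radius_mm}")
        if self.axis != 0:
            raise ParameterError("only axis-0 (axial) ROIs are supported")


@dataclass(frozen=True)
class ROIStats:
    """Per-ROI HU statistics: voxel count, mean, sample SD (n-1), SNR."""

    n_voxels: int
    mean_hu: float
    sd_hu: float
    snr: float


def roi_voxel_indices(geometry: ImageVolume, roi: DiskROI) -> tuple[np.ndarray, np.ndarray]:
    """In-plane (row, col) indices of voxels whose centres lie within the disk.

    Membership is a centre-point test (no partial-area weighting); the disk
    must lie fully inside the image extent.
    """
    nz, ny, nx = geometry.data.shape
    if not (0 <= roi.slice_index < nz):
        raise ParameterError(f"slice index {roi.slice_index} outside volume of {nz} slices")
    sp_r, sp_c = geometry.spacing[1], geometry.spacing[2]
    o_r, o_c = geometry.origin[1], geometry.origin[2]
    cy, cx = roi.center_mm
    if (cy - roi.radius_mm < o_r - 0.5 * sp_r
            or cy + roi.radius_mm > o_r + (ny - 0.5) * sp_r
            or cx - roi.radius_mm < o_c - 0.5 * sp_c
            or cx + roi.radius_mm > o_c + (nx - 0.5) * sp_c):
        raise ParameterError(f"ROI {roi} extends outside the image extent")
    rows = o_r + np.arange(ny) * sp_r
    cols = o_c + np.arange(nx) * sp_c
    dist2 = (rows[:, None] - cy) ** 2 + (cols[None, :] - cx) ** 2
    rr, cc = np.nonzero(dist2 <= roi.radius_mm ** 2)
    return rr, cc


def roi_stats(vol: ImageVolume, roi: DiskROI,
              indices: tuple[np.ndarray, np.ndarray] | None = None) -> ROIStats:
    """Mean, sample SD and SNR of the HU values inside a disk ROI.

    A constant ROI (SD exactly zero) yields ``snr = +inf`` with a warning;
    fewer than 2 member voxels is an error (the SD is undefined).
    """
    rr, cc = roi_voxel_indices(vol, roi) if indices is None else indices
    values = vol.data[roi.slice_index, rr, cc]
    n = len(values)
    if n < 2:
        raise ParameterError(f"ROI contains {n} voxel(s); at least 2 required for an SD")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        warnings.warn(f"ROI {roi.label or roi} has zero HU variance; SNR reported as +inf",
                      stacklevel=2)
        snr = float("inf") if mean >= 0 else float("-inf")
    else:
        snr = mean / sd
    return ROIStats(n_voxels=n, mean_hu=mean, sd_hu=sd, snr=snr)


def replicate_roi(
    rois: list[DiskROI],
    vols: list[ImageVolume],
    config_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Evaluate every ROI on every volume using identical voxel index sets.

    All volumes must share one grid geometry.  Returns a long-format table
    with one row per (roi, configuration): columns ``roi``, ``config``,
    ``n_voxels``, ``mean_hu``, ``sd_hu``, ``snr``.
    """
    if not vols:
        raise ParameterError("no volumes given")
    ref = vols[0]
    for v in vols[1:]:
        if not ref.same_grid(v):
            raise GeometryError("volumes are on different grids; ROI replication undefined")
    if config_labels is None:
        config_labels = [f"config{i}" for i in range(len(vols))]
    if len(config_labels) != len(vols):
        raise ParameterError("one label per volume required")
    index_sets = [roi_voxel_indices(ref, roi) for roi in rois]
    rows = []
    for roi, idx in zip(rois, index_sets):
        for label, vol in zip(config_labels, vols):
            s = roi_stats(vol, roi, indices=idx)
            rows.append({
                "roi": roi.label or f"roi@{roi.slice_index}:{roi.center_mm}",
                "config": label,
                "n_voxels": s.n_voxels,
                "mean_hu": s.mean_hu,
                "sd_hu": s.sd_hu,
                "snr": s.snr,
            })
    return pd.DataFrame(rows)


def mean_snr_per_config(table: pd.DataFrame) -> pd.Series:
    """Per-configuration SNR averaged over all ROIs (the summary plotted
    against dose)."""
    return table.groupby("config", sort=False)["snr"].mean()
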