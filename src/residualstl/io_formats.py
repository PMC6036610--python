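"""Volumetric image and STL surface I/O.

Conventions
-----------
Arrays are indexed ``(slice, row, column)``.  ``spacing`` and ``origin`` are
given per array axis in millimetres; the physical position of voxel center
``(i, j, k)`` is ``origin + index * spacing`` componentwise.  Meshes live in
the same physical millimetre space.

Only axis-aligned volumes are supported: an oblique (gantry-tilted) DICOM
series is rejected with :class:`~residualstl.errors.GeometryError` rather
than silently mis-measured.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .errors import FormatError, GeometryError, ParameterError

log = logging.getLogger(__name__)

#: Relative tolerance for the inter-slice gap uniformity check on DICOM series.
SLICE_GAP_RTOL = 1e-3

#: Tolerance for the axis-aligned direction-cosine check.
DIRECTION_ATOL = 1e-4


@dataclass
class ImageVolume:
    """A 3D scalar grid in Hounsfield Units with physical geometry.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values, finite.
    spacing : ndarray, shape (3,)
        Voxel size in mm per array axis, all positive.
    origin : ndarray, shape (3,)
        Physical position (mm) of the center of voxel ``(0, 0, 0)``.
    axis_order : str
        Metadata recording the index convention.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    axis_order: str = "slice,row,column"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ParameterError(f"volume data must be rank 3, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("volume contains non-finite HU values")
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,) or not np.all(self.spacing > 0):
            raise ParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ParameterError(f"origin must have 3 components, got {self.origin}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | object") -> bool:
        """True when shapes, spacings and origins coincide exactly."""
        return (
            self.data.shape == other.data.shape  # type: ignore[union-attr]
            and np.array_equal(self.spacing, other.spacing)  # type: ignore[union-attr]
            and np.array_equal(self.origin, other.origin)  # type: ignore[union-attr]
        )


@dataclass
class TriangleMesh:
    """A triangulated surface in physical mm coordinates.

    ``faces`` index into ``vertices`` with consistent outward winding.  A
    closed (watertight) outward-oriented mesh has non-negative signed volume.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ParameterError("face indices out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def open_edge_count(self) -> int:
        """Number of directed edges without an opposite-direction partner.

        Zero for any closed, consistently oriented surface.  Pinch edges
        (an edge shared by 4 faces, 2 each way) still count as closed: the
        enclosed volume remains well defined by the divergence theorem.
        """
        if not len(self.faces):
            return 0
        f = self.faces
        directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        lo = directed.min(axis=1).astype(np.int64)
        hi = directed.max(axis=1).astype(np.int64)
        sign = np.where(directed[:, 0] < directed[:, 1], 1, -1)
        key = lo * len(self.vertices) + hi
        order = np.argsort(key, kind="stable")
        key_s, sign_s = key[order], sign[order]
        boundaries = np.flatnonzero(np.diff(key_s)) + 1
        sums = np.add.reduceat(sign_s, np.concatenate([[0], boundaries]))
        return int(np.sum(np.abs(sums)))

    def is_closed(self) -> bool:
        return self.open_edge_count() == 0

    def as_trimesh(self, process: bool = False) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=process)


# ---------------------------------------------------------------------------
# Volumetric image reading/writing
# ---------------------------------------------------------------------------

_FORMATS = ("dicom-series", "nifti", "nrrd")


def _check_axis_aligned(image: sitk.Image) -> None:
    d = np.asarray(image.GetDirection()).reshape(3, 3)
    if not np.allclose(np.abs(d), np.eye(3), atol=DIRECTION_ATOL):
        raise GeometryError(
            "only axis-aligned volumes are supported; "
            f"got direction cosines {d.tolist()}"
        )


def _volume_from_sitk(image: sitk.Image) -> ImageVolume:
    _check_axis_aligned(image)
    data = sitk.GetArrayFromImage(image)  # (z, y, x)
    spacing = np.asarray(image.GetSpacing())[::-1]
    origin = np.asarray(image.GetOrigin())[::-1]
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing, origin=origin)


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom-series"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise FormatError(f"cannot infer volume format from {path}")


def _read_dicom_series(path: Path) -> ImageVolume:
    import pydicom

    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(path))
    if len(series_ids) == 0:
        raise FormatError(f"no DICOM series found in {path}")
    if len(series_ids) > 1:
        raise FormatError(
            f"directory {path} contains {len(series_ids)} DICOM series; expected one"
        )
    files = reader.GetGDCMSeriesFileNames(str(path), series_ids[0])
    # uniform slice gap check on the sorted positions
    zs = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            zs.append(float(ipp[2]))
    if len(zs) >= 3:
        gaps = np.diff(sorted(zs))
        if gaps.mean() > 0 and (gaps.max() - gaps.min()) > SLICE_GAP_RTOL * abs(gaps.mean()) + 1e-6:
            raise GeometryError(
                f"non-uniform slice gap in {path}: gaps range "
                f"{gaps.min():.4f}..{gaps.max():.4f} mm"
            )
    reader.SetFileNames(files)
    return _volume_from_sitk(reader.Execute())


def read_volume(path: str | Path, format: str | None = None) -> ImageVolume:
    """Read a volumetric image as HU with physical geometry.

    Parameters
    ----------
    path : str or Path
        File (NIfTI/NRRD) or directory containing exactly one DICOM series.
    format : {"dicom-series", "nifti", "nrrd"}, optional
        Inferred from the path when omitted.

    For DICOM the rescale slope/intercept is applied, slices are ordered by
    spatial position, and mixed-series directories or non-uniform slice gaps
    raise an error.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such path: {path}")
    if format is None:
        format = _infer_format(path)
    if format not in _FORMATS:
        raise ParameterError(f"unknown volume format {format!r}; expected one of {_FORMATS}")
    if format == "dicom-series":
        if not path.is_dir():
            raise FormatError(f"dicom-series expects a directory, got {path}")
        return _read_dicom_series(path)
    try:
        image = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # sitk wraps all reader failures in RuntimeError
        raise FormatError(f"cannot read {path}: {exc}") from exc
    return _volume_from_sitk(image)


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an ImageVolume as NIfTI (.nii/.nii.gz) or NRRD, preserving geometry."""
    image = sitk.GetImageFromArray(vol.data)
    image.SetSpacing(tuple(float(s) for s in vol.spacing[::-1]))
    image.SetOrigin(tuple(float(o) for o in vol.origin[::-1]))
    sitk.WriteImage(image, str(path))


# ---------------------------------------------------------------------------
# STL reading/writing
# ---------------------------------------------------------------------------

#: Vertices closer than this (mm) are merged when reading an STL.
STL_MERGE_TOL = 1e-8


def write_stl(mesh: TriangleMesh, path: str | Path, mode: str = "binary") -> None:
    """Write a mesh to STL, binary (default) or ascii.

    Facet normals are recomputed from the vertex winding.  A binary file is
    exactly ``80 + 4 + 50 * n_faces`` bytes.  Degenerate (zero-area) faces
    are written but logged.
    """
    if mode not in ("binary", "ascii"):
        raise ParameterError(f"mode must be 'binary' or 'ascii', got {mode!r}")
    if mesh.n_faces == 0:
        raise ParameterError("refusing to write an empty mesh")
    tm = mesh.as_trimesh(process=False)
    n_degenerate = int(np.sum(tm.area_faces == 0))
    if n_degenerate:
        log.warning("writing %d degenerate (zero-area) faces to %s", n_degenerate, path)
    data = trimesh.exchange.stl.export_stl(tm) if mode == "binary" else \
        trimesh.exchange.stl.export_stl_ascii(tm).encode()
    Path(path).write_bytes(data)


def _validate_stl_bytes(raw: bytes, path: Path) -> str:
    """Return 'ascii' or 'binary'; raise FormatError on malformed input."""
    if len(raw) < 15:
        raise FormatError(f"{path}: too short to be an STL file")
    stripped = raw.lstrip()
    if stripped.startswith(b"solid") and b"facet" in raw[:4096]:
        return "ascii"
    if len(raw) < 84:
        raise FormatError(f"{path}: binary STL shorter than its 84-byte header")
    (n_faces,) = struct.unpack("<I", raw[80:84])
    expected = 84 + 50 * n_faces
    if len(raw) != expected:
        raise FormatError(
            f"{path}: binary STL declares {n_faces} facets "
            f"({expected} bytes) but file has {len(raw)} bytes"
        )
    return "binary"


def read_stl(path: str | Path) -> TriangleMesh:
    """Read a binary or ascii STL (auto-detected), merging duplicate vertices.

    Vertices are merged only on exact coordinate match (within
    ``STL_MERGE_TOL``); face orientation is preserved as stored.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    raw = path.read_bytes()
    _validate_stl_bytes(raw, path)
    import io

    loaded = trimesh.load(io.BytesIO(raw), file_type="stl", process=False)
    verts = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    # exact-match dedup: STL stores one vertex triple per facet corner
    rounded = np.round(verts / STL_MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(rounded, axis=0, return_index=True, return_inverse=True)
    return TriangleMesh(vertices=verts[first], faces=inverse[faces])
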