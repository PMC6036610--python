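"""Voxel mask to watertight triangle mesh, and mesh volume/area.

Surface extraction emits the exact boundary of the voxel set (one quad, two
triangles, per exposed voxel face), so the enclosed mesh volume equals the
voxel-count volume identically and the surface is closed by construction —
including for masks touching the grid boundary.  This is the most
reproducible surface for a *metric* tool: no interpolation, no smoothing,
no resolution-dependent bevel.  An optional Laplacian smoothing pass is
available for visual parity with clinical STL exporters; it is off by
default because it is cosmetic and does not preserve volume.

Units follow radiology reporting: volumes in cm^3, areas in cm^2,
thicknesses (volume/area ratios) in mm.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError, ParameterError
from .io_formats import TriangleMesh
from .segmentation import BinaryMask

MM3_PER_CM3 = 1000.0
MM2_PER_CM2 = 100.0


def _boundary_quads(data: np.ndarray) -> np.ndarray:
    """Corner-index quads (N, 4, 3) for every exposed voxel face, wound outward."""
    quads = []
    for axis in range(3):
        b, c = (axis + 1) % 3, (axis + 2) % 3
        for sign in (+1, -1):
            exposed = data.copy()
            if sign == +1:
                exposed[tuple(slice(None) if a != axis else slice(0, -1) for a in range(3))] &= \
                    ~data[tuple(slice(None) if a != axis else slice(1, None) for a in range(3))]
            else:
                exposed[tuple(slice(None) if a != axis else slice(1, None) for a in range(3))] &= \
                    ~data[tuple(slice(None) if a != axis else slice(0, -1) for a in range(3))]
            vox = np.argwhere(exposed)
            if not len(vox):
                continue
            base = vox.copy()
            if sign == +1:
                base[:, axis] += 1
            eb = np.zeros(3, dtype=np.int64)
            ec = np.zeros(3, dtype=np.int64)
            eb[b], ec[c] = 1, 1
            if sign == +1:  # winding e_b then e_c gives outward normal +e_axis
                quad = np.stack([base, base + eb, base + eb + ec, base + ec], axis=1)
            else:
                quad = np.stack([base, base + ec, base + eb + ec, base + eb], axis=1)
            quads.append(quad)
    if not quads:
        return np.zeros((0, 4, 3), dtype=np.int64)
    return np.concatenate(quads)


def extract_surface(mask: BinaryMask, smooth_iterations: int = 0,
                    smooth_lamb: float = 0.5) -> TriangleMesh:
    """Closed, outward-oriented boundary mesh of a voxel mask, in mm.

    Parameters
    ----------
    mask : BinaryMask
        Non-empty segmentation.
    smooth_iterations : int
        Laplacian smoothing passes applied to the extracted surface
        (cosmetic; volume is no longer voxel-exact when > 0).

    The corner of voxel ``(i, j, k)`` nearest the origin sits at physical
    position ``origin + (index - 1/2) * spacing``: each voxel is a closed
    axis-aligned box centred on its voxel centre.
    """
    if mask.count == 0:
        raise ParameterError("cannot extract a surface from an empty mask")
    quads = _boundary_quads(mask.data)
    shape = mask.data.shape
    stride1 = (shape[1] + 1) * (shape[2] + 1)
    stride2 = shape[2] + 1
    keys = quads[..., 0] * stride1 + quads[..., 1] * stride2 + quads[..., 2]
    unique_keys, inverse = np.unique(keys.ravel(), return_inverse=True)
    corner_idx = np.stack(
        [unique_keys // stride1, (unique_keys % stride1) // stride2, unique_keys % stride2],
        axis=1,
    )
    vertices = mask.origin + (corner_idx - 0.5) * mask.spacing
    quad_faces = inverse.reshape(-1, 4)
    faces = np.concatenate([quad_faces[:, [0, 1, 2]], quad_faces[:, [0, 2, 3]]])
    mesh = TriangleMesh(vertices=vertices, faces=faces)
    if smooth_iterations > 0:
        import trimesh

        tm = mesh.as_trimesh(process=False)
        trimesh.smoothing.filter_laplacian(tm, lamb=smooth_lamb, iterations=smooth_iterations,
                                           volume_constraint=False)
        mesh = TriangleMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))
    return mesh


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume of a closed, outward-oriented mesh, in cm^3.

    Computed as the sum of signed tetrahedra (origin, v0, v1, v2) over all
    faces (divergence theorem).  Raises :class:`GeometryError` naming the
    open-edge count for a non-closed mesh, or when the net signed volume is
    negative (inward orientation).
    """
    open_edges = mesh.open_edge_count()
    if open_edges:
        raise GeometryError(f"mesh is not watertight: {open_edges} open edge(s)")
    v = mesh.vertices
    f = mesh.faces
    v0, v1, v2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    signed_mm3 = float(np.einsum("ij,ij->", v0, np.cross(v1, v2))) / 6.0
    if signed_mm3 < -1e-9 * max(1.0, abs(signed_mm3)):
        raise GeometryError(
            f"mesh has negative signed volume ({signed_mm3:.6g} mm^3): faces are inward-oriented"
        )
    return max(signed_mm3, 0.0) / MM3_PER_CM3


def mesh_area(mesh: TriangleMesh) -> float:
    """Total surface area in cm^2; degenerate faces contribute zero."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return float(np.linalg.norm(cross, axis=1).sum()) / 2.0 / MM2_PER_CM2


def mask_volume(mask: BinaryMask) -> float:
    """Voxel-count volume in cm^3: true voxels times the voxel volume."""
    return mask.count * mask.voxel_volume_mm3 / MM3_PER_CM3
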