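"""Surface extraction from anisotropic binary masks.

Masks from 2-D multi-slice acquisitions have far coarser resolution along the
slice axis than in-plane, so a surface meshed directly from the binary labels
shows a stair-step artifact.  The correction implemented here computes a 2-D
signed Euclidean distance transform per slice and interpolates those distance
maps linearly between slices onto a finer axial grid; meshing the level-0
isosurface of the interpolated field yields a smooth surface that still passes
exactly through the acquired slice contours.

Sign convention: distances are negative inside the structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import NumericalError, ParameterError, ValidationError
from .mesh import SurfaceMesh
from .volume import ImageVolume

__all__ = [
    "SignedDistanceVolume",
    "interslice_distance_interpolation",
    "signed_distance_3d",
    "extract_surface",
    "voxelize_mesh",
]


@dataclass
class SignedDistanceVolume:
    """A signed distance field (mm, negative inside) on a regular grid."""

    volume: ImageVolume
    source_spacing: tuple[float, float, float]

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volume.spacing

    @property
    def origin(self) -> tuple[float, float, float]:
        return self.volume.origin


def _slice_signed_edt(mask2d: np.ndarray, spacing_xy, clamp: float) -> np.ndarray:
    """2-D signed EDT of one slice in mm; empty/full slices clamp."""
    if not mask2d.any():
        return np.full(mask2d.shape, clamp)
    if mask2d.all():
        return np.full(mask2d.shape, -clamp)
    d_in = ndimage.distance_transform_edt(mask2d, sampling=spacing_xy)
    d_out = ndimage.distance_transform_edt(~mask2d, sampling=spacing_xy)
    return np.clip(d_out - d_in, -clamp, clamp)


def signed_distance_3d(mask: ImageVolume) -> SignedDistanceVolume:
    """Full 3-D signed EDT (mm, negative inside) on the mask's own grid."""
    mask.require_binary_mask()
    m = mask.data.astype(bool)
    if not m.any():
        raise ValidationError("mask is empty")
    d_in = ndimage.distance_transform_edt(m, sampling=mask.spacing)
    d_out = ndimage.distance_transform_edt(~m, sampling=mask.spacing)
    sdf = d_out - d_in
    return SignedDistanceVolume(
        ImageVolume(sdf, mask.spacing, mask.origin), mask.spacing
    )


def interslice_distance_interpolation(
    mask: ImageVolume, target_axial_spacing: float
) -> SignedDistanceVolume:
    """Per-slice signed 2-D EDTs, linearly interpolated along the slice axis.

    The target axial spacing is rounded to an integer divisor of the original
    slice spacing so that every acquired slice plane is a node of the output
    grid; on those planes the output equals the per-slice 2-D EDT exactly.
    """
    mask.require_binary_mask()
    m = mask.data.astype(bool)
    if not m.any():
        raise ValidationError("mask is empty")
    occupied = np.flatnonzero(m.any(axis=(0, 1)))
    if len(occupied) < 2:
        raise ValidationError(
            "mask occupies a single slice; inter-slice interpolation undefined"
        )
    dz = mask.spacing[2]
    if target_axial_spacing <= 0 or target_axial_spacing > dz + 1e-12:
        raise ParameterError(
            f"target axial spacing must be in (0, {dz}], got {target_axial_spacing}"
        )
    refine = int(np.ceil(dz / target_axial_spacing - 1e-9))
    tz = dz / refine

    clamp = float(np.linalg.norm(mask.grid.extent))  # grid diagonal
    nx, ny, nz = m.shape
    slices = np.empty((nx, ny, nz))
    for k in range(nz):
        slices[:, :, k] = _slice_signed_edt(m[:, :, k], mask.spacing[:2], clamp)

    # linear interpolation between adjacent slices onto the refined grid
    nz_out = (nz - 1) * refine + 1
    out = np.empty((nx, ny, nz_out))
    out[:, :, ::refine] = slices
    if refine > 1:
        for r in range(1, refine):
            w = r / refine
            out[:, :, r::refine] = (1 - w) * slices[:, :, :-1] + w * slices[:, :, 1:]
    vol = ImageVolume(out, (mask.spacing[0], mask.spacing[1], tz), mask.origin)
    return SignedDistanceVolume(vol, mask.spacing)


def _weld(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge coincident vertices and drop degenerate faces."""
    rounded = np.round(verts, 9)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    faces = inverse[faces]
    ok = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    return uniq, faces[ok]


def _marching_cubes(sdf: SignedDistanceVolume, step_size: int) -> SurfaceMesh:
    verts, faces, _, _ = measure.marching_cubes(
        sdf.data,
        level=0.0,
        spacing=sdf.spacing,
        gradient_direction="ascent",  # inside is negative
        step_size=step_size,
        allow_degenerate=False,
    )
    verts = verts + np.asarray(sdf.origin)
    verts, faces = _weld(verts, faces)
    mesh = SurfaceMesh(verts, faces).orient_outward()
    return mesh


def extract_surface(
    sdf: SignedDistanceVolume,
    decimate_to: int | None = None,
    smooth_sigma_vox: float = 0.0,
) -> SurfaceMesh:
    """Closed, outward-oriented level-0 isosurface of a signed distance field.

    ``decimate_to`` requests an approximate upper bound on the vertex count;
    coarsening is done by increasing the marching-cubes grid step, which keeps
    the output closed and oriented by construction.  ``smooth_sigma_vox``
    optionally smooths the field with a small Gaussian before meshing:
    voxel-quantization roughness of the level set (≈ half a voxel,
    uncorrelated between voxels) is averaged away while geometry at
    millimetre scale passes essentially unchanged.
    """
    if smooth_sigma_vox > 0:
        sdf = SignedDistanceVolume(
            ImageVolume(
                ndimage.gaussian_filter(sdf.data, smooth_sigma_vox, mode="nearest"),
                sdf.spacing,
                sdf.origin,
            ),
            sdf.source_spacing,
        )
    data = sdf.data
    if data.min() >= 0 or data.max() <= 0:
        raise NumericalError("no surface: the field has no zero crossing")
    mesh = _marching_cubes(sdf, 1)
    if decimate_to is not None and mesh.n_vertices > decimate_to:
        step = 2
        max_step = max(2, min(data.shape) // 4)
        while step <= max_step:
            try:
                coarse = _marching_cubes(sdf, step)
            except (ValueError, RuntimeError):
                break
            if not coarse.is_closed() or coarse.n_faces == 0:
                break
            mesh = coarse
            if mesh.n_vertices <= decimate_to:
                break
            step += 1
    mesh.require_closed_oriented("extracted surface")
    return mesh


def voxelize_mesh(mesh: SurfaceMesh, grid) -> ImageVolume:
    """Rasterize a closed mesh to a binary mask by parity counting.

    Rays are cast along +z through every in-plane voxel-centre column; voxel
    centres between an odd and the following even crossing are inside.
    """
    from .raycast import cast_all_hits, mesh_ray_arrays

    mesh.require_closed_oriented()
    xs, ys, zs = grid.world_axes()
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    n_cols = gx.size
    z0 = zs[0] - 1.0
    origins = np.column_stack(
        [gx.ravel(), gy.ravel(), np.full(n_cols, z0)]
    ).astype(np.float64)
    dirs = np.tile(np.array([0.0, 0.0, 1.0]), (n_cols, 1))
    v0, e1, e2, _ = mesh_ray_arrays(mesh)
    merge_tol = 1e-7 * max(mesh.bounding_box_diagonal(), 1.0)
    hits, n_hits = cast_all_hits(origins, dirs, v0, e1, e2, merge_tol)
    mask = np.zeros(grid.shape, dtype=np.uint8)
    zcoord = zs - z0
    for c in range(n_cols):
        k = n_hits[c]
        if k < 2:
            continue
        ix, iy = divmod(c, len(ys))
        inside = np.zeros(len(zs), dtype=bool)
        for h in range(0, k - 1, 2):
            inside |= (zcoord >= hits[c, h]) & (zcoord < hits[c, h + 1])
        mask[ix, iy, :] = inside
    return ImageVolume(mask, grid.spacing, grid.origin)
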