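"""Synthetic cohorts with known, localized surface deformations.

No imaging data accompany the study design this pipeline addresses, so every
stage is validated against cohorts generated here: a curved tube-like template
(standing in for a hippocampus segmented on anisotropic coronal slices), per
group a set of planted inward/outward surface deformations of known amplitude,
location and spatial support, and a smooth per-subject perturbation field.
The planted displacement is exactly evaluable at any surface point, giving
every downstream stage a recoverable ground truth.

Deformations are applied on the signed distance transform: moving the level-0
set outward by ``a * K(d / rho)`` (with ``K`` a C^2 Wendland bump, ``K(0)=1``,
``K(1)=0``, zero outside the support radius ``rho``) equals subtracting that
amount from the signed distance field, since ``|grad(sdf)| = 1`` near the
surface.  ``|a| < rho`` keeps the deformation fold-free at the amplitudes used
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError, ValidationError
from .mesh import SurfaceMesh
from .surfaces import (
    extract_surface,
    interslice_distance_interpolation,
    signed_distance_3d,
)
from .volume import GridSpec, ImageVolume, desk_grid

__all__ = [
    "EffectSpec",
    "SyntheticCohort",
    "Subject",
    "wendland",
    "make_template_mask",
    "apply_local_deformation",
    "make_cohort",
    "make_vertex_cohort",
]


def wendland(s: np.ndarray) -> np.ndarray:
    """C^2 compactly supported bump: (1-s)^4 (4s+1) on [0,1], else 0."""
    s = np.asarray(s, dtype=float)
    out = np.where(s < 1.0, (1.0 - np.clip(s, 0, 1)) ** 4 * (4.0 * s + 1.0), 0.0)
    return out


@dataclass(frozen=True)
class EffectSpec:
    """A planted local deformation: outward if ``amplitude > 0``, inward if < 0."""

    center: tuple[float, float, float]  # world mm, on/near the template surface
    radius: float  # support radius rho (mm)
    amplitude: float  # peak normal displacement (mm), signed
    group: str = ""  # group label the effect applies to

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"effect radius must be > 0, got {self.radius}")
        if abs(self.amplitude) >= self.radius:
            raise ParameterError(
                f"|amplitude| ({abs(self.amplitude)}) must be < radius ({self.radius})"
            )

    def displacement(self, points: np.ndarray) -> np.ndarray:
        """Planted normal displacement (signed mm) at world points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(points - np.asarray(self.center), axis=1)
        return self.amplitude * wendland(d / self.radius)


def generation_sdf(mask: ImageVolume) -> ImageVolume:
    """Signed distance debiased to the true (sub-voxel) boundary position.

    The voxel-centre EDT measures to the nearest voxel centre of the opposite
    class, overstating the distance to the actual boundary (which lies midway
    between centres) by half the local crossing spacing.  Left uncorrected,
    re-thresholding ``sdf - delta`` cannot express surface displacements
    smaller than a full voxel spacing — planted effects and subject noise
    below that scale would silently vanish.  The correction subtracts half
    the voxel extent projected on the local gradient direction.
    """
    sdf = signed_distance_3d(mask).volume
    data = sdf.data
    gx, gy, gz = np.gradient(data, *mask.spacing)
    gn = np.sqrt(gx * gx + gy * gy + gz * gz)
    gn = np.where(gn == 0, 1.0, gn)
    sx, sy, sz = mask.spacing
    # voxel cell extent along the gradient direction
    h = (np.abs(gx) * sx + np.abs(gy) * sy + np.abs(gz) * sz) / gn
    corrected = data - 0.5 * h * np.sign(data)
    # keep the sign: the correction may not move a voxel across the boundary
    corrected = np.where(np.sign(corrected) == np.sign(data), corrected,
                         0.05 * np.sign(data) * min(mask.spacing))
    return ImageVolume(corrected, mask.spacing, mask.origin)


def _effect_field(effects, grid: GridSpec) -> np.ndarray:
    """Sum of amplitude * K over the grid (mm offset of the level set)."""
    xs, ys, zs = grid.world_axes()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    out = np.zeros(grid.shape)
    for e in effects:
        d = np.sqrt(
            (gx - e.center[0]) ** 2 + (gy - e.center[1]) ** 2 + (gz - e.center[2]) ** 2
        )
        out += e.amplitude * wendland(d / e.radius)
    return out


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------

def _centerline(grid: GridSpec, curvature: float, length: float) -> np.ndarray:
    """Sampled centerline of the tube, centred in the grid (x-y plane arc)."""
    center = grid.center
    if length == 0:
        return center[None, :]
    step = min(grid.spacing) / 4.0
    n = max(2, int(np.ceil(length / step)) + 1)
    s = np.linspace(-length / 2.0, length / 2.0, n)
    if curvature == 0:
        pts = np.zeros((n, 3))
        pts[:, 0] = s
    else:
        rc = 1.0 / curvature
        phi = s / rc
        half = np.max(np.abs(phi))
        shift = rc * (1.0 + np.cos(half)) / 2.0
        pts = np.column_stack([rc * np.sin(phi), rc * np.cos(phi) - shift, np.zeros(n)])
    return center + pts


def make_template_mask(
    grid: GridSpec | None = None,
    curvature: float = 0.08,
    length: float = 14.0,
    radius: float = 2.0,
) -> ImageVolume:
    """Binary mask of a curved tube (capsule around a circular arc).

    ``curvature`` (1/mm) bends the centerline in the in-plane (x-y) plane;
    ``length`` is the arc length (mm); ``radius`` the tube radius (mm).
    ``curvature=0, length=0`` degenerates to a ball of the given radius.
    """
    if grid is None:
        grid = desk_grid()
    if radius <= 0:
        raise ParameterError(f"tube radius must be > 0, got {radius}")
    line = _centerline(grid, curvature, length)
    lo = line.min(axis=0) - radius
    hi = line.max(axis=0) + radius
    margin = 2.0 * np.asarray(grid.spacing)
    g_lo = np.asarray(grid.origin) + margin
    g_hi = np.asarray(grid.origin) + grid.extent - margin
    for a, name in enumerate("xyz"):
        if lo[a] < g_lo[a] or hi[a] > g_hi[a]:
            raise ParameterError(
                f"tube exceeds grid along {name}: needs [{lo[a]:.2f}, {hi[a]:.2f}] mm, "
                f"grid allows [{g_lo[a]:.2f}, {g_hi[a]:.2f}] mm (2-voxel margin)"
            )
    xs, ys, zs = grid.world_axes()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    vox = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d, _ = cKDTree(line).query(vox, workers=1)
    mask = (d <= radius).reshape(grid.shape).astype(np.uint8)
    vol = ImageVolume(mask, grid.spacing, grid.origin)
    validate_mask(vol)
    return vol


# ---------------------------------------------------------------------------
# mask validation
# ---------------------------------------------------------------------------

_CONN6 = ndimage.generate_binary_structure(3, 1)


def validate_mask(mask: ImageVolume, name: str = "mask") -> None:
    """Binary, single 6-connected component, no foreground on the border."""
    mask.require_binary_mask(name)
    m = mask.data.astype(bool)
    if not m.any():
        raise ValidationError(f"{name} is empty")
    _, n = ndimage.label(m, structure=_CONN6)
    if n != 1:
        raise ValidationError(f"{name} has {n} connected components, expected 1")
    border = (
        m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any()
        or m[:, :, 0].any() or m[:, :, -1].any()
    )
    if border:
        raise ValidationError(f"{name} touches the grid border")


def _largest_component(m: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(m, structure=_CONN6)
    if n <= 1:
        return m
    sizes = ndimage.sum_labels(m, lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    discarded = m.sum() - sizes[keep - 1]
    if discarded > 0.005 * m.sum():
        raise ValidationError(
            f"deformed mask split into {n} components; {discarded:.0f} voxels stranded"
        )
    return lab == keep


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------

class TruthField:
    """Exact planted displacement, evaluable at any surface point.

    ``normal_displacement`` gives the signed offset along the local outward
    normal (positive = outward); ``vectors`` multiplies it by the normal of
    the *undeformed* surface, interpolated from the signed distance gradient.
    """

    def __init__(self, effects, sdf: ImageVolume):
        self.effects = tuple(effects)
        self._sdf = sdf
        grads = np.gradient(sdf.data, *sdf.spacing)
        self._grads = grads

    def normal_displacement(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.zeros(len(points))
        for e in self.effects:
            out += e.displacement(points)
        return out

    def normals(self, points: np.ndarray) -> np.ndarray:
        idx = self._sdf.world_to_index(points).T
        g = np.column_stack(
            [ndimage.map_coordinates(gc, idx, order=1, mode="nearest")
             for gc in self._grads]
        )
        ln = np.linalg.norm(g, axis=1, keepdims=True)
        return g / np.where(ln == 0, 1.0, ln)

    def vectors(self, points: np.ndarray) -> np.ndarray:
        return self.normal_displacement(points)[:, None] * self.normals(points)


def deformed_level_set(mask: ImageVolume, effects) -> "SignedDistanceVolume":
    """Signed distance field of the mask with effects applied, un-thresholded.

    Meshing this field at level 0 yields the *exact* deformed surface, free of
    the sub-voxel quantization that re-thresholding to a binary mask incurs;
    use it for surface-pair experiments where the planted displacement must be
    preserved below voxel resolution.
    """
    from .surfaces import SignedDistanceVolume

    mask.require_binary_mask()
    sdf = generation_sdf(mask)
    offset = _effect_field(effects, mask.grid)
    return SignedDistanceVolume(
        ImageVolume(sdf.data - offset, mask.spacing, mask.origin), mask.spacing
    )


def apply_local_deformation(
    mask: ImageVolume, effect: EffectSpec
) -> tuple[ImageVolume, TruthField]:
    """Deform the implicit surface along its normal by ``amplitude * K(d/rho)``.

    Returns the re-thresholded mask and the exact displacement applied.
    """
    mask.require_binary_mask()
    sdf = generation_sdf(mask)
    center_sdf = ndimage.map_coordinates(
        sdf.data, mask.world_to_index(effect.center).T, order=1
    )[0]
    if abs(float(center_sdf)) > 2 * effect.radius:
        raise ValidationError(
            "effect center is farther than 2*radius from the mask boundary"
        )
    offset = _effect_field([effect], mask.grid)
    new = ((sdf.data - offset) < 0).astype(np.uint8)
    new = _largest_component(new.astype(bool)).astype(np.uint8)
    out = ImageVolume(new, mask.spacing, mask.origin)
    return out, TruthField([effect], sdf)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Subject:
    subject_id: str
    group: str
    mask: ImageVolume
    truth_scalar: np.ndarray  # planted normal displacement at template vertices
    truth_vectors: np.ndarray  # same, as 3-vectors


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    template_mask: ImageVolume
    template_mesh: SurfaceMesh
    effects: tuple[EffectSpec, ...]
    groups: tuple[str, ...]
    seed: int
    meta: dict = field(default_factory=dict)

    def by_group(self, group: str) -> list[Subject]:
        return [s for s in self.subjects if s.group == group]

    @property
    def group_labels(self) -> list[str]:
        return [s.group for s in self.subjects]

    def group_truth(self, group: str) -> np.ndarray:
        """Planted normal displacement of one group at template vertices."""
        for s in self.subjects:
            if s.group == group:
                return s.truth_scalar
        raise KeyError(group)

    def write(self, out_dir) -> None:
        """Masks as NIfTI, manifest and per-vertex truth as TSV."""
        import pandas as pd
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        self.template_mask.save(out / "template_mask.nii")
        for s in self.subjects:
            p = out / f"{s.subject_id}.nii"
            s.mask.save(p)
            rows.append({"subject_id": s.subject_id, "group": s.group,
                         "path": p.name, "seed": self.seed})
        pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
        truth = pd.DataFrame(
            {s.subject_id: s.truth_scalar for s in self.subjects}
        )
        truth.insert(0, "vertex_id", np.arange(len(self.template_mesh.vertices)))
        truth.to_csv(out / "truth_normal_displacement.tsv", sep="\t", index=False)


def _smooth_noise_field(shape, rng, sigma_vox=3.0) -> np.ndarray:
    """Smooth Gaussian random field (unnormalized, >= 3-voxel correlation)."""
    w = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(w, sigma=sigma_vox, mode="nearest")
    return f


def _check_effects(effects, groups) -> None:
    eff = [e for e in effects if e.group and e.group not in groups]
    if eff:
        raise ValidationError(f"effects reference unknown groups: {[e.group for e in eff]}")
    by_group: dict[str, list[EffectSpec]] = {}
    for e in effects:
        by_group.setdefault(e.group, []).append(e)
    for g, es in by_group.items():
        for i in range(len(es)):
            for j in range(i + 1, len(es)):
                d = np.linalg.norm(np.asarray(es[i].center) - np.asarray(es[j].center))
                if d < 1e-9 and es[i].amplitude * es[j].amplitude < 0:
                    raise ValidationError(
                        f"group {g!r}: overlapping effects of opposite sign at the "
                        f"same center {es[i].center}"
                    )


def make_cohort(
    grid: GridSpec | None = None,
    n_per_group: int = 8,
    effects: tuple[EffectSpec, ...] = (),
    subject_noise: float = 0.1,
    seed: int = 0,
    groups: tuple[str, ...] = ("VEH", "HAL", "OLZ"),
    template_kwargs: dict | None = None,
    mesh_vertices: int = 900,
) -> SyntheticCohort:
    """Generate a cohort of binary masks with planted group deformations.

    Each subject is the template deformed by its group's effects plus a smooth
    random perturbation of RMS amplitude ``subject_noise`` (mm) along the
    surface normal.  Identical seeds give identical cohorts.
    """
    if grid is None:
        grid = desk_grid()
    if n_per_group < 2:
        raise ParameterError(f"n_per_group must be >= 2, got {n_per_group}")
    if subject_noise < 0:
        raise ParameterError(f"subject_noise must be >= 0, got {subject_noise}")
    if not groups:
        raise ValidationError("groups must be non-empty")
    _check_effects(effects, groups)

    template = make_template_mask(grid, **(template_kwargs or {}))
    sdf = generation_sdf(template)
    band = np.abs(sdf.data) < 2.0 * max(grid.spacing)

    interp = interslice_distance_interpolation(template, min(grid.spacing[:2]))
    template_mesh = extract_surface(interp, decimate_to=mesh_vertices)
    verts = template_mesh.vertices

    group_offsets = {}
    group_truths = {}
    for g in groups:
        es = [e for e in effects if e.group == g]
        group_offsets[g] = _effect_field(es, grid) if es else 0.0
        tf = TruthField(es, sdf)
        group_truths[g] = (tf.normal_displacement(verts), tf.vectors(verts))

    rng = np.random.default_rng(seed)
    subjects: list[Subject] = []
    for g in groups:
        for i in range(n_per_group):
            data = sdf.data - group_offsets[g]
            if subject_noise > 0:
                f = _smooth_noise_field(grid.shape, rng)
                rms = np.sqrt(np.mean(f[band] ** 2))
                data = data - subject_noise * f / rms
            m = _largest_component(data < 0).astype(np.uint8)
            vol = ImageVolume(m, grid.spacing, grid.origin)
            validate_mask(vol, f"subject {g}{i:02d}")
            scalar, vecs = group_truths[g]
            subjects.append(Subject(f"{g}{i:02d}", g, vol, scalar.copy(), vecs.copy()))
    return SyntheticCohort(
        subjects, template, template_mesh, tuple(effects), tuple(groups), seed
    )


def radial_expansion_field(
    grid: GridSpec, center, radius: float, strength: float
):
    """Analytic smooth radial expansion: u(x) = s * K(|x-c|/rho) * (x-c).

    A known ground-truth diffeomorphism for volumetric (TBM) experiments: the
    Jacobian exceeds 1 inside the support (peak ``(1+s)^3``-ish at the
    centre) and equals 1 outside.  ``strength`` must be small enough to keep
    the map fold-free (|s| well below ~0.2 for the Wendland kernel).
    """
    from .tbm import DeformationField

    xs, ys, zs = grid.world_axes()
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    cx, cy, cz = center
    dx, dy, dz = gx - cx, gy - cy, gz - cz
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    k = strength * wendland(r / radius)
    u = np.stack([k * dx, k * dy, k * dz], axis=-1)
    return DeformationField(u, grid.spacing, grid.origin)


def make_vertex_cohort(
    mesh: SurfaceMesh,
    effects: tuple[EffectSpec, ...] = (),
    n_per_group: int = 8,
    subject_noise: float = 0.1,
    seed: int = 0,
    groups: tuple[str, ...] = ("A", "B"),
    noise_smoothing_sweeps: int = 10,
    isotropic_jitter: float = 0.02,
    volume_neutral_noise: bool = False,
) -> tuple[list[SurfaceMesh], list[str], dict[str, np.ndarray]]:
    """Corresponded subject meshes built directly at the vertex level.

    Displaces the template vertices along their normals by the group effect
    plus smooth per-subject noise, bypassing voxelization and registration.
    A small isotropic 3-D jitter (``isotropic_jitter`` mm sd per axis,
    emulating mesh discretization scatter) keeps the per-vertex displacement
    covariance full-rank; purely normal displacements would be rank-1 and
    make Hotelling's T^2 degenerate.  With ``volume_neutral_noise`` the
    area-weighted mean of each subject's noise field is removed, so the noise
    perturbs shape but leaves the enclosed volume unchanged to first order
    (used to isolate pure shape variation).  Used to study the statistical
    stage in isolation.  Returns (meshes, group labels, per-group planted
    normal displacement at the vertices).
    """
    _check_effects(effects, groups)
    normals = mesh.vertex_normals()
    verts = mesh.vertices
    adj = mesh.vertex_adjacency()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    rng = np.random.default_rng(seed)
    # area weights for the volume-neutral projection
    tri = mesh.triangles
    fa = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    va = np.zeros(len(verts))
    for col in range(3):
        np.add.at(va, mesh.faces[:, col], fa / 3.0)

    truth = {}
    for g in groups:
        t = np.zeros(len(verts))
        for e in effects:
            if e.group == g:
                t += e.displacement(verts)
        truth[g] = t

    meshes, labels = [], []
    for g in groups:
        for _ in range(n_per_group):
            disp = truth[g].copy()
            if subject_noise > 0:
                f = rng.standard_normal(len(verts))
                for _ in range(noise_smoothing_sweeps):
                    f = (f + adj @ f) / (1.0 + deg)
                if volume_neutral_noise:
                    f = f - np.sum(va * f) / va.sum()
                f *= subject_noise / np.sqrt(np.mean(f**2))
                disp = disp + f
            new_verts = verts + disp[:, None] * normals
            if isotropic_jitter > 0:
                new_verts = new_verts + isotropic_jitter * rng.standard_normal(
                    verts.shape
                )
            meshes.append(mesh.with_vertices(new_verts))
            labels.append(g)
    return meshes, labels, truth
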