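"""Elastic surface registration with normal-ray correspondences.

A reference surface is brought into dense correspondence with a target surface
by alternating three steps:

1. *Correspondence search* — from every reference vertex a ray is cast along
   its outward normal (both senses; the nearest accepted hit wins).  A hit is
   accepted only if the dot product between the source vertex normal and the
   target surface normal at the hit exceeds 0.5 (a 60 degree tolerance) and
   the ray meets the target exactly once within the maximum ray length.
   Vertices without an accepted hit get weight zero.
2. *Rigid alignment* — weighted least-squares proper rigid transform of the
   reference onto its corresponding points (Kabsch/Umeyama via SVD, reflection
   corrected).
3. *Elastic step* — each vertex translates toward its corresponding point;
   motion is restricted by a stiffness parameter ``beta`` that couples each
   vertex to its mesh neighbours (the weighted update field is diffused over
   the mesh graph; zero-weight vertices simply translate along with their
   neighbours).

The loop runs for a fixed number of iterations (default 60) while the
stiffness decreases geometrically, so the surface behaves rigidly at first and
becomes progressively more elastic.  When every surface is registered by the
same reference, each vertex index denotes the same anatomical location on
every surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RegistrationError, ValidationError
from .mesh import SurfaceMesh
from .raycast import cast_senses, mesh_ray_arrays
from .surfaces import extract_surface, interslice_distance_interpolation

__all__ = [
    "CorrespondenceSet",
    "RigidTransform",
    "RegistrationConfig",
    "GeometricErrorMap",
    "find_correspondences",
    "rigid_align",
    "elastic_step",
    "register",
    "build_average_surface",
]


@dataclass
class CorrespondenceSet:
    """Per-source-vertex target point, validity flag and weight."""

    points: np.ndarray  # (N, 3) world mm; rows of invalid entries are NaN
    valid: np.ndarray  # (N,) bool
    weights: np.ndarray  # (N,) in [0, 1]; exactly 0 where invalid

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self o other (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.12g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        m = np.loadtxt(path)
        return cls(m[:3, :3], m[:3, 3])


@dataclass
class RegistrationConfig:
    n_iterations: int = 60
    beta_start: float = 10.0
    beta_end: float = 0.1
    angle_tolerance_deg: float = 60.0
    max_ray_fraction: float = 0.25  # of target bounding-box diagonal
    convergence_tol: float = 1e-4  # mm mean vertex motion
    min_valid_fraction: float = 0.1
    rigid_init_iterations: int = 30  # cap on the rigid-only phase (early-stops)

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.beta_start <= 0 or self.beta_end <= 0:
            raise ParameterError("stiffness must be strictly positive")
        if self.beta_end > self.beta_start:
            raise ParameterError("stiffness schedule must be non-increasing")
        if not (0 < self.angle_tolerance_deg < 90):
            raise ParameterError("angle tolerance must be in (0, 90) degrees")

    @property
    def cos_tolerance(self) -> float:
        return float(np.cos(np.deg2rad(self.angle_tolerance_deg)))

    def beta(self, iteration: int) -> float:
        """Geometric decay from beta_start to beta_end over the schedule."""
        if self.n_iterations == 1:
            return self.beta_start
        f = iteration / (self.n_iterations - 1)
        return float(self.beta_start * (self.beta_end / self.beta_start) ** f)


@dataclass
class GeometricErrorMap:
    """Per-vertex Euclidean distance (mm) from registered surface to target.

    ``history`` records the mean valid-correspondence distance at each
    iteration of the registration loop.
    """

    values: np.ndarray
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def max(self) -> float:
        return float(self.values.max())


# ---------------------------------------------------------------------------
# correspondence search
# ---------------------------------------------------------------------------

def accept_correspondence(
    normal_dot: float, n_intersections_before: int, distance: float,
    cos_tolerance: float = 0.5, max_ray_length: float = np.inf,
) -> bool:
    """The correspondence acceptance rule, factored out for direct testing.

    The candidate corresponding point is the nearest distinct intersection of
    the normal ray with the target.  It is accepted iff the dot product
    between the source vertex normal and the target normal at the hit
    strictly exceeds ``cos_tolerance`` (0.5 for the default 60 degree
    tolerance), the hit lies within ``max_ray_length``, and the ray does not
    intersect the surface any other time before reaching it
    (``n_intersections_before == 0``; an earlier sheet of the target blocks
    the match).
    """
    return (
        n_intersections_before == 0
        and distance <= max_ray_length
        and normal_dot > cos_tolerance
    )


class _TargetCache:
    """Precomputed ray-casting arrays for a static target mesh."""

    def __init__(self, target: SurfaceMesh):
        self.v0, self.e1, self.e2, self.fn = mesh_ray_arrays(target)
        self.diag = target.bounding_box_diagonal()


def find_correspondences(
    source: SurfaceMesh, target: SurfaceMesh, config: RegistrationConfig | None = None,
    _cache: _TargetCache | None = None, _validate: bool = True,
) -> CorrespondenceSet:
    """Normal-ray correspondences from every source vertex onto the target."""
    config = config or RegistrationConfig()
    if _validate:
        source.require_closed_oriented("source")
        target.require_closed_oriented("target")
    cache = _cache or _TargetCache(target)
    origins = np.ascontiguousarray(source.vertices)
    normals = np.ascontiguousarray(source.vertex_normals())
    v0, e1, e2, fn = cache.v0, cache.e1, cache.e2, cache.fn
    diag = cache.diag
    max_len = config.max_ray_fraction * diag
    merge_tol = 1e-7 * max(diag, 1.0)
    counts, t_near, tri_near, dot_near = cast_senses(
        origins, normals, v0, e1, e2, fn, normals, max_len, merge_tol
    )
    cos_tol = config.cos_tolerance
    # the nearest distinct hit is the candidate; it must pass the normal test
    ok = (counts >= 1) & (dot_near > cos_tol)  # (N, 2) per sense
    # choose between senses: nearest accepted hit; tie -> larger dot product
    t_sel = np.where(ok, t_near, np.inf)
    with np.errstate(invalid="ignore"):
        tie = ok.all(axis=1) & (np.abs(t_near[:, 0] - t_near[:, 1]) <= merge_tol)
    sense = np.argmin(t_sel, axis=1)
    sense[tie] = np.argmax(dot_near[tie], axis=1)
    rows = np.arange(len(origins))
    valid = ok[rows, sense]
    t = t_near[rows, sense]
    sign = np.where(sense == 0, 1.0, -1.0)
    points = np.full_like(origins, np.nan)
    points[valid] = (
        origins[valid] + (sign[valid] * t[valid])[:, None] * normals[valid]
    )
    weights = valid.astype(float)
    return CorrespondenceSet(points, valid, weights)


# ---------------------------------------------------------------------------
# rigid alignment (weighted Kabsch/Umeyama)
# ---------------------------------------------------------------------------

def rigid_align(corr: CorrespondenceSet, source: SurfaceMesh) -> RigidTransform:
    """Weighted least-squares proper rigid transform source -> targets.

    Minimizes sum_i w_i ||R s_i + t - p_i||^2 via SVD of the weighted
    cross-covariance; a reflection is corrected by flipping the smallest
    singular direction, so det(R) = +1 always.
    """
    w = corr.weights[corr.valid]
    s = source.vertices[corr.valid]
    p = corr.points[corr.valid]
    if len(s) < 3:
        raise RegistrationError(
            f"rigid alignment needs >= 3 valid correspondences, got {len(s)}"
        )
    wsum = w.sum()
    cs = (w[:, None] * s).sum(0) / wsum
    cp = (w[:, None] * p).sum(0) / wsum
    sc, pc = s - cs, p - cp
    h = (w[:, None] * sc).T @ pc
    u, sv, vt = np.linalg.svd(h)
    scale = np.linalg.norm(sc, axis=1).max()
    if sv[1] <= 1e-12 * max(sv[0], 1e-300) or scale == 0:
        raise RegistrationError("degenerate (collinear) correspondences")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = cp - r @ cs
    return RigidTransform(r, t)


# ---------------------------------------------------------------------------
# elastic step
# ---------------------------------------------------------------------------

def elastic_step(
    source: SurfaceMesh, corr: CorrespondenceSet, beta: float, adjacency=None,
    damping: float = 0.05,
) -> SurfaceMesh:
    """Translate vertices toward their corresponding points, stiffness-coupled.

    The applied displacement field ``d`` minimizes

        sum_i w_i ||d_i - (p_i - v_i)||^2  +  beta sum_{(i,j) in edges} ||d_i - d_j||^2

    i.e. it solves ``(W + beta L + damping (I - W)) d = W (p - v)`` with ``L``
    the combinatorial graph Laplacian of the mesh.  High ``beta`` couples
    neighbours strongly (stiff, smooth motion), low ``beta`` lets vertices
    follow their own correspondence.  A spatially constant target field moves
    every vertex exactly by that constant for any ``beta``; zero-weight
    vertices carry no data term and simply translate along with their
    neighbours (the small damping term localizes that diffusion).
    """
    if beta <= 0:
        raise ParameterError(f"stiffness beta must be > 0, got {beta}")
    if len(corr.weights) != source.n_vertices:
        raise ValidationError("correspondence set does not match source vertex count")
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    if adjacency is None:
        adjacency = source.vertex_adjacency()
    deg = np.asarray(adjacency.sum(axis=1)).ravel()
    lap = sparse.diags(deg) - adjacency
    w = np.where(corr.valid, corr.weights, 0.0)
    raw = np.where(corr.valid[:, None], corr.points - source.vertices, 0.0)
    lhs = (sparse.diags(w + damping * (1.0 - w)) + beta * lap).tocsc()
    d = spsolve(lhs, w[:, None] * raw)
    return source.with_vertices(source.vertices + d)


# ---------------------------------------------------------------------------
# full registration loop
# ---------------------------------------------------------------------------

def _closest_point_distance(points: np.ndarray, target: SurfaceMesh) -> np.ndarray:
    """Euclidean distance from each point to the target surface."""
    import trimesh.proximity as prox

    _, dist, _ = prox.closest_point_naive(target.to_trimesh(), points)
    return np.asarray(dist)


def register(
    source: SurfaceMesh, target: SurfaceMesh, config: RegistrationConfig | None = None
) -> tuple[SurfaceMesh, GeometricErrorMap, RigidTransform]:
    """Deform ``source`` into dense correspondence with ``target``.

    Alternates correspondence search, rigid SVD alignment and the elastic step
    for ``config.n_iterations`` iterations while the stiffness decreases.
    Returns the deformed source (same topology as the input source), the final
    per-vertex geometric-error map, and the accumulated rigid part.
    """
    config = config or RegistrationConfig()
    source.require_closed_oriented("source")
    target.require_closed_oriented("target")
    work = source.copy()
    adjacency = work.vertex_adjacency()
    cache = _TargetCache(target)
    rigid_acc = RigidTransform.identity()
    # rigid-only phase: capture the global pose before any elastic motion
    for _ in range(config.rigid_init_iterations):
        corr = find_correspondences(work, target, config, cache, _validate=False)
        if corr.n_valid < 3:
            break
        rigid = rigid_align(corr, work)
        moved = rigid.apply(work.vertices)
        motion = float(np.linalg.norm(moved - work.vertices, axis=1).mean())
        work = work.with_vertices(moved)
        rigid_acc = rigid.compose(rigid_acc)
        if motion < config.convergence_tol:
            break
    history: list[float] = []
    for it in range(config.n_iterations):
        corr = find_correspondences(work, target, config, cache, _validate=False)
        frac = corr.n_valid / work.n_vertices
        if frac < config.min_valid_fraction:
            raise RegistrationError(
                f"correspondence collapse at iteration {it}: only "
                f"{100 * frac:.1f}% of vertices have a valid match"
            )
        history.append(
            float(
                np.linalg.norm(
                    corr.points[corr.valid] - work.vertices[corr.valid], axis=1
                ).mean()
            )
        )
        before = work.vertices.copy()
        rigid = rigid_align(corr, work)
        work = work.with_vertices(rigid.apply(work.vertices))
        rigid_acc = rigid.compose(rigid_acc)
        work = elastic_step(work, corr, config.beta(it), adjacency)
        motion = float(np.linalg.norm(work.vertices - before, axis=1).mean())
        if motion < config.convergence_tol:
            break
    error = GeometricErrorMap(
        _closest_point_distance(work.vertices, target), history
    )
    return work, error, rigid_acc


# ---------------------------------------------------------------------------
# population average
# ---------------------------------------------------------------------------

def build_average_surface(
    masks,
    config: RegistrationConfig | None = None,
    reference_mask=None,
    decimate_to: int = 900,
    target_decimate_to: int | None = None,
    axial_spacing: float | None = None,
    smooth_sigma_vox: float = 1.0,
):
    """Population-average surface and per-subject corresponded meshes.

    Each subject mask is surfaced (stair-step corrected); the reference surface
    (from ``reference_mask``, defaulting to the first subject) is registered to
    every subject, corresponding vertex positions are averaged, and a second
    registration pass against each subject from the average puts every subject
    surface in dense correspondence with the final average.  Averaging is done
    in surface space.
    """
    masks = list(masks)
    if len(masks) < 2:
        raise ValidationError("need at least 2 masks to build an average surface")
    config = config or RegistrationConfig()

    def _surface(mask, n_verts):
        ax = axial_spacing if axial_spacing is not None else min(mask.spacing[:2])
        return extract_surface(
            interslice_distance_interpolation(mask, ax),
            decimate_to=n_verts,
            smooth_sigma_vox=smooth_sigma_vox,
        )

    tgt_dec = target_decimate_to or 2 * decimate_to
    targets = [_surface(m, tgt_dec) for m in masks]
    ref_mask = reference_mask if reference_mask is not None else masks[0]
    reference = _surface(ref_mask, decimate_to)

    def _pass(ref):
        registered = []
        for i, tgt in enumerate(targets):
            try:
                reg, _, rig = register(ref, tgt, config)
            except RegistrationError as exc:
                raise RegistrationError(f"subject {i}: {exc}") from exc
            # map back into the reference pose: statistics see only the
            # elastic (shape) part, not the subject's rigid pose, so a
            # localized effect cannot leak into a whole-surface offset
            registered.append(reg.with_vertices(rig.inverse().apply(reg.vertices)))
        avg = ref.with_vertices(
            np.mean([r.vertices for r in registered], axis=0)
        )
        return avg, registered

    avg1, _ = _pass(reference)
    avg2, registered = _pass(avg1)
    final_avg = avg2.with_vertices(np.mean([r.vertices for r in registered], axis=0))
    return final_avg, registered
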