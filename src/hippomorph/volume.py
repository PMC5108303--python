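"""Image volumes on regular anisotropic grids.

An :class:`ImageVolume` is a 3-D scalar or label array indexed ``[ix, iy, iz]``
together with voxel spacing (mm) and a world-space origin.  The world position
of voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (voxel-centre
convention, 0-based indices, axis-aligned grids).  The slice axis of a 2-D
multi-slice acquisition is axis 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import ParameterError, ValidationError

__all__ = ["GridSpec", "ImageVolume"]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid geometry: array shape, voxel spacing (mm) and origin (mm).

    Defaults mirror a 2-D multi-slice acquisition with 0.187 mm in-plane
    resolution and 0.5 mm slice thickness.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (0.187, 0.187, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ParameterError(f"grid shape must be 3 entries >= 8, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ParameterError(f"all spacings must be > 0, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid (mm) along each axis."""
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)

    @property
    def center(self) -> np.ndarray:
        """World coordinates of the grid centre."""
        return np.asarray(self.origin) + self.extent / 2.0

    def world_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )


def desk_grid() -> GridSpec:
    """Desk-scale default grid: 96 x 96 x 40 voxels at (0.25, 0.25, 0.5) mm."""
    return GridSpec(shape=(96, 96, 40), spacing=(0.25, 0.25, 0.5))


@dataclass
class ImageVolume:
    """A 3-D image with voxel spacing and world origin (see module docstring)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"all spacings must be > 0, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.data.shape, self.spacing, self.origin)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel indices of world-space points."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    # -- mask helpers -------------------------------------------------------
    def is_binary(self) -> bool:
        return bool(np.isin(np.unique(self.data), (0, 1)).all())

    def require_binary_mask(self, name: str = "mask") -> None:
        if not self.is_binary():
            raise ValidationError(f"{name} must be binary {{0,1}}")

    def foreground_volume(self) -> float:
        """Voxel-count volume of the nonzero region in mm^3."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing, self.origin, dict(self.meta))

    # -- I/O ----------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        img.header.set_zooms(self.spacing)
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(np.linalg.norm(aff[:3, a]) for a in range(3))
        origin = tuple(aff[:3, 3])
        return cls(np.asanyarray(img.dataobj), spacing, origin)
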