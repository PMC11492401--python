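"""Axis-aligned 3D voxel volumes with physical spacing and origin.

One coordinate convention is used throughout the package: voxel indices are
0-based, ``world = origin + index * spacing`` gives the position (mm) of a
voxel *center*, and axes are ordered (x, y, z) = (right, anterior, superior).
Two volumes are co-registered iff shape, spacing and origin are all equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["Volume3D", "GridMismatchError"]


class GridMismatchError(ValueError):
    """Raised when two volumes expected to share a grid do not."""


@dataclass
class Volume3D:
    """A scalar voxel grid (HU, relative electron density, or Gy).

    Parameters
    ----------
    values
        3D array of voxel values, indexed ``[x, y, z]``.
    spacing
        Voxel size in mm per axis; strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self) -> "Volume3D":
        return replace(self, values=self.values.copy())

    def with_values(self, values: np.ndarray) -> "Volume3D":
        """Same grid, new voxel values (shape must match)."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError(f"shape {values.shape} != grid shape {self.shape}")
        return replace(self, values=values)

    # ---- geometry -------------------------------------------------------

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable world-coordinate grids (x, y, z), each shaped for meshing."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Fractional voxel indices for world points (…, 3)."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.array(self.origin)) / np.array(self.spacing)

    @property
    def lower_edge(self) -> np.ndarray:
        """World position of the outer boundary face of voxel (0,0,0)."""
        return np.array(self.origin) - 0.5 * np.array(self.spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # ---- co-registration ------------------------------------------------

    def same_grid(self, other: "Volume3D") -> bool:
        return (
            self.shape == other.shape
            and self.spacing == other.spacing
            and self.origin == other.origin
        )

    def assert_coregistered(self, other: "Volume3D") -> None:
        for attr in ("shape", "spacing", "origin"):
            a, b = getattr(self, attr), getattr(other, attr)
            if tuple(a) != tuple(b):
                raise GridMismatchError(f"volumes differ in {attr}: {a} vs {b}")

    # ---- IO -------------------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        img = nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "Volume3D":
        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        if not np.allclose(rot, np.diag(np.diag(rot))):
            raise ValueError("only axis-aligned NIfTI volumes are supported")
        spacing = tuple(np.diag(rot))
        origin = tuple(affine[:3, 3])
        return cls(np.asarray(img.dataobj), spacing=spacing, origin=origin)


def centered_origin(shape, spacing) -> tuple[float, float, float]:
    """Origin placing the grid's world center at (0, 0, 0)."""
    return tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
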