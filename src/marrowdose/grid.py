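"""Voxel-grid data model and NIfTI I/O.

All image-derived quantities in the package (HU maps, label maps,
time-integrated-activity maps, dose maps) live on a :class:`VoxelGrid`:
0-based voxel indices, half-open extents, world coordinate of a voxel
center = origin + index * spacing in RAS-like axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "save_volume", "load_volume"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a regular voxel grid.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis (nx, ny, nz); every entry must be >= 1.
    spacing : tuple of float
        Voxel edge lengths in mm; every entry must be > 0.
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = field(default="RAS", compare=True)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid voxel spacing {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def check_same(self, other: "VoxelGrid") -> None:
        """Raise if *other* is not the same grid (shape, spacing, origin)."""
        if (self.shape != other.shape or
                not np.allclose(self.spacing, other.spacing) or
                not np.allclose(self.origin, other.origin)):
            raise ValueError(f"grid mismatch: {self} vs {other}")

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """World mm coordinates -> (float) voxel indices."""
        return (np.asarray(xyz) - np.asarray(self.origin)) / np.asarray(self.spacing)

    @classmethod
    def from_affine(cls, shape, affine) -> "VoxelGrid":
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return cls(tuple(shape), spacing, origin)


def save_volume(path, data: np.ndarray, grid: VoxelGrid) -> None:
    """Write a volume as single-file NIfTI-1 with the grid's affine."""
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read a single-file NIfTI-1 volume and its grid."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data, VoxelGrid.from_affine(data.shape, img.affine)
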