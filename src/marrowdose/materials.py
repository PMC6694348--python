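"""CT (HU) to transport-material conversion.

A diagnostic CT in Hounsfield units is converted to a per-voxel mass density
and tissue class (air, lung, soft tissue, bone) through a piecewise-linear
calibration table.  The bundled table anchors air at -1000 HU, water at 0 HU
(density 1.0 g/cm3) and cortical bone at +1000 HU; any monotone user table
with the same columns can be supplied instead.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VoxelGrid

__all__ = ["TISSUE_CLASSES", "MaterialMap", "load_hu_calibration", "hu_to_material"]

#: Integer codes used in :attr:`MaterialMap.tissue_class`.
TISSUE_CLASSES = {"air": 0, "lung": 1, "soft_tissue": 2, "bone": 3}


def _data_path(name: str):
    return importlib.resources.files("marrowdose.data").joinpath(name)


def load_hu_calibration(path=None) -> pd.DataFrame:
    """Load a HU -> (density, tissue class) calibration table.

    The table must have columns ``hu``, ``density_g_cm3``, ``tissue_class``,
    sorted by HU with non-decreasing density.
    """
    tab = pd.read_csv(path if path is not None else _data_path("hu_calibration.csv"))
    required = {"hu", "density_g_cm3", "tissue_class"}
    if not required.issubset(tab.columns):
        raise ValueError(f"calibration table must have columns {sorted(required)}")
    if not tab["hu"].is_monotonic_increasing:
        raise ValueError("calibration HU anchors must be increasing")
    if np.any(np.diff(tab["density_g_cm3"].to_numpy()) < 0):
        raise ValueError("calibration density must be monotone in HU")
    unknown = set(tab["tissue_class"]) - set(TISSUE_CLASSES)
    if unknown:
        raise ValueError(f"unknown tissue classes in calibration: {unknown}")
    return tab


@dataclass
class MaterialMap:
    """Per-voxel mass density (g/cm3) and tissue class (integer code)."""

    grid: VoxelGrid
    density: np.ndarray
    tissue_class: np.ndarray

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=float)
        self.tissue_class = np.asarray(self.tissue_class, dtype=np.int8)
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        if self.tissue_class.shape != self.grid.shape:
            raise ValueError("tissue_class shape does not match grid")
        if np.any(self.density < 0):
            raise ValueError("negative density")

    @property
    def voxel_mass_g(self) -> np.ndarray:
        """Per-voxel mass in grams (density * voxel volume)."""
        return self.density * (self.grid.voxel_volume_mm3 / 1000.0)

    def class_mask(self, name: str) -> np.ndarray:
        return self.tissue_class == TISSUE_CLASSES[name]


def hu_to_material(ct_hu: np.ndarray, grid: VoxelGrid,
                   calibration: pd.DataFrame | None = None) -> MaterialMap:
    """Convert a HU volume to a :class:`MaterialMap`.

    Density is interpolated piecewise-linearly between the calibration
    anchors; the tissue class of a voxel is that of the calibration segment
    containing its HU value (the class recorded at the segment's lower
    anchor).  HU values outside the calibrated range or non-finite are
    rejected.
    """
    ct_hu = np.asarray(ct_hu, dtype=float)
    if ct_hu.shape != grid.shape:
        raise ValueError("HU volume shape does not match grid")
    if not np.all(np.isfinite(ct_hu)):
        raise ValueError("non-finite HU values present")
    cal = calibration if calibration is not None else load_hu_calibration()
    hu_anchor = cal["hu"].to_numpy(dtype=float)
    if ct_hu.min() < hu_anchor[0] or ct_hu.max() > hu_anchor[-1]:
        raise ValueError(
            f"HU range [{ct_hu.min():.0f}, {ct_hu.max():.0f}] outside calibration "
            f"[{hu_anchor[0]:.0f}, {hu_anchor[-1]:.0f}]")

    density = np.interp(ct_hu, hu_anchor, cal["density_g_cm3"].to_numpy(dtype=float))
    seg = np.clip(np.searchsorted(hu_anchor, ct_hu, side="right") - 1,
                  0, len(hu_anchor) - 1)
    class_codes = cal["tissue_class"].map(TISSUE_CLASSES).to_numpy(dtype=np.int8)
    tissue = class_codes[seg]
    return MaterialMap(grid=grid, density=density, tissue_class=tissue)
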