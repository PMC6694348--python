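"""Skeleton segmentation and per-voxel marrow composition.

The skeleton is segmented from CT by a HU threshold (default 200) with
per-slice hole filling.  Each skeletal voxel is then assigned to one of 13
active-marrow-bearing bone regions via a supplied label volume, and carries
the region's reference mass fractions of active bone marrow (f_BM), inactive
(fatty) marrow (f_iaBM) and mineralized hard bone (f_HB).  The fractions of
every skeletal voxel sum to one, so that the voxel represents the full bone
mixture whose absorbed dose the transport engine scores.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import VoxelGrid

__all__ = ["N_REGIONS", "load_skeletal_composition", "segment_skeleton",
           "SkeletalCompositionMap", "assign_skeletal_regions"]

log = logging.getLogger(__name__)

N_REGIONS = 13


def load_skeletal_composition(path=None) -> pd.DataFrame:
    """Load the 13-region (f_BM, f_iaBM, f_HB) reference-fraction table.

    The bundled table is an editable reference-male-style input; rows must
    sum to 1 within 1e-6.
    """
    src = path if path is not None else importlib.resources.files(
        "marrowdose.data").joinpath("skeletal_composition.csv")
    tab = pd.read_csv(src)
    required = {"region_id", "region", "f_bm", "f_iabm", "f_hb"}
    if not required.issubset(tab.columns):
        raise ValueError(f"composition table must have columns {sorted(required)}")
    _validate_composition(tab)
    return tab


def _validate_composition(tab: pd.DataFrame) -> None:
    frac = tab[["f_bm", "f_iabm", "f_hb"]].to_numpy(dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("composition fractions must lie in [0, 1]")
    bad = np.abs(frac.sum(axis=1) - 1.0) > 1e-6
    if np.any(bad):
        rows = tab.loc[bad, "region"].tolist()
        raise ValueError(f"composition rows do not sum to 1: {rows}")
    ids = tab["region_id"].to_numpy(dtype=int)
    if np.any(ids < 1) or np.any(ids > N_REGIONS):
        raise ValueError(f"region ids must be 1..{N_REGIONS}")


def segment_skeleton(ct_hu: np.ndarray, threshold: float = 200.0) -> np.ndarray:
    """Binary skeleton mask: HU >= threshold, then per-slice hole filling.

    Hole filling runs independently on each axial (last-axis) slice, closing
    marrow cavities enclosed by cortical bone.  An empty result is legal
    (warning only).
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    ct_hu = np.asarray(ct_hu, dtype=float)
    mask = ct_hu >= threshold
    for k in range(mask.shape[2]):
        mask[:, :, k] = ndimage.binary_fill_holes(mask[:, :, k])
    if not mask.any():
        warnings.warn("skeleton segmentation produced an empty mask")
    return mask


@dataclass
class SkeletalCompositionMap:
    """Per-voxel bone region label (0 = non-skeletal, 1..13) and fractions."""

    grid: VoxelGrid
    region_label: np.ndarray
    f_bm: np.ndarray
    f_iabm: np.ndarray
    f_hb: np.ndarray

    def __post_init__(self):
        for name in ("f_bm", "f_iabm", "f_hb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape does not match grid")
            setattr(self, name, arr)
        self.region_label = np.asarray(self.region_label, dtype=np.int16)
        skel = self.region_label > 0
        total = self.f_bm + self.f_iabm + self.f_hb
        if np.any(np.abs(total[skel] - 1.0) > 1e-9):
            raise ValueError("skeletal voxel fractions do not sum to 1")
        if np.any(total[~skel] != 0.0):
            raise ValueError("non-skeletal voxels must carry zero fractions")

    @property
    def skeleton_mask(self) -> np.ndarray:
        return self.region_label > 0


def assign_skeletal_regions(skeleton_mask: np.ndarray,
                            region_labels: np.ndarray,
                            composition: pd.DataFrame | None = None,
                            grid: VoxelGrid | None = None,
                            default_region: int | str = "lumbar_spine",
                            ) -> SkeletalCompositionMap:
    """Attach reference marrow fractions to every skeletal voxel.

    ``region_labels`` assigns each voxel a bone region id in 1..13 (0 for
    unlabeled).  Skeletal voxels left unlabeled fall back to
    ``default_region`` (name or id; the spine-equivalent default is logged),
    mirroring template-registration gaps in the clinical workflow.
    """
    skeleton_mask = np.asarray(skeleton_mask, dtype=bool)
    region_labels = np.asarray(region_labels)
    if region_labels.shape != skeleton_mask.shape:
        raise ValueError("region label volume must match skeleton mask shape")
    comp = composition if composition is not None else load_skeletal_composition()
    _validate_composition(comp)
    if region_labels.max(initial=0) > N_REGIONS:
        raise ValueError(f"region label > {N_REGIONS} present")
    if region_labels.min(initial=0) < 0:
        raise ValueError("negative region label present")

    if isinstance(default_region, str):
        row = comp.loc[comp["region"] == default_region]
        if row.empty:
            raise ValueError(f"unknown default region {default_region!r}")
        default_id = int(row["region_id"].iloc[0])
    else:
        default_id = int(default_region)

    labels = np.where(skeleton_mask, region_labels, 0).astype(np.int16)
    unlabeled = skeleton_mask & (labels == 0)
    if unlabeled.any():
        log.info("assigning default region %d to %d unlabeled skeletal voxels",
                 default_id, int(unlabeled.sum()))
        labels[unlabeled] = default_id

    # region_id -> fraction lookup arrays (index 0 = non-skeletal, zeros)
    lut = np.zeros((N_REGIONS + 1, 3))
    for _, r in comp.iterrows():
        lut[int(r["region_id"])] = (r["f_bm"], r["f_iabm"], r["f_hb"])
    frac = lut[labels]
    grid = grid if grid is not None else VoxelGrid(skeleton_mask.shape)
    return SkeletalCompositionMap(grid=grid, region_label=labels,
                                  f_bm=frac[..., 0], f_iabm=frac[..., 1],
                                  f_hb=frac[..., 2])
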