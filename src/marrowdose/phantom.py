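"""Synthetic voxel-patient generator.

Every downstream stage (material conversion, skeletal composition, kinetics,
transport, marrow models, reference dosimetry) is exercised on synthetic
patients: a CT-like HU volume of a body ellipsoid containing a 13-region
skeleton, two kidneys and spherical bone/soft-tissue lesions, together with
ground-truth VOIs, compartmental Lu-177 kinetics (mono-exponential organ
curves, bi-exponential blood), the analytic per-voxel time-integrated
activity they imply, and noisy "measured" activity samples at the clinical
time points (24/48/72 h SPECT, 24 h whole-body planar, five blood samples).

The generator emulates the geometry and bookkeeping of the clinical inputs,
not anthropomorphic realism: organs are ellipsoids and rods, activity is
uniform within a compartment, and noise is multiplicative Gaussian.
Regenerating with the same seed reproduces the patient bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grid import VoxelGrid
from .kinetics import ExpFit, tia_analytic
from .materials import MaterialMap, hu_to_material
from .skeleton import SkeletalCompositionMap, assign_skeletal_regions

__all__ = ["PhantomConfig", "SyntheticPatient", "generate_phantom"]

# truth_voi label codes
VOI_BACKGROUND = 0
VOI_ROB = 1
VOI_KIDNEY_L = 2
VOI_KIDNEY_R = 3
VOI_LESION_BASE = 10  # lesion i -> 10 + i


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic patient.

    Defaults mirror the clinical setting the package targets: ~6 GBq
    Lu-177-PSMA administered, abdominal SPECT at 24/48/72 h, a whole-body
    planar at 24 h, five blood samples, hematocrit 0.43, an osseous-dominant
    lesion pattern with strong lesion-to-background contrast, and effective
    half-lives of tens of hours (physical decay included in the rates).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    administered_gbq: float = 6.0
    hematocrit: float = 0.43

    n_bone_lesions: int = 4
    n_soft_lesions: int = 1
    lesion_radius_mm: float = 10.0
    lesion_tia_fraction: float | None = None

    # activity fractions of the administered activity at t = 0 and
    # effective half-lives (hours)
    kidney_fraction: float = 0.025          # per kidney
    kidney_half_life_h: float = 35.0
    lesion_fraction: float = 0.15           # all lesions together
    lesion_half_life_h: float = 70.0
    rob_fraction: float = 0.45
    rob_half_life_h: float = 45.0
    # blood bi-exponential (fractions of administered, as concentration
    # over blood_volume_ml)
    blood_fractions: tuple[float, float] = (0.30, 0.06)
    blood_half_lives_h: tuple[float, float] = (1.5, 40.0)
    blood_volume_ml: float = 5000.0

    noise_pct: float = 5.0
    spect_times_h: tuple[float, ...] = (24.0, 48.0, 72.0)
    blood_times_h: tuple[float, ...] = (0.5, 1.33, 24.0, 48.0, 72.0)

    hu_soft: float = 0.0
    hu_bone: float = 600.0
    hu_bone_lesion: float = 700.0
    hu_noise: float = 15.0

    def validate(self):
        if self.administered_gbq <= 0:
            raise ValueError("administered activity must be positive")
        t0 = (2 * self.kidney_fraction + self.lesion_fraction
              + self.rob_fraction)
        if t0 > 1.0 + 1e-9:
            raise ValueError("compartment activities at t=0 exceed the "
                             "administered activity")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.lesion_tia_fraction is not None and not (
                0 <= self.lesion_tia_fraction < 1):
            raise ValueError("lesion_tia_fraction must lie in [0, 1)")

    @classmethod
    def from_json(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items() if k != "seed"})
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticPatient:
    """Ground-truth bundle produced by :func:`generate_phantom`."""

    grid: VoxelGrid
    ct_hu: np.ndarray
    truth_voi: np.ndarray          # VOI_* label codes
    region_labels: np.ndarray      # skeletal regions 0..13
    truth_tia: np.ndarray          # decays per voxel
    truth_kinetics: dict[str, ExpFit]
    compartment_tias: dict[str, float]
    measured: pd.DataFrame         # t_hours, activity_MBq, compartment
    blood_samples: pd.DataFrame    # t_hours, conc_mbq_ml
    activity_24h: np.ndarray       # SPECT-like spatial weight volume
    marrow_voi: np.ndarray         # granulocyte-image-like marrow VOI
    hematocrit: float
    administered_gbq: float
    config: PhantomConfig
    seed: int
    lesion_ids: tuple[int, ...] = field(default_factory=tuple)

    # -- convenience builders for the downstream stages -------------------
    def material_map(self) -> MaterialMap:
        return hu_to_material(self.ct_hu, self.grid)

    def skeletal_map(self) -> SkeletalCompositionMap:
        return assign_skeletal_regions(self.region_labels > 0,
                                       self.region_labels, grid=self.grid)

    @property
    def skeleton_mask(self) -> np.ndarray:
        return self.region_labels > 0

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.truth_voi >= VOI_LESION_BASE

    def voi_masks(self) -> dict[str, np.ndarray]:
        masks = {"kidney_L": self.truth_voi == VOI_KIDNEY_L,
                 "kidney_R": self.truth_voi == VOI_KIDNEY_R,
                 "rob": self.truth_voi == VOI_ROB,
                 "lesions": self.lesion_mask}
        return masks


def _ellipsoid(grid_shape, center, semi_axes):
    idx = np.indices(grid_shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semi_axes[a]) ** 2 for a in range(3))
    return r2 <= 1.0


def _cylinder_z(grid_shape, cx, cy, radius, z_lo, z_hi):
    idx = np.indices(grid_shape, dtype=float)
    r2 = (idx[0] - cx) ** 2 + (idx[1] - cy) ** 2
    return (r2 <= radius**2) & (idx[2] >= z_lo) & (idx[2] < z_hi)


def _box(grid_shape, x, y, z):
    m = np.zeros(grid_shape, dtype=bool)
    m[x[0]:x[1], y[0]:y[1], z[0]:z[1]] = True
    return m


def _build_skeleton(shape):
    """13-region skeleton layout (region id -> mask), torso-like."""
    nx, ny, nz = shape
    sx, sy, sz = nx / 64.0, ny / 64.0, nz / 64.0  # scale from reference layout

    def S(v, s):
        return int(round(v * s))

    spine = _cylinder_z(shape, S(32, sx), S(42, sy), 3.5 * sx, S(8, sz), S(48, sz))
    regions = {}
    zidx = np.indices(shape)[2]
    regions[6] = spine & (zidx < S(14, sz))                      # sacrum
    regions[5] = spine & (zidx >= S(14, sz)) & (zidx < S(24, sz))  # lumbar
    regions[4] = spine & (zidx >= S(24, sz)) & (zidx < S(40, sz))  # thoracic
    regions[3] = spine & (zidx >= S(40, sz)) & (zidx < S(48, sz))  # cervical
    regions[1] = _ellipsoid(shape, (S(32, sx), S(36, sy), S(55, sz)),
                            (6 * sx, 6 * sy, 5 * sz))            # skull
    regions[2] = _box(shape, (S(29, sx), S(35, sx)), (S(26, sy), S(30, sy)),
                      (S(50, sz), S(53, sz)))                    # mandible
    regions[7] = _box(shape, (S(30, sx), S(34, sx)), (S(16, sy), S(19, sy)),
                      (S(28, sz), S(38, sz)))                    # sternum
    # ribs: elliptical shells at a few thoracic levels, with anterior
    # (costal-cartilage) gaps so the rings are open in every axial slice
    idx = np.indices(shape, dtype=float)
    gap_ribs = (np.abs(idx[0] - S(32, sx)) < 4 * sx) & (idx[1] < S(24, sy))
    ribs = np.zeros(shape, dtype=bool)
    for z0 in (26, 30, 34, 38):
        ring = ((idx[0] - S(32, sx)) / (16 * sx)) ** 2 + \
               ((idx[1] - S(30, sy)) / (14 * sy)) ** 2
        ribs |= (np.abs(np.sqrt(ring) - 1.0) < 0.10) & \
                (np.abs(idx[2] - S(z0, sz)) < max(1.0, sz))
    regions[8] = ribs & ~gap_ribs
    regions[9] = (_box(shape, (S(20, sx), S(30, sx)), (S(20, sy), S(23, sy)),
                       (S(44, sz), S(46, sz)))
                  | _box(shape, (S(34, sx), S(44, sx)), (S(20, sy), S(23, sy)),
                         (S(44, sz), S(46, sz))))                # clavicles
    regions[10] = (_box(shape, (S(16, sx), S(22, sx)), (S(38, sy), S(42, sy)),
                        (S(34, sz), S(42, sz)))
                   | _box(shape, (S(42, sx), S(48, sx)), (S(38, sy), S(42, sy)),
                          (S(34, sz), S(42, sz))))               # scapulae
    # pelvic ring with an anterior (pubic-symphysis) gap, again to keep
    # axial slices free of enclosed holes
    ring = ((idx[0] - S(32, sx)) / (13 * sx)) ** 2 + \
           ((idx[1] - S(32, sy)) / (11 * sy)) ** 2
    gap_pelvis = (np.abs(idx[0] - S(32, sx)) < 3 * sx) & (idx[1] < S(32, sy))
    regions[11] = (np.abs(np.sqrt(ring) - 1.0) < 0.18) & \
        (idx[2] >= S(8, sz)) & (idx[2] < S(16, sz)) & ~gap_pelvis  # os coxae
    regions[12] = (_cylinder_z(shape, S(12, sx), S(30, sy), 2.2 * sx,
                               S(30, sz), S(44, sz))
                   | _cylinder_z(shape, S(52, sx), S(30, sy), 2.2 * sx,
                                 S(30, sz), S(44, sz)))          # humeri
    regions[13] = (_cylinder_z(shape, S(24, sx), S(30, sy), 2.5 * sx,
                               S(2, sz), S(10, sz))
                   | _cylinder_z(shape, S(40, sx), S(30, sy), 2.5 * sx,
                                 S(2, sz), S(10, sz)))           # femora
    return regions


def generate_phantom(config: PhantomConfig | None = None,
                     seed: int = 0) -> SyntheticPatient:
    """Build a synthetic patient; bit-identical for a fixed (config, seed)."""
    cfg = config if config is not None else PhantomConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.shape)
    grid = VoxelGrid(shape, cfg.spacing_mm)

    body = _ellipsoid(shape, tuple(s / 2.0 - 0.5 for s in shape),
                      (0.44 * shape[0], 0.40 * shape[1], 0.49 * shape[2]))
    region_masks = _build_skeleton(shape)
    region_labels = np.zeros(shape, dtype=np.int16)
    for rid in sorted(region_masks):
        m = region_masks[rid] & body
        if not m.any():
            raise RuntimeError(f"skeleton region {rid} empty on this grid")
        region_labels[m] = rid
    skeleton = region_labels > 0

    sx, sy, sz = (shape[0] / 64.0, shape[1] / 64.0, shape[2] / 64.0)
    kidney_l = _ellipsoid(shape, (20 * sx, 33 * sy, 24 * sz),
                          (4 * sx, 3 * sy, 5 * sz)) & body & ~skeleton
    kidney_r = _ellipsoid(shape, (44 * sx, 33 * sy, 24 * sz),
                          (4 * sx, 3 * sy, 5 * sz)) & body & ~skeleton

    # lesions: spheres carved out of the skeleton (bone) or soft tissue
    r_vox = cfg.lesion_radius_mm / float(np.mean(cfg.spacing_mm))
    lesion_masks = []
    skel_idx = np.argwhere(skeleton)
    soft_idx = np.argwhere(body & ~skeleton & ~kidney_l & ~kidney_r)
    for i in range(cfg.n_bone_lesions):
        c = skel_idx[rng.integers(len(skel_idx))]
        m = _ellipsoid(shape, tuple(c), (r_vox,) * 3) & skeleton
        lesion_masks.append(m)
    for i in range(cfg.n_soft_lesions):
        c = soft_idx[rng.integers(len(soft_idx))]
        m = _ellipsoid(shape, tuple(c), (r_vox,) * 3) & body & ~skeleton
        lesion_masks.append(m)
    lesion_all = np.zeros(shape, dtype=bool)
    voi = np.where(body, VOI_ROB, VOI_BACKGROUND).astype(np.int16)
    lesion_ids = []
    for i, m in enumerate(lesion_masks):
        m = m & ~lesion_all  # each voxel belongs to exactly one lesion
        if (m & (kidney_l | kidney_r)).any():
            raise ValueError(f"lesion {i} overlaps a kidney; rejecting config")
        if not m.any():
            continue
        lesion_all |= m
        voi[m] = VOI_LESION_BASE + i
        lesion_ids.append(VOI_LESION_BASE + i)
    voi[kidney_l] = VOI_KIDNEY_L
    voi[kidney_r] = VOI_KIDNEY_R

    # --- CT volume -------------------------------------------------------
    hu = np.full(shape, -1000.0)
    hu[body] = cfg.hu_soft + cfg.hu_noise * rng.standard_normal(
        int(body.sum()))
    hu[kidney_l | kidney_r] = 30.0 + 10.0 * rng.standard_normal(
        int((kidney_l | kidney_r).sum()))
    hu[skeleton] = np.clip(
        cfg.hu_bone + 50.0 * rng.standard_normal(int(skeleton.sum())),
        250.0, 1400.0)
    bone_lesion = lesion_all & skeleton
    hu[bone_lesion] = np.clip(
        cfg.hu_bone_lesion + 50.0 * rng.standard_normal(int(bone_lesion.sum())),
        250.0, 1400.0)
    soft_lesion = lesion_all & ~skeleton
    hu[soft_lesion] = 40.0 + 10.0 * rng.standard_normal(int(soft_lesion.sum()))
    hu[body] = np.clip(hu[body], -150.0, 1400.0)

    # --- kinetics (amplitudes MBq, rates 1/h) ----------------------------
    a_mbq = cfg.administered_gbq * 1000.0
    ln2 = np.log(2.0)
    kin = {
        "kidney_L": ExpFit([cfg.kidney_fraction * a_mbq],
                           [ln2 / cfg.kidney_half_life_h]),
        "kidney_R": ExpFit([cfg.kidney_fraction * a_mbq],
                           [ln2 / cfg.kidney_half_life_h]),
        "lesions": ExpFit([cfg.lesion_fraction * a_mbq],
                          [ln2 / cfg.lesion_half_life_h]),
        "rob": ExpFit([cfg.rob_fraction * a_mbq],
                      [ln2 / cfg.rob_half_life_h]),
    }
    blood = ExpFit(
        [f * a_mbq / cfg.blood_volume_ml for f in cfg.blood_fractions],
        [ln2 / t for t in cfg.blood_half_lives_h])

    if cfg.lesion_tia_fraction is not None:
        others = sum(tia_analytic(kin[k]) for k in
                     ("kidney_L", "kidney_R", "rob"))
        f = cfg.lesion_tia_fraction
        target_tia = f / (1.0 - f) * others
        lam = kin["lesions"].rates[0]
        from .kinetics import MBQ_H_TO_BQ_S
        kin["lesions"] = ExpFit([target_tia / MBQ_H_TO_BQ_S * lam], [lam])
        t0 = (kin["kidney_L"].amplitudes[0] + kin["kidney_R"].amplitudes[0]
              + kin["lesions"].amplitudes[0] + kin["rob"].amplitudes[0])
        if t0 > a_mbq + 1e-9:
            raise ValueError("lesion_tia_fraction requires more activity at "
                             "t=0 than was administered")

    comp_tia = {k: tia_analytic(v) for k, v in kin.items()}

    # --- analytic per-voxel truth TIA (uniform within compartments) ------
    tia = np.zeros(shape)
    masks = {"kidney_L": kidney_l, "kidney_R": kidney_r,
             "lesions": lesion_all, "rob": body & ~kidney_l & ~kidney_r
             & ~lesion_all}
    for name, m in masks.items():
        n = int(m.sum())
        if n == 0:
            if comp_tia[name] > 0:
                raise RuntimeError(f"compartment {name} empty but active")
            continue
        tia[m] = comp_tia[name] / n

    # --- measured data ---------------------------------------------------
    noise = cfg.noise_pct / 100.0
    rows = []
    for name in ("kidney_L", "kidney_R", "lesions"):
        for t in cfg.spect_times_h:
            a = float(kin[name](np.array(t)))
            rows.append((t, a * (1.0 + noise * rng.standard_normal()), name))
    for t in cfg.spect_times_h:
        a = float(sum(kin[k](np.array(t)) for k in kin))
        rows.append((t, a * (1.0 + noise * rng.standard_normal()),
                     "spect_total"))
    wb = float(sum(kin[k](np.array(24.0)) for k in kin))
    rows.append((24.0, wb * (1.0 + noise * rng.standard_normal()),
                 "whole_body"))
    measured = pd.DataFrame(rows, columns=["t_hours", "activity_MBq",
                                           "compartment"])
    measured["activity_MBq"] = measured["activity_MBq"].clip(lower=0.0)

    bt = np.asarray(cfg.blood_times_h)
    bconc = blood(bt) * (1.0 + noise * rng.standard_normal(len(bt)))
    blood_samples = pd.DataFrame({"t_hours": bt,
                                  "conc_mbq_ml": np.clip(bconc, 0.0, None)})

    # SPECT-like 24 h activity image (spatial weight for TIA allocation)
    act24 = np.zeros(shape)
    for name, m in masks.items():
        n = int(m.sum())
        if n:
            act24[m] = float(kin[name](np.array(24.0))) / n
    act24 *= np.clip(1.0 + noise * rng.standard_normal(shape), 0.0, None)

    # granulocyte-image-like marrow VOI: marrow displaced from lesions
    marrow_voi = skeleton & ~lesion_all

    kin["blood"] = blood
    return SyntheticPatient(
        grid=grid, ct_hu=hu, truth_voi=voi, region_labels=region_labels,
        truth_tia=tia, truth_kinetics=kin, compartment_tias=comp_tia,
        measured=measured, blood_samples=blood_samples, activity_24h=act24,
        marrow_voi=marrow_voi, hematocrit=cfg.hematocrit,
        administered_gbq=cfg.administered_gbq, config=cfg, seed=seed,
        lesion_ids=tuple(lesion_ids))
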