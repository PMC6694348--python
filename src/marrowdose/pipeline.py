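"""End-to-end dosimetry pipeline on synthetic patients.

phantom -> kinetics fits -> TIA map -> voxel Monte Carlo -> marrow models
(MC1/MC2/gMC3) -> reference S-value dosimetry (SMIRD) -> comparison report.
Every stage failure carries a stage tag; a fixed (config, seed) reproduces
the report byte-identically.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .analysis import model_ratio_table
from .bm_models import (aggregate_bm_dose, apply_gmc3, apply_mc1, apply_mc2)
from .coefficients import CoefficientTables
from .engine import simulate_dose
from .grid import save_volume
from .kinetics import (build_tia_map, fit_biexp, fit_monoexp, hybrid_rob_tia,
                       rmblr, tia_analytic)
from .nuclear import DecayData
from .phantom import PhantomConfig, generate_phantom
from .smird import PatientAnatomy, SValueTable, smird_bm_dose

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-patient dosimetry run."""

    phantom: PhantomConfig
    n_histories: int = 200_000
    include_photons: bool = True
    electron_mode: str = "local"
    w_mode: str = "per_event"
    models: tuple[str, ...] = ("MC1", "MC2", "gMC3", "SMIRD")
    red_marrow_mass_override_g: float | None = None

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        phantom = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("phantom", {}).items()})
        raw.pop("seed", None)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(phantom=phantom, **raw)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"[stage {name}] {exc}") from exc
        return wrapper
    return deco


def _table_checksums() -> dict[str, str]:
    out = {}
    data = importlib.resources.files("marrowdose.data")
    for entry in sorted(p.name for p in data.iterdir() if p.name.endswith(".csv")):
        out[entry] = hashlib.md5(
            data.joinpath(entry).read_bytes()).hexdigest()
    return out


def run_pipeline(config: PipelineConfig | None = None, seed: int = 0,
                 outdir=None) -> dict:
    """Run the full chain and return report, results and intermediates.

    The returned dict holds the per-model report DataFrame (``report``),
    the per-model :class:`DosimetryResult` objects (``results``), the TIA
    and dose maps, the synthetic patient and a JSON-serializable run
    manifest.  With ``outdir`` all artifacts are written to disk
    (NIfTI volumes, CSV report, manifest).
    """
    cfg = config if config is not None else PipelineConfig(PhantomConfig())

    patient = _stage("phantom")(generate_phantom)(cfg.phantom, seed=seed)
    material = _stage("materials")(patient.material_map)()
    skeletal = _stage("skeleton")(patient.skeletal_map)()

    # --- kinetics fits on the measured samples ---------------------------
    @_stage("kinetics")
    def _kinetics():
        meas = patient.measured
        fits = {}
        for comp in ("kidney_L", "kidney_R", "lesions"):
            if comp == "lesions" and not patient.lesion_mask.any():
                continue
            sub = meas[meas["compartment"] == comp]
            fits[comp] = fit_monoexp(sub["t_hours"], sub["activity_MBq"])
        blood_fit = fit_biexp(patient.blood_samples["t_hours"],
                              patient.blood_samples["conc_mbq_ml"])
        tias = {c: tia_analytic(f) for c, f in fits.items()}
        tias.setdefault("lesions", 0.0)

        ratio = rmblr(patient.hematocrit)
        rm_mass = (cfg.red_marrow_mass_override_g
                   or float((skeletal.f_bm * material.voxel_mass_g).sum()))
        blood_conc_tia_bq_s_ml = tia_analytic(blood_fit)  # Bq s / ml
        blood_bm_tia = ratio * blood_conc_tia_bq_s_ml * rm_mass

        spect = meas[meas["compartment"] == "spect_total"]
        wb24 = float(meas.loc[meas["compartment"] == "whole_body",
                              "activity_MBq"].iloc[0])
        rob_tia = hybrid_rob_tia(spect["t_hours"], spect["activity_MBq"],
                                 wb24,
                                 kidney_tia_bq_s=tias["kidney_L"]
                                 + tias["kidney_R"],
                                 blood_bm_tia_bq_s=blood_bm_tia)
        return fits, tias, rob_tia, blood_conc_tia_bq_s_ml, ratio, rm_mass

    fits, tias, rob_tia, blood_conc_tia, rmblr_val, rm_mass = _kinetics()

    # --- per-voxel TIA map ------------------------------------------------
    @_stage("tia-map")
    def _tia():
        comp = {"kidney_L": tias["kidney_L"], "kidney_R": tias["kidney_R"],
                "lesions": tias["lesions"], "rob": rob_tia}
        return build_tia_map(patient.voi_masks(), comp, patient.grid,
                             spatial_weights=patient.activity_24h,
                             voxel_mass_g=material.voxel_mass_g,
                             administered_gbq=patient.administered_gbq)

    tia_map = _tia()

    # --- Monte Carlo ------------------------------------------------------
    decay = DecayData.lu177()
    tables = CoefficientTables.load()
    dose_map = _stage("simulate")(simulate_dose)(
        tia_map, material, skeletal, decay, tables,
        n_histories=cfg.n_histories, seed=seed,
        include_photons=cfg.include_photons,
        electron_mode=cfg.electron_mode, w_mode=cfg.w_mode)

    # --- marrow models and reference dosimetry ---------------------------
    results = {}

    @_stage("bm-models")
    def _models():
        mc1 = apply_mc1(skeletal, material)
        if "MC1" in cfg.models:
            results["MC1"] = aggregate_bm_dose(dose_map, mc1,
                                               patient.administered_gbq)
        if "MC2" in cfg.models:
            mc2 = apply_mc2(mc1, patient.lesion_mask)
            results["MC2"] = aggregate_bm_dose(dose_map, mc2,
                                               patient.administered_gbq)
        if "gMC3" in cfg.models:
            g = apply_gmc3(skeletal, material, patient.marrow_voi)
            results["gMC3"] = aggregate_bm_dose(dose_map, g,
                                                patient.administered_gbq)

    _models()

    if "SMIRD" in cfg.models:
        @_stage("smird")
        def _smird():
            body_mass = float(material.voxel_mass_g[
                material.density > 0.5].sum())
            kmass = tuple(
                float(material.voxel_mass_g[patient.truth_voi == code].sum())
                for code in (2, 3))
            anatomy = PatientAnatomy(red_marrow_mass_g=rm_mass,
                                     kidney_mass_g=kmass,
                                     whole_body_mass_g=body_mass,
                                     hematocrit=patient.hematocrit)
            table = SValueTable.load()
            results["SMIRD"] = smird_bm_dose(
                blood_conc_tia / 1e6,                      # Bq s -> MBq s
                (tias["kidney_L"] / 1e6, tias["kidney_R"] / 1e6),
                rob_tia / 1e6, table, anatomy,
                administered_gbq=patient.administered_gbq,
                rmblr_value=rmblr_val)

        _smird()

    report = pd.DataFrame(
        [{"model": tag, "bm_dose_mgy": r.bm_dose_mgy,
          "bm_dose_mgy_per_gbq": r.bm_dose_mgy_per_gbq,
          "stderr_mgy": r.stderr_mgy if r.stderr_mgy is not None else np.nan}
         for tag, r in results.items()])

    ratios = None
    if {"MC1", "MC2", "SMIRD"}.issubset(results):
        ratios = model_ratio_table(pd.DataFrame([{
            "patient": f"synthetic-{seed}",
            "smird_mgy": results["SMIRD"].bm_dose_mgy,
            "mc1_mgy": results["MC1"].bm_dose_mgy,
            "mc2_mgy": results["MC2"].bm_dose_mgy}]))

    manifest = {"package_version": __version__, "seed": seed,
                "config": {"phantom": patient.config.to_dict(),
                           "n_histories": cfg.n_histories,
                           "include_photons": cfg.include_photons,
                           "electron_mode": cfg.electron_mode,
                           "w_mode": cfg.w_mode, "models": list(cfg.models)},
                "table_checksums": _table_checksums(),
                "compartment_tias_bq_s": {k: float(v) for k, v in
                                          {**tias, "rob": rob_tia}.items()}}

    if outdir is not None:
        import pathlib
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_volume(outdir / "ct_hu.nii.gz", patient.ct_hu, patient.grid)
        save_volume(outdir / "truth_voi.nii.gz", patient.truth_voi,
                    patient.grid)
        save_volume(outdir / "tia.nii.gz", tia_map.tia, patient.grid)
        save_volume(outdir / "dose_bone.nii.gz", dose_map.dose_bone,
                    patient.grid)
        save_volume(outdir / "dose_bm.nii.gz", dose_map.dose_bm, patient.grid)
        report.to_csv(outdir / "report.csv", index=False)
        if ratios is not None:
            ratios.to_csv(outdir / "model_ratios.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("pipeline artifacts written to %s", outdir)

    return {"report": report, "results": results, "ratios": ratios,
            "tia_map": tia_map, "dose_map": dose_map, "patient": patient,
            "fits": fits, "manifest": manifest}
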