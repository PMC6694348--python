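"""Reference organ-level bone-marrow dosimetry with mass-scaled S values.

The reference method (SMIRD) combines three source contributions to the red
marrow: the blood self-dose (via the red-marrow-to-blood concentration
ratio), the kidney cross-doses, and the remainder-of-body cross-dose, which
by convention also carries the total lesion activity (no dedicated lesion
S-value channel exists for an arbitrary lesion distribution):

    D = S(rm<-rm) * RMBLR * C_blood * m_rm
        + sum_k S(rm<-kidney_k) * TIA_k + S(rm<-ROB) * TIA_ROB

with every S value scaled from its reference phantom mass to the
patient-specific mass (inverse-linear for the marrow self term, a
configurable exponent for cross terms; exponent 1 by default for the
electron-dominated Lu-177 emissions).

The bundled S-value table is illustrative (RADAR-style structure, not the
licensed values); it is an input, and tests assert structure and
arithmetic, not clinical values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bm_models import DosimetryResult

__all__ = ["SValueTable", "PatientAnatomy", "scale_svalue", "smird_bm_dose"]

REQUIRED_SOURCES = ("red_marrow", "kidney_L", "kidney_R", "rob")


@dataclass
class SValueTable:
    """Source -> red-marrow S values (mGy per MBq s) with reference masses."""

    table: pd.DataFrame
    phantom_tag: str = "illustrative-adult-male"

    def __post_init__(self):
        required = {"source", "target", "s_mgy_per_mbq_s", "ref_mass_g"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"S-value table must have columns {sorted(required)}")
        if np.any(self.table["s_mgy_per_mbq_s"].to_numpy() < 0):
            raise ValueError("S values must be nonnegative")
        if np.any(self.table["ref_mass_g"].to_numpy() <= 0):
            raise ValueError("reference masses must be positive")
        missing = set(REQUIRED_SOURCES) - set(self.table["source"])
        if missing:
            raise ValueError(f"missing required sources: {sorted(missing)}")

    @classmethod
    def load(cls, path=None, phantom_tag: str | None = None) -> "SValueTable":
        src = path if path is not None else importlib.resources.files(
            "marrowdose.data").joinpath("svalues_example.csv")
        tag = phantom_tag or ("illustrative-adult-male" if path is None
                              else "user")
        return cls(pd.read_csv(src), tag)

    def entry(self, source: str) -> tuple[float, float]:
        row = self.table.loc[self.table["source"] == source]
        if row.empty:
            raise ValueError(f"source {source!r} not in S-value table")
        return (float(row["s_mgy_per_mbq_s"].iloc[0]),
                float(row["ref_mass_g"].iloc[0]))


@dataclass
class PatientAnatomy:
    """Patient-specific masses and hematocrit for S-value scaling."""

    red_marrow_mass_g: float
    kidney_mass_g: tuple[float, float]
    whole_body_mass_g: float
    hematocrit: float

    def __post_init__(self):
        masses = (self.red_marrow_mass_g, *self.kidney_mass_g,
                  self.whole_body_mass_g)
        if any(m <= 0 for m in masses):
            raise ValueError("all masses must be positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must lie in (0, 1)")

    @property
    def rob_mass_g(self) -> float:
        """Whole body minus kidneys and red marrow (scaling convention)."""
        return (self.whole_body_mass_g - sum(self.kidney_mass_g)
                - self.red_marrow_mass_g)


def scale_svalue(s_ref: float, m_ref: float, m_patient: float,
                 mode: str = "self", exponent: float = 1.0) -> float:
    """Scale a reference S value to the patient anatomy.

    Self-dose terms scale by (m_ref / m_patient); cross-dose terms by the
    target-mass ratio raised to ``exponent`` (0 disables scaling).
    """
    if m_ref <= 0 or m_patient <= 0:
        raise ValueError("masses must be positive")
    if mode not in ("self", "cross"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    power = 1.0 if mode == "self" else exponent
    return s_ref * (m_ref / m_patient) ** power


def smird_bm_dose(blood_conc_tia_mbq_s_ml: float,
                  kidney_tias_mbq_s: tuple[float, float],
                  rob_tia_incl_lesions_mbq_s: float,
                  table: SValueTable, anatomy: PatientAnatomy,
                  administered_gbq: float = 0.0,
                  rmblr_value: float | None = None,
                  c_ecf: float = 0.19,
                  cross_exponent: float = 1.0,
                  cross_scale_by: str = "target") -> DosimetryResult:
    """Reference bone-marrow dose from blood, kidney and ROB sources.

    ``blood_conc_tia_mbq_s_ml`` is the blood activity-concentration TIA; the
    marrow self-TIA is RMBLR * C_blood * red-marrow mass (1 g marrow taken
    as 1 ml).  Kidney and ROB TIAs are in MBq s.  Linear in every TIA.
    ``cross_scale_by`` selects whether the kidney cross terms scale with the
    target (red marrow, default) or source (kidney) mass.
    """
    from .kinetics import rmblr as rmblr_fn

    tias = (blood_conc_tia_mbq_s_ml, *kidney_tias_mbq_s,
            rob_tia_incl_lesions_mbq_s)
    if any(t < 0 for t in tias):
        raise ValueError("TIAs must be nonnegative")
    ratio = (rmblr_value if rmblr_value is not None
             else rmblr_fn(anatomy.hematocrit, c_ecf))

    s_rm, m_rm_ref = table.entry("red_marrow")
    d = scale_svalue(s_rm, m_rm_ref, anatomy.red_marrow_mass_g, "self") * (
        ratio * blood_conc_tia_mbq_s_ml * anatomy.red_marrow_mass_g)

    for src, tia, m_kid in zip(("kidney_L", "kidney_R"), kidney_tias_mbq_s,
                               anatomy.kidney_mass_g):
        s_k, m_ref = table.entry(src)
        if cross_scale_by == "target":
            _, m_rm_ref2 = table.entry("red_marrow")
            s_scaled = scale_svalue(s_k, m_rm_ref2, anatomy.red_marrow_mass_g,
                                    "cross", cross_exponent)
        else:
            s_scaled = scale_svalue(s_k, m_ref, m_kid, "cross", cross_exponent)
        d += s_scaled * tia

    s_rob, m_rob_ref = table.entry("rob")
    if cross_scale_by == "target":
        _, m_rm_ref2 = table.entry("red_marrow")
        s_scaled = scale_svalue(s_rob, m_rm_ref2, anatomy.red_marrow_mass_g,
                                "cross", cross_exponent)
    else:
        s_scaled = scale_svalue(s_rob, m_rob_ref, anatomy.rob_mass_g, "cross",
                                cross_exponent)
    d += s_scaled * rob_tia_incl_lesions_mbq_s

    return DosimetryResult(model_tag="SMIRD", bm_dose_mgy=float(d),
                           administered_gbq=float(administered_gbq),
                           provenance={"phantom": table.phantom_tag,
                                       "rmblr": ratio,
                                       "cross_exponent": cross_exponent,
                                       "cross_scale_by": cross_scale_by})
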