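"""Cohort statistics and packaged study tables.

Summaries of the published 11-cycle Lu-177-PSMA cohort: per-model median
bone-marrow dose per administered activity, integer dose-ratio tables
between the marrow models, the image-derived (gMC3) dose reduction, and
Pearson correlations of doses with hematological response (nadir-to-baseline
blood-count ratios) and with lesion-load covariates.

The published per-cycle dose table, its per-cycle integer model-ratio table,
the two-patient gMC3 comparison and the patient characteristics are shipped
as CSV fixtures.  Note that integer ratios recomputed from the *rounded*
published doses can differ by one unit from the published per-cycle ratios
(which were formed from unrounded doses); both routes are exposed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["load_cohort_doses", "load_model_ratios", "load_gmc3_table",
           "load_patient_table", "BloodSeries", "nadir_baseline_ratio",
           "pearson", "round_half_away", "round_sig",
           "model_ratio_table", "dose_per_activity_summary",
           "gmc3_reduction", "correlate_doses"]


def _fixture(name: str) -> pd.DataFrame:
    return pd.read_csv(
        importlib.resources.files("marrowdose.data").joinpath(name))


def load_cohort_doses() -> pd.DataFrame:
    """Per-cycle doses (mGy) for SMIRD/MC1/MC2 with administered activity
    (GBq) and lesion-load covariates."""
    return _fixture("table_cohort_doses.csv")


def load_model_ratios() -> pd.DataFrame:
    """Published per-cycle integer dose ratios between the models."""
    return _fixture("table_model_ratios.csv")


def load_gmc3_table() -> pd.DataFrame:
    """Two-patient comparison including the image-derived gMC3 dose."""
    return _fixture("table_gmc3.csv")


def load_patient_table() -> pd.DataFrame:
    """Patient characteristics and baseline blood counts."""
    return _fixture("table_patients.csv")


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

@dataclass
class BloodSeries:
    """A blood-count time series with its pre-therapy baseline at t = 0."""

    analyte: str
    t_days: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.t_days = np.asarray(self.t_days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t_days.shape != self.values.shape or self.t_days.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if np.any(np.diff(self.t_days) < 0):
            raise ValueError("times must be nondecreasing")
        if not (self.t_days[0] == 0):
            raise ValueError("series must start with the baseline at t = 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")

    @property
    def baseline(self) -> float:
        return float(self.values[0])


def nadir_baseline_ratio(series: BloodSeries) -> float:
    """Lowest post-baseline value divided by the baseline."""
    if len(series.values) < 2:
        raise ValueError("need at least one post-baseline sample")
    return float(series.values[1:].min() / series.baseline)


def pearson(x, y) -> tuple[float, float, float]:
    """Sample Pearson correlation with two-sided p (t distribution, n-2 df).

    Returns (r, p, R^2); both vectors must be nonconstant with n >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined correlation")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, float(res.pvalue), r * r


def round_half_away(x) -> np.ndarray:
    """Round to nearest integer with halves away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from decimal import Decimal
    exp = int(np.floor(np.log10(abs(x))))
    q = round(Decimal(repr(float(x))).scaleb(-(exp - sig + 1)))
    return float(Decimal(q).scaleb(exp - sig + 1))


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def model_ratio_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle integer dose ratios MC1/SMIRD, MC2/SMIRD, MC1/MC2.

    Ratios are rounded half-away-from-zero to integers; a final row holds
    the column medians (of the integer ratios).  Rows with a zero SMIRD or
    MC2 dose are rejected.
    """
    required = {"patient", "smird_mgy", "mc1_mgy", "mc2_mgy"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    if (cohort["smird_mgy"] <= 0).any() or (cohort["mc2_mgy"] <= 0).any():
        bad = cohort.loc[(cohort["smird_mgy"] <= 0) |
                         (cohort["mc2_mgy"] <= 0), "patient"].tolist()
        raise ValueError(f"zero SMIRD or MC2 dose for {bad}; ratio undefined")
    out = pd.DataFrame({
        "patient": cohort["patient"],
        "mc1_smird": round_half_away(cohort["mc1_mgy"] / cohort["smird_mgy"]),
        "mc2_smird": round_half_away(cohort["mc2_mgy"] / cohort["smird_mgy"]),
        "mc1_mc2": round_half_away(cohort["mc1_mgy"] / cohort["mc2_mgy"]),
    })
    med = {"patient": "median"}
    for c in ("mc1_smird", "mc2_smird", "mc1_mc2"):
        med[c] = int(np.median(out[c]))
    return pd.concat([out, pd.DataFrame([med])], ignore_index=True)


def dose_per_activity_summary(cohort: pd.DataFrame,
                              models=("mc1", "mc2", "smird")) -> pd.DataFrame:
    """Per-model median (and range) dose per administered activity.

    Values are mGy/GBq, reported to two significant figures.
    """
    if (cohort["activity_gbq"] <= 0).any():
        raise ValueError("administered activity must be positive")
    rows = []
    for m in models:
        per = cohort[f"{m}_mgy"] / cohort["activity_gbq"]
        rows.append({"model": m.upper(),
                     "median_mgy_per_gbq": round_sig(float(per.median())),
                     "min_mgy_per_gbq": round_sig(float(per.min())),
                     "max_mgy_per_gbq": round_sig(float(per.max()))})
    return pd.DataFrame(rows)


def gmc3_reduction(dose_mc1_mgy: float, dose_gmc3_mgy: float) -> int:
    """Percent dose reduction of the image-derived model vs MC1 (integer)."""
    if dose_mc1_mgy <= 0:
        raise ValueError("MC1 dose must be positive")
    if dose_gmc3_mgy < 0:
        raise ValueError("doses must be nonnegative")
    return int(round_half_away(100.0 * (1.0 - dose_gmc3_mgy / dose_mc1_mgy)))


def correlate_doses(cohort: pd.DataFrame, outcome: pd.Series | np.ndarray,
                    models=("mc1", "mc2", "smird"),
                    per_gbq: bool = False) -> pd.DataFrame:
    """Pearson correlation of per-model doses with an outcome vector.

    With ``per_gbq`` the doses are normalized by administered activity first
    (the publication's normalization convention is ambiguous, so both are
    reported by the pipeline).
    """
    y = np.asarray(outcome, dtype=float)
    rows = []
    for m in models:
        x = cohort[f"{m}_mgy"].to_numpy(dtype=float)
        if per_gbq:
            x = x / cohort["activity_gbq"].to_numpy(dtype=float)
        r, p, r2 = pearson(x, y)
        rows.append({"model": m.upper(), "r": r, "p": p, "r2": r2,
                     "normalization": "per_gbq" if per_gbq else "absolute"})
    return pd.DataFrame(rows)
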