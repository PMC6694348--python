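"""Time-activity kinetics and time-integrated activity (TIA).

Compartment kinetics after a Lu-177 administration are described by mono- or
bi-exponential effective curves A(t) = sum_i A_i exp(-lambda_i t) (MBq, 1/h);
the effective rates contain physical decay, so time integration runs over
[0, inf) of the fitted curve.  Conversions: 1 MBq h = 3.6e9 Bq s (decays).

The module also implements the organ-level ingredients of reference marrow
dosimetry: the hematocrit-based red-marrow-to-blood activity concentration
ratio (RMBLR), the hybrid SPECT-planar remainder-of-body (ROB) model in which
a mono-exponential fitted to sequential abdominal SPECT totals is rescaled
through the whole-body planar activity at 24 h, and the scaling of abdominal
lesion quantities to the whole body by the total-to-abdominal lesion-volume
ratio.  Finally, per-voxel TIA maps are built by distributing compartment
TIAs over VOIs proportionally to a 24-h activity image (kidneys, lesions) or
uniformly per unit mass (ROB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .grid import VoxelGrid

__all__ = ["ExpFit", "FitError", "fit_monoexp", "fit_biexp", "tia_analytic",
           "rmblr", "hybrid_rob_tia", "scale_lesions_to_whole_body",
           "TIAMap", "build_tia_map", "MBQ_H_TO_BQ_S"]

MBQ_H_TO_BQ_S = 3600.0 * 1e6


class FitError(RuntimeError):
    """Raised when a time-activity fit fails; carries residual diagnostics."""


@dataclass
class ExpFit:
    """A fitted sum of decaying exponentials.

    amplitudes are in MBq (or MBq/ml for concentration curves), rates in 1/h,
    sorted by descending rate for the bi-exponential case.  Amplitudes and
    rates are constrained nonnegative/positive, so the fitted curve is
    nonnegative on [0, inf).
    """

    amplitudes: np.ndarray
    rates: np.ndarray
    covariance: np.ndarray | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        self.rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        if self.amplitudes.shape != self.rates.shape:
            raise ValueError("amplitudes and rates must have equal length")
        if np.any(self.rates <= 0):
            raise ValueError("fitted rates must be positive")
        if np.any(self.amplitudes < 0):
            raise ValueError("fitted amplitudes must be nonnegative")
        order = np.argsort(-self.rates)
        self.amplitudes = self.amplitudes[order]
        self.rates = self.rates[order]
        if self.n_terms == 2 and np.isclose(self.rates[0], self.rates[1]):
            raise ValueError("bi-exponential rates must be distinct")

    @property
    def n_terms(self) -> int:
        return len(self.rates)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.sum(self.amplitudes[:, None] *
                      np.exp(-np.outer(self.rates, np.ravel(t))),
                      axis=0).reshape(t.shape)


def _check_samples(t, a, n_min):
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    if t.shape != a.shape or t.ndim != 1:
        raise ValueError("time and activity must be 1-D arrays of equal length")
    if len(t) < n_min:
        raise ValueError(f"need at least {n_min} samples")
    if np.any(t < 0):
        raise ValueError("negative sample times")
    if np.any(a < 0):
        raise ValueError("negative activities")
    if len(np.unique(t)) != len(t):
        raise ValueError("sample times must be distinct")
    order = np.argsort(t)
    return t[order], a[order]


def fit_monoexp(t_hours, activity) -> ExpFit:
    """Least-squares mono-exponential fit A exp(-lambda t).

    Initialization is the log-linear regression of log(activity) on t
    (zero activities nudged to a tiny positive value), refined by bounded
    nonlinear least squares; deterministic.
    """
    t, a = _check_samples(t_hours, activity, 2)
    loga = np.log(np.maximum(a, 1e-12))
    slope, intercept = np.polyfit(t, loga, 1)
    lam0 = max(-slope, 1e-6)
    a0 = max(np.exp(intercept), 1e-12)

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - a

    sol = least_squares(resid, x0=[a0, lam0],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]))
    if not sol.success:
        raise FitError(f"mono-exponential fit did not converge: {sol.message}; "
                       f"residuals {sol.fun}")
    cov = _covariance(sol)
    return ExpFit(sol.x[:1], sol.x[1:2], covariance=cov, residuals=sol.fun)


def fit_biexp(t_hours, activity) -> ExpFit:
    """Least-squares bi-exponential fit A1 exp(-l1 t) + A2 exp(-l2 t).

    Initialization by curve peeling: a mono-exponential on the late half of
    the samples seeds the slow term, its residual on the early samples seeds
    the fast term.  Bounded nonnegative least squares, deterministic; both
    unconstrained amplitudes (default) are estimated.
    """
    t, a = _check_samples(t_hours, activity, 4)
    half = len(t) // 2
    slow = fit_monoexp(t[half:], a[half:])
    early = np.maximum(a[:half] - slow(t[:half]), 1e-12)
    if len(t[:half]) >= 2:
        fast = fit_monoexp(t[:half], early)
        a1, l1 = float(fast.amplitudes[0]), float(fast.rates[0])
    else:  # degenerate split; seed fast term above the slow rate
        a1, l1 = float(early[0]), 10.0 * float(slow.rates[0])
    x0 = [a1, max(l1, 2.0 * float(slow.rates[0])),
          float(slow.amplitudes[0]), float(slow.rates[0])]

    def resid(p):
        return p[0] * np.exp(-p[1] * t) + p[2] * np.exp(-p[3] * t) - a

    sol = least_squares(resid, x0=x0, bounds=(0.0, np.inf))
    if not sol.success:
        raise FitError(f"bi-exponential fit did not converge: {sol.message}; "
                       f"residuals {sol.fun}")
    if np.isclose(sol.x[1], sol.x[3], rtol=1e-3):
        raise FitError("bi-exponential fit collapsed to equal rates")
    cov = _covariance(sol)
    return ExpFit(sol.x[[0, 2]], sol.x[[1, 3]], covariance=cov,
                  residuals=sol.fun)


def _covariance(sol):
    """Gauss-Newton covariance estimate from the least-squares Jacobian."""
    m, n = sol.jac.shape
    if m <= n:
        return None
    dof = m - n
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        return s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        return None


def tia_analytic(fit: ExpFit, t_from: float = 0.0,
                 t_to: float = np.inf) -> float:
    """Analytic time integral of the fitted curve, in Bq s (decays).

    sum_i A_i / lambda_i (exp(-lambda_i t_from) - exp(-lambda_i t_to)),
    converted from MBq h.
    """
    if t_to < t_from:
        raise ValueError("t_to must be >= t_from")
    lo = np.exp(-fit.rates * t_from)
    hi = np.exp(-fit.rates * t_to) if np.isfinite(t_to) else 0.0
    mbq_h = float(np.sum(fit.amplitudes / fit.rates * (lo - hi)))
    return mbq_h * MBQ_H_TO_BQ_S


def rmblr(hematocrit: float, c_ecf: float = 0.19) -> float:
    """Red-marrow-to-blood activity concentration ratio.

    For a tracer without specific marrow or blood-cell binding the marrow
    concentration is the extracellular-fluid fraction ``c_ecf`` of the plasma
    concentration, giving c_ecf / (1 - hematocrit) -- below one for
    physiological inputs (setting c_ecf = 1 - hematocrit recovers the
    PRRT convention of RMBLR = 1).
    """
    if not 0.0 < hematocrit < 1.0:
        raise ValueError("hematocrit must lie in (0, 1)")
    return c_ecf / (1.0 - hematocrit)


def hybrid_rob_tia(spect_t_hours, spect_total_mbq, whole_body_24h_mbq: float,
                   kidney_tia_bq_s: float = 0.0,
                   blood_bm_tia_bq_s: float = 0.0) -> float:
    """Remainder-of-body TIA from the hybrid SPECT-planar model, in Bq s.

    A mono-exponential is fitted to the sequential (abdominal) SPECT total
    activities, rescaled so it passes through the planar whole-body activity
    at 24 h p.i., and integrated over [0, inf); kidney and blood-attributed
    TIAs are then subtracted.
    """
    t, a = _check_samples(spect_t_hours, spect_total_mbq, 3)
    if whole_body_24h_mbq <= 0:
        raise ValueError("whole-body activity at 24 h must be positive")
    fit = fit_monoexp(t, a)
    scale = whole_body_24h_mbq / float(fit(np.array(24.0)))
    total = scale * tia_analytic(fit)
    rob = total - kidney_tia_bq_s - blood_bm_tia_bq_s
    if rob < 0:
        raise ValueError(
            f"subtrahends exceed whole-body TIA ({total:.4g} Bq s): "
            "inconsistent inputs")
    return rob


def scale_lesions_to_whole_body(abdominal_value: float,
                                total_lesion_volume_ml: float,
                                abdominal_lesion_volume_ml: float) -> float:
    """Scale an abdominal-field lesion quantity by total/abdominal volume."""
    if abdominal_lesion_volume_ml <= 0:
        raise ValueError("abdominal lesion volume must be positive")
    if total_lesion_volume_ml < abdominal_lesion_volume_ml:
        raise ValueError("total lesion volume must be >= abdominal volume")
    return abdominal_value * (total_lesion_volume_ml / abdominal_lesion_volume_ml)


@dataclass
class TIAMap:
    """Per-voxel time-integrated activity (decays = Bq s)."""

    grid: VoxelGrid
    tia: np.ndarray
    compartment_totals: dict[str, float]
    administered_gbq: float = 0.0

    def __post_init__(self):
        self.tia = np.asarray(self.tia, dtype=float)
        if self.tia.shape != self.grid.shape:
            raise ValueError("TIA shape does not match grid")
        if np.any(self.tia < 0):
            raise ValueError("negative TIA")

    @property
    def total(self) -> float:
        return float(self.tia.sum())

    def summary(self) -> pd.DataFrame:
        rows = [{"compartment": k, "tia_bq_s": v}
                for k, v in self.compartment_totals.items()]
        rows.append({"compartment": "whole_body", "tia_bq_s": self.total})
        return pd.DataFrame(rows)


def build_tia_map(voi_masks: dict[str, np.ndarray],
                  compartment_tias: dict[str, float],
                  grid: VoxelGrid,
                  spatial_weights: np.ndarray | None = None,
                  voxel_mass_g: np.ndarray | None = None,
                  uniform_compartments: tuple[str, ...] = ("rob",),
                  administered_gbq: float = 0.0) -> TIAMap:
    """Distribute compartment TIAs onto voxels.

    Within kidneys and lesions, voxel TIA is proportional to the 24-h
    activity image ``spatial_weights`` (uniform if none is given); within
    compartments named in ``uniform_compartments`` (the ROB) it is uniform
    per unit mass when ``voxel_mass_g`` is supplied, else per voxel.  Each
    compartment's voxel sum equals its input TIA exactly.
    """
    tia = np.zeros(grid.shape)
    totals: dict[str, float] = {}
    for name, total_tia in compartment_tias.items():
        if name not in voi_masks:
            raise ValueError(f"no VOI mask for compartment {name!r}")
        mask = np.asarray(voi_masks[name], dtype=bool)
        if mask.shape != grid.shape:
            raise ValueError(f"VOI {name!r} shape does not match grid")
        if total_tia < 0:
            raise ValueError(f"negative TIA for compartment {name!r}")
        if name in uniform_compartments:
            w = (voxel_mass_g[mask] if voxel_mass_g is not None
                 else np.ones(int(mask.sum())))
        elif spatial_weights is not None:
            w = np.asarray(spatial_weights, dtype=float)[mask]
            if np.any(w < 0):
                raise ValueError("spatial weights must be nonnegative")
        else:
            w = np.ones(int(mask.sum()))
        wsum = float(w.sum())
        if total_tia > 0 and (mask.sum() == 0 or wsum == 0):
            raise ValueError(
                f"compartment {name!r} has zero total weight but TIA "
                f"{total_tia:.4g}")
        if wsum > 0:
            tia[mask] += total_tia * (w / wsum)
        totals[name] = float(total_tia)
    return TIAMap(grid=grid, tia=tia, compartment_totals=totals,
                  administered_gbq=administered_gbq)
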