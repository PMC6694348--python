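"""Interaction-coefficient tables and the active-marrow weighting factor.

A clinical CT voxel classed as bone contains an unresolved mixture of active
bone marrow (BM), inactive fatty marrow (iaBM) and mineralized hard bone
(HB).  The transport engine scores energy imparted to the whole mixture; the
dose to the active marrow alone is obtained by multiplying each deposition
by a weighting factor

    w(E) = (c_BM(E)) / (f_BM c_BM(E) + f_iaBM c_iaBM(E) + f_HB c_HB(E)),

where c_i is the photon mass attenuation coefficient (cm^2/g) or the
electron mass stopping power (MeV cm^2/g) of constituent i and the f_i are
the voxel's mass fractions (summing to one).  w is an effective interaction
probability of the active marrow relative to the mixture: it equals one for
pure marrow, and drops below one when hard bone attenuates more strongly
than marrow at the deposition energy.

Coefficient curves are log-log interpolated from versioned CSV tables
bundled with the package (1-600 keV); toy constant-coefficient tables can be
constructed for validation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoefficientTables", "mixture_coefficient", "weighting_factor"]

#: medium names used for the three bone constituents
CONSTITUENT_MEDIA = {"bm": "marrow_red", "iabm": "marrow_yellow",
                     "hb": "bone_cortical"}


def _loglog_interp(e, e_grid, values):
    e = np.asarray(e, dtype=float)
    if np.any(e < e_grid[0] - 1e-9) or np.any(e > e_grid[-1] + 1e-9):
        raise ValueError(
            f"energy outside table range [{e_grid[0]:g}, {e_grid[-1]:g}] keV")
    return np.exp(np.interp(np.log(e), np.log(e_grid), np.log(values)))


@dataclass
class CoefficientTables:
    """Photon mass attenuation and electron stopping-power curves per medium.

    ``photon`` / ``electron`` are DataFrames with an ``energy_keV`` column
    and one strictly positive column per medium; ``z_over_a`` maps media to
    their electron density ratio Z/A (used by the transport engine for the
    Klein-Nishina incoherent component).
    """

    photon: pd.DataFrame
    electron: pd.DataFrame
    z_over_a: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for tab, label in ((self.photon, "photon"), (self.electron, "electron")):
            if "energy_keV" not in tab.columns:
                raise ValueError(f"{label} table needs an energy_keV column")
            vals = tab.drop(columns="energy_keV").to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"{label} coefficients must be positive")
            if not tab["energy_keV"].is_monotonic_increasing:
                raise ValueError(f"{label} energy grid must be increasing")

    @classmethod
    def load(cls, photon_path=None, electron_path=None, media_path=None
             ) -> "CoefficientTables":
        data = importlib.resources.files("marrowdose.data")
        photon = pd.read_csv(photon_path or data.joinpath(
            "photon_mass_attenuation.csv"))
        electron = pd.read_csv(electron_path or data.joinpath(
            "electron_stopping_power.csv"))
        media = pd.read_csv(media_path or data.joinpath("media.csv"))
        zoa = dict(zip(media["medium"], media["z_over_a"]))
        return cls(photon, electron, zoa)

    @classmethod
    def from_constants(cls, values: dict[str, float],
                       e_range=(1.0, 600.0)) -> "CoefficientTables":
        """Constant (energy-independent) coefficient curves, for validation."""
        e = np.array(e_range, dtype=float)
        cols = {"energy_keV": e}
        cols.update({m: np.full(2, v) for m, v in values.items()})
        tab = pd.DataFrame(cols)
        return cls(tab.copy(), tab.copy())

    @property
    def energy_range_kev(self) -> tuple[float, float]:
        e = self.photon["energy_keV"].to_numpy()
        return float(e[0]), float(e[-1])

    def coefficient(self, medium: str, e_kev, particle: str):
        """c(E) for one medium: photon mu/rho or electron S/rho."""
        tab = {"photon": self.photon, "electron": self.electron}[particle]
        if medium not in tab.columns:
            raise ValueError(f"no {particle} coefficients for medium {medium!r}")
        return _loglog_interp(e_kev, tab["energy_keV"].to_numpy(dtype=float),
                              tab[medium].to_numpy(dtype=float))

    def constituents(self, e_kev, particle: str):
        """(c_BM, c_iaBM, c_HB) at the given energies."""
        return tuple(self.coefficient(CONSTITUENT_MEDIA[k], e_kev, particle)
                     for k in ("bm", "iabm", "hb"))


def _check_fractions(f_bm, f_iabm, f_hb):
    total = np.asarray(f_bm) + np.asarray(f_iabm) + np.asarray(f_hb)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("constituent mass fractions must sum to 1")


def mixture_coefficient(e_kev, particle: str, fractions,
                        tables: CoefficientTables):
    """Mass-fraction-weighted coefficient of the bone mixture at E.

    ``fractions`` is (f_BM, f_iaBM, f_HB); broadcasting over arrays of
    energies and fractions is supported.
    """
    f_bm, f_iabm, f_hb = fractions
    _check_fractions(f_bm, f_iabm, f_hb)
    c_bm, c_iabm, c_hb = tables.constituents(e_kev, particle)
    return f_bm * c_bm + f_iabm * c_iabm + f_hb * c_hb


def weighting_factor(e_kev, particle: str, fractions,
                     tables: CoefficientTables):
    """Active-marrow weighting factor w(E) = c_BM(E) / c_mixture(E)."""
    mix = mixture_coefficient(e_kev, particle, fractions, tables)
    if np.any(mix <= 0):
        raise ValueError("mixture coefficient is nonpositive")
    c_bm = tables.coefficient(CONSTITUENT_MEDIA["bm"], e_kev, particle)
    return c_bm / mix
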