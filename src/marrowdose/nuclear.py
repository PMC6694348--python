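"""Lu-177 emission data and decay sampling.

Lu-177 decays by beta-minus emission (maximum energies up to 498 keV, mean
around 134-140 keV) accompanied by gamma lines, dominated by 208.4 keV
(10.4%) and 113.0 keV (6.2%).  The bundled tables hold the photon lines
(energy, yield per decay) and a binned beta spectrum; both can be replaced
by user CSVs, including monoenergetic test spectra.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecayData", "sample_decay"]


@dataclass
class DecayData:
    """Photon lines and a binned electron (beta) spectrum for one nuclide.

    photon_lines: array (n, 2) of (energy keV, yield per decay).
    beta_bins: array (m, 3) of (e_lo keV, e_hi keV, probability); the
    probabilities sum to 1.  A decay emits each photon line with its yield
    probability and exactly one beta electron.
    """

    photon_lines: np.ndarray
    beta_bins: np.ndarray

    def __post_init__(self):
        self.photon_lines = np.atleast_2d(np.asarray(self.photon_lines, float))
        self.beta_bins = np.atleast_2d(np.asarray(self.beta_bins, float))
        if self.photon_lines.size and (np.any(self.photon_lines[:, 0] <= 0)
                                       or np.any(self.photon_lines[:, 1] < 0)):
            raise ValueError("photon energies must be > 0 and yields >= 0")
        if self.beta_bins.size:
            p = self.beta_bins[:, 2]
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("beta spectrum probabilities must sum to 1")
            if np.any(self.beta_bins[:, 1] <= 0):
                raise ValueError("beta bin energies must be positive")

    @classmethod
    def lu177(cls) -> "DecayData":
        data = importlib.resources.files("marrowdose.data")
        lines = pd.read_csv(data.joinpath("lu177_photons.csv"))
        beta = pd.read_csv(data.joinpath("lu177_beta_spectrum.csv"))
        p = beta["probability"].to_numpy()
        return cls(lines[["energy_keV", "yield"]].to_numpy(),
                   np.column_stack([beta["e_lo_keV"], beta["e_hi_keV"],
                                    p / p.sum()]))

    @classmethod
    def monoenergetic(cls, energy_kev: float, particle: str = "electron",
                      yield_per_decay: float = 1.0) -> "DecayData":
        """Single-line test spectrum (one photon line or a delta beta bin)."""
        if particle == "photon":
            return cls(np.array([[energy_kev, yield_per_decay]]),
                       np.zeros((0, 3)))
        return cls(np.zeros((0, 2)),
                   np.array([[energy_kev, energy_kev, 1.0]]))

    @property
    def mean_beta_energy_kev(self) -> float:
        if not self.beta_bins.size:
            return 0.0
        centers = 0.5 * (self.beta_bins[:, 0] + self.beta_bins[:, 1])
        return float(centers @ self.beta_bins[:, 2])

    @property
    def mean_photon_energy_per_decay_kev(self) -> float:
        if not self.photon_lines.size:
            return 0.0
        return float(self.photon_lines[:, 0] @ self.photon_lines[:, 1])

    def sample_beta_energies(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n beta energies: bin by probability, uniform within bin."""
        if not self.beta_bins.size:
            return np.zeros(0)
        idx = rng.choice(len(self.beta_bins), size=n, p=self.beta_bins[:, 2])
        lo, hi = self.beta_bins[idx, 0], self.beta_bins[idx, 1]
        return lo + (hi - lo) * rng.random(n)


def sample_decay(decay_data: DecayData, rng: np.random.Generator,
                 n_histories: int = 1):
    """Sample primaries for ``n_histories`` decays.

    Returns a list of (particle, energies, history_index) groups: one entry
    per photon line holding the energies and history ids of the photons it
    emitted (Bernoulli per history with the line yield), plus one electron
    group with a beta energy per history.  Directions are sampled
    isotropically at transport time.
    """
    out = []
    for e, y in decay_data.photon_lines:
        hist = np.flatnonzero(rng.random(n_histories) < y)
        out.append(("photon", np.full(len(hist), e), hist))
    if decay_data.beta_bins.size:
        out.append(("electron",
                    decay_data.sample_beta_energies(n_histories, rng),
                    np.arange(n_histories)))
    return out
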