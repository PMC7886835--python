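"""Filtered x-ray tube spectra.

The tube spectrum is modeled with Kramers' bremsstrahlung law,
N(E) dE ∝ (kVp − E)/E, hardened by a copper filter of thickness t:
N_f(E) = N(E) · exp(−μ_Cu(E)·t).  Tungsten characteristic lines and the
anode heel effect are deliberately omitted; for dose-pattern work in the
40-150 kV fluoroscopic range the filtered continuum carries the relevant
energy dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import (
    DEFAULT_DENSITY,
    ENERGY_MIN_KEV,
    Material,
    attenuation_coefficient,
)

__all__ = ["Spectrum", "generate_spectrum", "monoenergetic", "sample_energy"]


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon-energy distribution of the filtered beam.

    ``relative_fluence`` is nonnegative, zero above ``kvp`` and below the
    5 keV transport cutoff, and sums to 1.
    """

    kvp: float
    filter_cu_mm: float
    energy_bins: np.ndarray      # keV, bin centers
    relative_fluence: np.ndarray

    def __post_init__(self) -> None:
        w = self.relative_fluence
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("relative_fluence must be nonnegative and sum to 1")
        if np.any((self.energy_bins > self.kvp) & (w > 0)):
            raise ValueError("nonzero fluence above kvp")
        if np.any(self.energy_bins < ENERGY_MIN_KEV):
            raise ValueError("bins below the 5 keV cutoff")

    @property
    def mean_energy_keV(self) -> float:
        return float(self.energy_bins @ self.relative_fluence)

    def cdf(self) -> np.ndarray:
        c = np.cumsum(self.relative_fluence)
        c[-1] = 1.0
        return c


def generate_spectrum(kvp_kV: float, filter_cu_mm: float, bin_width_keV: float = 1.0) -> Spectrum:
    """Kramers spectrum at tube potential ``kvp_kV`` filtered by copper.

    Bins run from the 5 keV cutoff up to ``kvp_kV`` at ``bin_width_keV``
    spacing (bin centers); weights are normalized to sum to 1.
    """
    if not 40.0 <= kvp_kV <= 150.0:
        raise ValueError(f"kvp {kvp_kV} outside supported range 40-150 kV")
    if filter_cu_mm < 0:
        raise ValueError("filter thickness must be nonnegative")
    edges = np.arange(ENERGY_MIN_KEV, kvp_kV + bin_width_keV, bin_width_keV)
    edges = edges[edges <= kvp_kV]
    if edges[-1] < kvp_kV:
        edges = np.append(edges, kvp_kV)
    centers = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    w = kramers_filtered(centers, kvp_kV, filter_cu_mm) * widths
    total = w.sum()
    if total <= 0:
        raise ValueError("spectrum is empty after filtration")
    return Spectrum(kvp=float(kvp_kV), filter_cu_mm=float(filter_cu_mm),
                    energy_bins=centers, relative_fluence=w / total)


def monoenergetic(energy_keV: float) -> Spectrum:
    """Single-line spectrum, useful for benchmark geometries."""
    if energy_keV < ENERGY_MIN_KEV:
        raise ValueError("energy below the 5 keV cutoff")
    return Spectrum(kvp=float(energy_keV), filter_cu_mm=0.0,
                    energy_bins=np.array([float(energy_keV)]),
                    relative_fluence=np.array([1.0]))


def kramers_filtered(energy_keV, kvp_kV: float, filter_cu_mm: float):
    """Unnormalized filtered Kramers fluence density at ``energy_keV``."""
    e = np.asarray(energy_keV, dtype=float)
    n = np.clip(kvp_kV - e, 0.0, None) / e
    if filter_cu_mm > 0:
        mu_cu = attenuation_coefficient(Material.COPPER, e, DEFAULT_DENSITY[Material.COPPER])
        n = n * np.exp(-np.asarray(mu_cu) * filter_cu_mm / 10.0)  # mm -> cm
    return n


def sample_energy(spectrum: Spectrum, rng: np.random.Generator, size: int | None = None):
    """Inverse-CDF sample of photon energies (keV) from ``spectrum``."""
    u = rng.random(size)
    idx = np.searchsorted(spectrum.cdf(), u, side="right")
    idx = np.minimum(idx, spectrum.energy_bins.size - 1)
    out = spectrum.energy_bins[idx]
    if size is None:
        return float(out)
    return out
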