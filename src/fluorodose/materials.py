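"""Photon cross-section tables for the materials used in transport.

The packaged CSV (``data/photon_xsections.csv``) carries, per material and
energy, the mass attenuation coefficient mu/rho, the mass energy-transfer
coefficient mu_tr/rho (equal to the energy-absorption coefficient below
150 keV, where radiative losses are negligible), and the fractional
partition of the total cross section into photoelectric, Compton
(incoherent) and Rayleigh (coherent) channels.  Values between grid points
are obtained by log-log linear interpolation, which stays positive and is
monotone-safe between anchors.

Provenance of the numeric data is documented in ``data/README.md``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Material",
    "MaterialTable",
    "load_material_table",
    "attenuation_coefficient",
    "ENERGY_MIN_KEV",
    "ENERGY_MAX_KEV",
]

ENERGY_MIN_KEV = 5.0
ENERGY_MAX_KEV = 150.0


class Material(enum.IntEnum):
    """Material identifiers; integer values index the transport lookup arrays."""

    AIR = 0
    LUNG = 1
    SOFT_TISSUE = 2
    BONE = 3
    WATER = 4
    COPPER = 5


_NAME_TO_MATERIAL = {m.name.lower(): m for m in Material}

#: nominal mass densities, g/cm^3 (used where a caller supplies no density)
DEFAULT_DENSITY = {
    Material.AIR: 0.0012,
    Material.LUNG: 0.26,
    Material.SOFT_TISSUE: 1.06,
    Material.BONE: 1.92,
    Material.WATER: 1.00,
    Material.COPPER: 8.96,
}


class EnergyRangeError(ValueError):
    """Photon energy outside the tabulated 5-150 keV range."""


@dataclass
class MaterialTable:
    """Cross-section data for one material on an ascending energy grid."""

    material: Material
    energy_keV: np.ndarray
    mu_rho: np.ndarray        # cm^2/g
    mutr_rho: np.ndarray      # cm^2/g
    f_pe: np.ndarray
    f_co: np.ndarray
    f_ra: np.ndarray
    _log_e: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.energy_keV) > 0):
            raise ValueError("energy grid must be strictly ascending")
        if self.energy_keV[0] > ENERGY_MIN_KEV or self.energy_keV[-1] < ENERGY_MAX_KEV:
            raise ValueError("energy grid must cover 5-150 keV")
        if np.any(self.mu_rho <= 0) or np.any(self.mutr_rho <= 0):
            raise ValueError("coefficients must be positive")
        s = self.f_pe + self.f_co + self.f_ra
        if np.any(np.abs(s - 1.0) > 1e-9):
            raise ValueError("interaction fractions must sum to 1")
        self._log_e = np.log(self.energy_keV)

    def _interp_loglog(self, values: np.ndarray, energy_keV):
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise EnergyRangeError(
                f"energy {energy_keV} keV outside tabulated range "
                f"[{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}]"
            )
        return np.exp(np.interp(np.log(e), self._log_e, np.log(values)))

    def mu_over_rho(self, energy_keV):
        """Mass attenuation coefficient, cm^2/g."""
        return self._interp_loglog(self.mu_rho, energy_keV)

    def mutr_over_rho(self, energy_keV):
        """Mass energy-transfer coefficient, cm^2/g."""
        return self._interp_loglog(self.mutr_rho, energy_keV)

    def fractions(self, energy_keV):
        """(photoelectric, Compton, Rayleigh) fractions, renormalized after interpolation."""
        fpe = self._interp_loglog(self.f_pe, energy_keV)
        fco = self._interp_loglog(self.f_co, energy_keV)
        fra = self._interp_loglog(self.f_ra, energy_keV)
        s = fpe + fco + fra
        return fpe / s, fco / s, fra / s


_TABLES: dict[Material, MaterialTable] | None = None


def load_material_table(material: Material | str) -> MaterialTable:
    """Return the packaged :class:`MaterialTable` for ``material``."""
    global _TABLES
    if _TABLES is None:
        path = resources.files("fluorodose.data") / "photon_xsections.csv"
        with resources.as_file(path) as p:
            df = pd.read_csv(p)
        _TABLES = {}
        for name, g in df.groupby("material", sort=False):
            mat = _NAME_TO_MATERIAL[name]
            g = g.sort_values("energy_keV")
            _TABLES[mat] = MaterialTable(
                material=mat,
                energy_keV=g["energy_keV"].to_numpy(float),
                mu_rho=g["mu_rho"].to_numpy(float),
                mutr_rho=g["mutr_rho"].to_numpy(float),
                f_pe=g["f_pe"].to_numpy(float),
                f_co=g["f_co"].to_numpy(float),
                f_ra=g["f_ra"].to_numpy(float),
            )
    if isinstance(material, str):
        material = _NAME_TO_MATERIAL[material.lower()]
    return _TABLES[Material(material)]


def attenuation_coefficient(material: Material | str, energy_keV, density_g_cm3) -> np.ndarray | float:
    """Linear attenuation coefficient mu in 1/cm.

    ``mu = (mu/rho)(E) * density``; mu/rho is log-log interpolated on the
    packaged grid.  Raises :class:`EnergyRangeError` outside 5-150 keV and
    ``ValueError`` for non-positive density.
    """
    density = np.asarray(density_g_cm3, dtype=float)
    if np.any(density <= 0):
        raise ValueError("density must be positive")
    table = load_material_table(material)
    out = table.mu_over_rho(energy_keV) * density
    if np.ndim(out) == 0:
        return float(out)
    return out


def fine_grid(step_keV: float = 0.25):
    """Dense energy grid with per-material lookup arrays for the transport kernel.

    Returns ``(energies, mu_rho[n_mat, nE], mutr_rho, f_pe, f_co, f_ra)`` with
    materials indexed by :class:`Material` value.
    """
    energies = np.arange(ENERGY_MIN_KEV, ENERGY_MAX_KEV + step_keV / 2, step_keV)
    n_mat = len(Material)
    mu = np.empty((n_mat, energies.size))
    mutr = np.empty_like(mu)
    fpe = np.empty_like(mu)
    fco = np.empty_like(mu)
    fra = np.empty_like(mu)
    for m in Material:
        t = load_material_table(m)
        mu[m] = t.mu_over_rho(energies)
        mutr[m] = t.mutr_over_rho(energies)
        fpe[m], fco[m], fra[m] = t.fractions(energies)
    return energies, mu, mutr, fpe, fco, fra
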