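"""Bundled photon interaction data: attenuation coefficients, air kerma
per fluence, and Hp(10) fluence-to-dose conversion coefficients.

All tables ship as plain-text files under :mod:`irscatter.data` (see each
file's provenance header) and are interpolated log-log between nodes,
which is the standard treatment for photon cross sections and guarantees
monotone behaviour between adjacent nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "MATERIALS",
    "CrossSectionTable",
    "cross_sections",
    "mu_total",
    "mu_partials",
    "air_kerma_per_fluence",
    "hp10_per_fluence",
    "ENERGY_MIN_KEV",
    "ENERGY_MAX_KEV",
]

#: material name -> density in g/cm^3, matching the bundled tables
MATERIALS = {
    "air": 1.20479e-3,
    "water": 1.000,
    "soft_tissue": 1.060,
    "aluminium": 2.699,
    "copper": 8.960,
    "lead": 11.35,
    "tungsten": 19.30,
}

ENERGY_MIN_KEV = 10.0
ENERGY_MAX_KEV = 150.0

KEV_TO_JOULE = 1.602176634e-16


def _load_table(name: str) -> np.ndarray:
    ref = resources.files("irscatter.data").joinpath(name)
    with ref.open("r") as fh:
        return np.loadtxt(fh)


@dataclass(frozen=True)
class CrossSectionTable:
    """Linear attenuation coefficients (1/cm) for one material.

    ``mu_total`` equals the sum of the three partial coefficients at
    every grid node by construction of the bundled tables.
    """

    material: str
    energies: np.ndarray       # keV, ascending
    mu_photoelectric: np.ndarray
    mu_compton: np.ndarray
    mu_rayleigh: np.ndarray
    mu_total: np.ndarray

    def mu(self, energy_kev, channel: str = "total") -> np.ndarray:
        """Log-log interpolated attenuation coefficient at ``energy_kev``."""
        col = getattr(self, f"mu_{channel}")
        return _loglog_interp(energy_kev, self.energies, col)


def _loglog_interp(x, xp: np.ndarray, fp: np.ndarray):
    x = np.asarray(x, dtype=float)
    if np.any(x < xp[0] - 1e-9) or np.any(x > xp[-1] + 1e-9):
        raise ValueError(
            f"energy {x} keV outside table support [{xp[0]}, {xp[-1]}] keV"
        )
    xc = np.clip(x, xp[0], xp[-1])
    out = np.exp(np.interp(np.log(xc), np.log(xp), np.log(np.maximum(fp, 1e-300))))
    return out if out.ndim else float(out)


@lru_cache(maxsize=None)
def cross_sections(material: str) -> CrossSectionTable:
    """Load (cached) the bundled cross-section table for ``material``."""
    if material not in MATERIALS:
        raise ValueError(f"unknown material {material!r}; known: {sorted(MATERIALS)}")
    raw = _load_table(f"{material}.txt")
    return CrossSectionTable(
        material=material,
        energies=raw[:, 0],
        mu_photoelectric=raw[:, 1],
        mu_compton=raw[:, 2],
        mu_rayleigh=raw[:, 3],
        mu_total=raw[:, 4],
    )


def mu_total(material: str, energy_kev):
    return cross_sections(material).mu(energy_kev, "total")


def mu_partials(material: str, energy_kev):
    """(photoelectric, compton, rayleigh) linear coefficients at energy."""
    t = cross_sections(material)
    return (
        t.mu(energy_kev, "photoelectric"),
        t.mu(energy_kev, "compton"),
        t.mu(energy_kev, "rayleigh"),
    )


@lru_cache(maxsize=1)
def _air_muen() -> np.ndarray:
    return _load_table("air_muen.txt")


@lru_cache(maxsize=1)
def _hp10_table() -> np.ndarray:
    return _load_table("hp10_slab.txt")


def air_kerma_per_fluence(energy_kev):
    """Air kerma per unit photon fluence, Gy*cm^2 per photon.

    Computed as E * (muen/rho)_air with (muen/rho) log-log interpolated
    from the bundled air table.
    """
    tab = _air_muen()
    muen = _loglog_interp(energy_kev, tab[:, 0], tab[:, 1])  # cm^2/g
    e = np.asarray(energy_kev, dtype=float)
    out = e * KEV_TO_JOULE * muen * 1e3  # cm^2/g -> cm^2/kg
    return out if out.ndim else float(out)


def hp10_per_fluence(energy_kev):
    """Hp(10) per unit fluence on the ICRU slab, pSv*cm^2, normal incidence."""
    tab = _hp10_table()
    return _loglog_interp(energy_kev, tab[:, 0], tab[:, 1])
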