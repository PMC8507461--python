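"""Regenerate the bundled photon cross-section tables in src/irscatter/data/.

Each material file tabulates linear attenuation coefficients (1/cm) on a
1 keV grid from 10 to 150 keV, split into the three interaction channels
used by the transport code:

  * photoelectric -- from Cromer-Liberman anomalous scattering factors
    (f'' via gemmi), sigma_pe = 2 r_e lambda f'';
  * incoherent (Compton) -- free-electron Klein-Nishina total cross
    section times the electron density;
  * coherent (Rayleigh) -- Thomson differential cross section weighted by
    the squared IT92 atomic form factor, integrated over solid angle.

The free-electron treatment of incoherent scattering (no incoherent
scattering function) deliberately matches the scattering kernel of the
transport code, so sampled interaction branches and tabulated partial
coefficients are mutually consistent.  Run from the repository root:

    python scripts/make_physics_tables.py
"""

from __future__ import annotations

import math
from pathlib import Path

import gemmi
import numpy as np
from scipy.integrate import quad

R_E_CM = 2.8179403262e-13  # classical electron radius, cm
N_AVOGADRO = 6.02214076e23
ELECTRON_REST_KEV = 510.99895
HC_KEV_ANGSTROM = 12.39841984  # h*c, keV * Angstrom

DATA_DIR = Path(__file__).resolve().parents[1] / "src" / "irscatter" / "data"

# material -> (density g/cm3, {element symbol: mass fraction})
MATERIALS = {
    "air": (1.20479e-3, {"C": 0.000124, "N": 0.755268, "O": 0.231781, "Ar": 0.012827}),
    "water": (1.000, {"H": 0.111894, "O": 0.888106}),
    # ICRU-44 adult soft tissue
    "soft_tissue": (1.060, {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.708,
                            "Na": 0.002, "P": 0.003, "S": 0.003, "Cl": 0.002,
                            "K": 0.003}),
    "aluminium": (2.699, {"Al": 1.0}),
    "copper": (8.960, {"Cu": 1.0}),
    "lead": (11.35, {"Pb": 1.0}),
    "tungsten": (19.30, {"W": 1.0}),
}

ENERGIES_KEV = np.arange(10, 151, 1.0)


def klein_nishina_total(energy_kev: float) -> float:
    """Total Klein-Nishina cross section per electron, cm^2."""
    a = energy_kev / ELECTRON_REST_KEV
    t1 = (1.0 + a) / a**2 * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - math.log(1.0 + 2.0 * a) / a)
    t2 = math.log(1.0 + 2.0 * a) / (2.0 * a)
    t3 = (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    return 2.0 * math.pi * R_E_CM**2 * (t1 + t2 - t3)


def sigma_photoelectric(z: int, energy_kev: float) -> float:
    """Photoabsorption cross section per atom from Cromer-Liberman f''."""
    _fp, fpp = gemmi.cromer_liberman(z=z, energy=energy_kev * 1e3)
    lam_cm = HC_KEV_ANGSTROM / energy_kev * 1e-8
    return 2.0 * R_E_CM * lam_cm * max(fpp, 0.0)


def sigma_rayleigh(symbol: str, energy_kev: float) -> float:
    """Coherent cross section per atom: Thomson kernel x |f0(q)|^2."""
    it92 = gemmi.Element(symbol).it92
    lam_a = HC_KEV_ANGSTROM / energy_kev  # Angstrom

    def integrand(theta: float) -> float:
        stol = math.sin(theta / 2.0) / lam_a
        f0 = it92.calculate_sf(stol * stol)
        return (1.0 + math.cos(theta) ** 2) * f0 * f0 * math.sin(theta)

    val, _err = quad(integrand, 0.0, math.pi, limit=200)
    return math.pi * R_E_CM**2 * val


def build_material(name: str) -> np.ndarray:
    density, fractions = MATERIALS[name]
    rows = np.zeros((len(ENERGIES_KEV), 5))
    rows[:, 0] = ENERGIES_KEV
    for symbol, w in fractions.items():
        el = gemmi.Element(symbol)
        atoms_per_cm3 = density * w * N_AVOGADRO / el.weight
        electrons_per_cm3 = atoms_per_cm3 * el.atomic_number
        for i, e in enumerate(ENERGIES_KEV):
            rows[i, 1] += atoms_per_cm3 * sigma_photoelectric(el.atomic_number, e)
            rows[i, 2] += electrons_per_cm3 * klein_nishina_total(e)
            rows[i, 3] += atoms_per_cm3 * sigma_rayleigh(symbol, e)
    rows[:, 4] = rows[:, 1:4].sum(axis=1)
    return rows


def main() -> None:
    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for name in MATERIALS:
        density = MATERIALS[name][0]
        rows = build_material(name)
        header = (
            f"# Linear attenuation coefficients for {name} (density {density} g/cm^3)\n"
            "# Photoelectric: Cromer-Liberman f'' (gemmi); incoherent: free-electron\n"
            "# Klein-Nishina; coherent: Thomson x IT92 form factor.\n"
            "# Regenerate with scripts/make_physics_tables.py\n"
            "# E_keV mu_pe mu_compton mu_rayleigh mu_total  (mu in 1/cm)\n"
        )
        path = DATA_DIR / f"{name}.txt"
        with open(path, "w") as fh:
            fh.write(header)
            for r in rows:
                fh.write(f"{r[0]:.1f} {r[1]:.6e} {r[2]:.6e} {r[3]:.6e} {r[4]:.6e}\n")
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
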