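"""Tungsten-anode x-ray spectra: a semi-empirical Birch-Marshall-type
bremsstrahlung model with K-characteristic lines.

The model integrates Kramers-type production over electron penetration
depth (Thomson-Whiddington slowing-down), attenuates each depth element
through the anode self-filtration path set by the anode angle, and then
hardens the emerging spectrum with inherent plus added filtration.  It is
a relative spectrum: absolute output never matters downstream because
every simulated dose is re-normalised to the machine-reported kerma-area
product (or reference-point air kerma) of the irradiation event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .physics import (
    ENERGY_MIN_KEV,
    air_kerma_per_fluence,
    cross_sections,
)

__all__ = ["Spectrum", "generate_spectrum", "attenuate", "first_hvl_mm_al"]

W_K_EDGE_KEV = 69.525
# K-line energies (keV) and relative emission intensities for tungsten
W_K_LINES = ((59.32, 1.00), (57.98, 0.573), (67.24, 0.332), (69.07, 0.088))
# Thomson-Whiddington constant, keV^2 cm^2/g
C_TW = 7.85e5
# semi-empirical K-line yield relative to the unfiltered continuum
K_LINE_YIELD = 0.35


@dataclass
class Spectrum:
    """Binned relative photon-fluence spectrum.

    ``energy_edges`` are ascending with uniform width; ``weights[i]`` is
    the relative photon fluence in ``[edges[i], edges[i+1])``.
    """

    energy_edges: np.ndarray
    weights: np.ndarray
    kvp: float

    def __post_init__(self) -> None:
        self.energy_edges = np.asarray(self.energy_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.energy_edges.ndim != 1 or len(self.energy_edges) != len(self.weights) + 1:
            raise ValueError("energy_edges must have len(weights)+1 entries")
        widths = np.diff(self.energy_edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("energy_edges must be ascending with uniform width")
        if np.any(self.weights < 0):
            raise ValueError("negative spectrum weight")
        if not np.any(self.weights > 0):
            raise ValueError("spectrum has no positive bin")
        above = self.energy_edges[:-1] >= self.kvp
        if np.any(self.weights[above] > 0):
            raise ValueError("positive weight above the tube voltage")

    @property
    def energy_mid(self) -> np.ndarray:
        return 0.5 * (self.energy_edges[:-1] + self.energy_edges[1:])

    @property
    def total_fluence(self) -> float:
        return float(self.weights.sum())

    def mean_energy(self) -> float:
        return float(np.average(self.energy_mid, weights=self.weights))

    def normalized(self) -> "Spectrum":
        """Unit total fluence."""
        return Spectrum(self.energy_edges.copy(), self.weights / self.total_fluence, self.kvp)

    def low_energy_fraction(self, below_kev: float = 30.0) -> float:
        sel = self.energy_mid < below_kev
        return float(self.weights[sel].sum() / self.total_fluence)


def generate_spectrum(
    kvp: float,
    filtration_cu: float = 0.0,
    filtration_al: float = 0.0,
    anode_angle: float = 12.0,
    bin_width: float = 1.0,
    inherent_al: float = 2.5,
    inherent_cu: float = 0.1,
    normalize: bool = False,
) -> Spectrum:
    """Generate a filtered tungsten spectrum for the given technique.

    Parameters
    ----------
    kvp:
        Tube voltage, 40-150 kV.
    filtration_cu, filtration_al:
        Added filtration in mm of copper / aluminium.
    anode_angle:
        Target angle in degrees; sets the anode self-filtration path.
    bin_width:
        Bin width in keV, 0.5-2.
    inherent_al, inherent_cu:
        Inherent tube filtration (mm Al / mm Cu equivalent); defaults
        represent a modern flat-panel angiography tube and are
        configuration-overridable.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kvp {kvp} outside the supported 40-150 kV range")
    if filtration_cu < 0 or filtration_al < 0:
        raise ValueError("negative filtration")
    if not 0.5 <= bin_width <= 2.0:
        raise ValueError("bin_width must lie in [0.5, 2] keV")

    n_bins = int(math.ceil((kvp - ENERGY_MIN_KEV) / bin_width))
    edges = ENERGY_MIN_KEV + bin_width * np.arange(n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])

    mu_w = cross_sections("tungsten")
    rho_w = 19.30
    sec_path = 1.0 / math.tan(math.radians(anode_angle))

    # Kramers production integrated over Thomson-Whiddington depth, with
    # anode self-attenuation of the photons produced at each depth.
    weights = np.zeros(n_bins)
    n_depth = 64
    for i, e in enumerate(mid):
        if e >= kvp:
            continue
        xi_max = (kvp**2 - e**2) / C_TW  # g/cm^2
        xi = np.linspace(0.0, xi_max, n_depth + 1)
        t_e = np.sqrt(np.maximum(kvp**2 - C_TW * xi, 0.0))
        prod = np.maximum(t_e - e, 0.0) / e
        atten = np.exp(-mu_w.mu(e) / rho_w * xi * sec_path)
        weights[i] = np.trapezoid(prod * atten, xi)

    continuum_total = weights.sum()

    # tungsten K lines for voltages above the K edge
    if kvp > W_K_EDGE_KEV and continuum_total > 0:
        yield_scale = K_LINE_YIELD * (kvp / W_K_EDGE_KEV - 1.0) ** 1.65
        rel_sum = sum(r for _, r in W_K_LINES)
        for e_line, rel in W_K_LINES:
            if e_line >= kvp:
                continue
            j = int((e_line - ENERGY_MIN_KEV) // bin_width)
            weights[j] += continuum_total * yield_scale * rel / rel_sum

    s = Spectrum(edges, weights, kvp=float(kvp))
    for material, mm in (
        ("aluminium", inherent_al + filtration_al),
        ("copper", inherent_cu + filtration_cu),
    ):
        if mm > 0:
            s = attenuate(s, material, mm / 10.0)
    return s.normalized() if normalize else s


def attenuate(s: Spectrum, material: str, thickness_cm: float) -> Spectrum:
    """Exponentially attenuate each bin through ``thickness_cm`` of material."""
    if thickness_cm < 0:
        raise ValueError("negative thickness")
    mu = cross_sections(material).mu(s.energy_mid)
    return Spectrum(s.energy_edges.copy(), s.weights * np.exp(-mu * thickness_cm), s.kvp)


def first_hvl_mm_al(s: Spectrum) -> float:
    """First half-value layer in mm Al, by bisection on air-kerma transmission.

    The HVL is defined on air kerma, so each bin is weighted by the air
    kerma per fluence at its midpoint energy.
    """
    kerma_w = air_kerma_per_fluence(s.energy_mid) * s.weights
    k0 = kerma_w.sum()
    mu_al = cross_sections("aluminium").mu(s.energy_mid)

    def transmission(t_mm: float) -> float:
        return float((kerma_w * np.exp(-mu_al * t_mm / 10.0)).sum()) / k0

    lo, hi = 0.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if transmission(mid) > 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
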