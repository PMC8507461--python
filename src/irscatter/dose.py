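"""Fluence-to-Hp(10) conversion and per-event normalisation.

The simulated tallies are relative (per source photon).  Absolute doses
come from normalising by the machine-reported output of the irradiation
event: either the kerma-area product PKA (Gy*cm^2) or the air kerma at
the interventional reference point Kair (mGy), whichever mode is chosen.
The measured-output normalisation carries a 10% (k=2) uncertainty,
established by independent detector checks of the machine-reported
values; it is combined in quadrature with the Monte-Carlo statistical
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .events import IrradiationEvent
from .physics import hp10_per_fluence
from .transport import FluenceTally

__all__ = [
    "EventDose",
    "hp10_per_fluence",
    "fluence_to_hp10",
    "normalize_event",
    "combine_uncertainty",
    "U_NORM_REL",
]

#: relative expanded (k=2) uncertainty of the machine-reported output
U_NORM_REL = 0.10


@dataclass
class EventDose:
    """Absolute Hp(10) of one event at one detector point."""

    event_id: str
    point_id: str
    hp10_uSv: float
    u_stat_uSv: float            # 1-sigma Monte-Carlo statistical error
    u_norm_rel: float = U_NORM_REL  # relative, expanded (k=2)
    position_used: Optional[tuple] = None
    movement_corrected: bool = False

    def __post_init__(self) -> None:
        if self.hp10_uSv < 0 or self.u_stat_uSv < 0:
            raise ValueError("dose and statistical uncertainty must be >= 0")


def fluence_to_hp10(tally: FluenceTally, point_id: str) -> tuple[float, float]:
    """Hp(10) per source photon (pSv) and its 1-sigma statistical error.

    Sum over tally bins of fluence times the slab conversion coefficient
    at the bin midpoint, with the variance propagated bin-wise.
    """
    flu = tally.fluence_per_photon(point_id)
    var = tally.var_of_mean(point_id)
    mids = 0.5 * (tally.energy_edges[:-1] + tally.energy_edges[1:])
    h = hp10_per_fluence(np.clip(mids, 10.0, 150.0))
    hp = float((flu * h).sum())
    u = float(math.sqrt((h**2 * var).sum()))
    return hp, u


def normalize_event(
    hp10_rel_pSv: float,
    u_stat_rel_pSv: float,
    tally: FluenceTally,
    event: IrradiationEvent,
    point_id: str,
    mode: str = "pka",
    position_used: Optional[tuple] = None,
    movement_corrected: bool = False,
) -> EventDose:
    """Scale the per-photon Hp(10) to absolute microsievert using the
    event's machine-reported output.

    ``mode='pka'`` uses hp10_abs = hp10_rel * PKA_event / PKA_simulated;
    ``mode='kair'`` the analogous ratio of reference-point air kermas.
    An event with zero reported output yields zero dose.
    """
    if mode == "pka":
        sim, reported = tally.simulated_pka, event.p_ka
    elif mode == "kair":
        sim, reported = tally.simulated_kair_mGy, event.k_air_ref
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if sim <= 0.0:
        raise ValueError(f"simulated normalisation quantity is zero (mode {mode})")
    scale = reported / sim * 1e-6  # pSv -> uSv
    return EventDose(
        event_id=event.event_id,
        point_id=point_id,
        hp10_uSv=hp10_rel_pSv * scale,
        u_stat_uSv=u_stat_rel_pSv * scale,
        position_used=position_used,
        movement_corrected=movement_corrected,
    )


def combine_uncertainty(d: EventDose) -> float:
    """Expanded uncertainty U (k=2) in uSv: MC statistics and the output
    normalisation term combined in quadrature."""
    if d.hp10_uSv == 0.0:
        return 0.0
    rel_stat = d.u_stat_uSv / d.hp10_uSv
    return 2.0 * d.hp10_uSv * math.sqrt(rel_stat**2 + (d.u_norm_rel / 2.0) ** 2)
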