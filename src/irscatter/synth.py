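"""Synthetic procedures emulating the four study conditions (A-D): event
logs, operator traces and room configurations, generated entirely from
code so that every pipeline stage is testable without clinical data.

Profile envelopes (event counts, kVp and copper-filtration sets, field
sizes, angulation ranges, total PKA / Kair, treatment span, shield use)
reproduce the published per-case technique summaries: a single-event
experimental exposure (A), a long abdominal procedure with a ceiling
shield and an operator who steps away during one acquisition (B), a
short extremity procedure with the operator close to the table (C), and
a long renal procedure with a wandering operator (D).  Operator scripts
are deterministic waypoint paths plus seeded Gaussian jitter (sigma 3 cm)
emulating tracking noise, sampled at 5 Hz with dropout gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .events import IrradiationEvent, ProcedureLog, write_events
from .geometry import RoomModel, default_room, save_room
from .tracking import PositionTrace, write_trace
from .transport import DetectorPoint

__all__ = [
    "CaseProfile", "CASE_PROFILES", "generate_case",
    "generate_movement_event", "write_case_dir", "DEFAULT_POINT_OFFSETS",
]

TRACE_HZ = 5.0
JITTER_SIGMA_M = 0.03
#: operator trunk reference when "close to the patient": ~0.7 m lateral
#: of the isocenter, at chest height
NEAR_TABLE_POS = (0.70, -0.20, 0.45)
AWAY_POS = (1.80, -0.60, 0.45)
OUT_OF_ROOM_POS = (3.50, -2.50, 0.45)

#: dosemeter points as offsets from the tracked trunk reference
DEFAULT_POINT_OFFSETS = [
    DetectorPoint("chest", (0.0, 0.0, 0.0), "trunk dosemeter, chest height"),
    DetectorPoint("collar", (0.0, 0.0, 0.25), "collar dosemeter"),
]


@dataclass(frozen=True)
class CaseProfile:
    name: str
    n_events: int
    n_acquisitions: int
    kvp_range: tuple
    filtration_set: tuple          # mm Cu choices
    field_range: tuple             # cm^2
    angulation_range: tuple        # degrees, +RAO/-LAO
    total_pka: float               # Gy*cm^2
    total_kair: float              # mGy
    duration_s: float
    shield: bool
    operator_script: str           # static_near | moves_away_once | walks_and_leaves

    def __post_init__(self) -> None:
        if self.n_acquisitions > self.n_events:
            raise ValueError("n_acquisitions cannot exceed n_events")
        if self.n_events == 0 and self.total_pka > 0:
            raise ValueError("infeasible profile: output without events")


CASE_PROFILES = {
    "A": CaseProfile("A", 1, 0, (79.0, 79.0), (0.3,), (835.0, 835.0), (0.0, 0.0),
                     4.1, 17.6, 120.0, False, "static_near"),
    "B": CaseProfile("B", 115, 17, (70.0, 86.0), (0.1, 0.2, 0.3, 0.6, 0.9),
                     (457.0, 1091.0), (0.0, 38.0), 163.0, 679.0, 8640.0, True,
                     "moves_away_once"),
    "C": CaseProfile("C", 19, 7, (66.0, 82.0), (0.3, 0.6, 0.9), (325.0, 825.0),
                     (0.0, 0.0), 0.06, 0.3, 780.0, False, "static_near"),
    "D": CaseProfile("D", 186, 10, (68.0, 85.0), (0.2, 0.3, 0.6, 0.9), (54.0, 630.0),
                     (-35.0, 26.0), 10.5, 200.0, 8040.0, True, "walks_and_leaves"),
}

#: share of the total output delivered by image acquisitions (the high
#: dose-rate runs), with the remainder spread over fluoroscopy
ACQUISITION_OUTPUT_SHARE = 0.6


def _draw_pka(rng: np.random.Generator, n: int, total: float) -> np.ndarray:
    """Log-normal shares rescaled to the exact total."""
    if n == 0 or total == 0.0:
        return np.zeros(n)
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    return raw / raw.sum() * total


def generate_case(profile: CaseProfile, seed: int = 0,
                  ) -> tuple[ProcedureLog, PositionTrace, RoomModel]:
    """Realise one synthetic procedure from a case profile.

    Event technique factors are drawn uniformly within the profile
    envelope; per-event PKA follows a log-normal shape rescaled so the
    procedure total matches the profile exactly; Kair scales with PKA.
    Regeneration with the same seed is byte-identical.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    t0 = 1_600_000_000.0
    n = profile.n_events
    n_acq = profile.n_acquisitions
    n_fluoro = n - n_acq

    # interleave acquisitions among the fluoroscopy runs
    types = np.array(["fluoroscopy"] * n, dtype=object)
    if n_acq:
        acq_idx = np.linspace(0, n - 1, n_acq).round().astype(int)
        types[acq_idx] = "acquisition"

    pka = np.zeros(n)
    if n:
        is_acq = types == "acquisition"
        pka[is_acq] = _draw_pka(rng, int(is_acq.sum()),
                                profile.total_pka * (ACQUISITION_OUTPUT_SHARE if n_fluoro else 1.0))
        pka[~is_acq] = _draw_pka(rng, int((~is_acq).sum()),
                                 profile.total_pka * ((1 - ACQUISITION_OUTPUT_SHARE) if n_acq else 1.0))
    kair = pka * (profile.total_kair / profile.total_pka) if profile.total_pka else np.zeros(n)

    durations = np.where(types == "acquisition",
                         rng.uniform(3.0, 10.0, n),
                         rng.uniform(5.0, 60.0, n))
    # spread event starts over the treatment span, keeping them disjoint
    total_beam = durations.sum()
    slack = max(profile.duration_s - total_beam, 60.0)
    gaps = rng.dirichlet(np.ones(n)) * slack if n else np.array([])
    starts = t0 + np.cumsum(gaps) + np.concatenate([[0.0], np.cumsum(durations)[:-1]]) if n else np.array([])

    events = []
    for i in range(n):
        events.append(IrradiationEvent(
            event_id=f"{profile.name}{i + 1:04d}",
            t_start=round(float(starts[i]), 3),
            duration=round(float(durations[i]), 3),
            event_type=str(types[i]),
            kvp=round(float(rng.uniform(*profile.kvp_range)), 1),
            filtration_cu=float(rng.choice(profile.filtration_set)),
            ang_primary=round(float(rng.uniform(*profile.angulation_range)), 1),
            ang_secondary=0.0,
            field_area=round(float(rng.uniform(*profile.field_range)), 1),
            p_ka=float(pka[i]),
            k_air_ref=float(kair[i]),
        ).validate())
    log = ProcedureLog(events=events, source_format="csv")

    trace = _operator_trace(profile, rng, t0, events)
    room = default_room(shield=profile.shield)
    return log, trace, room


def _operator_trace(profile: CaseProfile, rng: np.random.Generator,
                    t0: float, events: list) -> PositionTrace:
    span = profile.duration_s + 120.0
    t = t0 - 30.0 + np.arange(int(span * TRACE_HZ)) / TRACE_HZ
    base = np.tile(np.asarray(NEAR_TABLE_POS), (len(t), 1))

    if profile.operator_script == "moves_away_once" and events:
        # step back for one mid-procedure acquisition, then return
        acq = [e for e in events if e.event_type == "acquisition"]
        anchor = acq[len(acq) // 2] if acq else events[len(events) // 2]
        t_go = anchor.t_start
        t_back = anchor.t_start + max(anchor.duration, 7.0) + 20.0
        away = np.asarray(AWAY_POS)
        frac = np.clip((t - t_go) / max(anchor.duration, 7.0), 0.0, 1.0)
        moving = (t >= t_go) & (t < t_back)
        base[moving] = (np.asarray(NEAR_TABLE_POS)[None]
                        + frac[moving, None] * (away - np.asarray(NEAR_TABLE_POS))[None])
    elif profile.operator_script == "walks_and_leaves" and events:
        # wander alongside the patient, leave the room twice
        y_walk = 0.35 * np.sin(2 * np.pi * (t - t[0]) / 600.0)
        base[:, 1] += y_walk
        for k in (1, 2):
            t_leave = t0 + k * profile.duration_s / 3.0
            gone = (t >= t_leave) & (t < t_leave + 90.0)
            base[gone] = np.asarray(OUT_OF_ROOM_POS)

    xyz = base + rng.normal(0.0, JITTER_SIGMA_M, base.shape)
    valid = np.ones(len(t), dtype=bool)
    # camera dropout gaps (~1% of samples, short bursts)
    n_gaps = max(1, len(t) // 3000)
    for _ in range(n_gaps):
        g0 = rng.integers(0, max(len(t) - 10, 1))
        valid[g0:g0 + rng.integers(3, 10)] = False
    return PositionTrace(t=t, xyz=xyz, valid=valid, sample_rate_hz=TRACE_HZ)


def generate_movement_event(
    distance_start_m: float = 0.70,
    distance_end_m: float = 1.50,
    duration_s: float = 7.0,
    n_frames: int = 7,
    p_ka: float = 1.0,
    kvp: float = 80.0,
    t_start: float = 1_600_000_000.0,
) -> tuple[IrradiationEvent, PositionTrace]:
    """A long image acquisition during which the operator recedes
    monotonically from ``distance_start_m`` to ``distance_end_m``
    (lateral distance from the isocenter), one trace sample per frame."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    event = IrradiationEvent(
        event_id="move0001", t_start=t_start, duration=duration_s,
        event_type="acquisition", kvp=kvp, filtration_cu=0.3,
        field_area=600.0, p_ka=p_ka, k_air_ref=p_ka * 4.0,
    ).validate()
    times = t_start + np.arange(n_frames) * (duration_s / n_frames)
    dist = np.linspace(distance_start_m, distance_end_m, n_frames)
    xyz = np.column_stack([
        dist,
        np.full(n_frames, NEAR_TABLE_POS[1]),
        np.full(n_frames, NEAR_TABLE_POS[2]),
    ])
    trace = PositionTrace(t=times, xyz=xyz, valid=np.ones(n_frames, bool),
                          sample_rate_hz=n_frames / duration_s)
    return event, trace


def write_case_dir(case: str, seed: int, out_dir) -> Path:
    """Materialise a synthetic case as events.csv, trace.csv, room.yaml
    and points.csv under ``out_dir``."""
    profile = CASE_PROFILES[case]
    log, trace, room = generate_case(profile, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_events(log, out / "events.csv", "csv")
    write_trace(trace, out / "trace.csv")
    save_room(room, out / "room.yaml")
    import csv
    with open(out / "points.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["point_id", "x", "y", "z", "label"])
        for p in DEFAULT_POINT_OFFSETS:
            w.writerow([p.point_id, *p.position, p.label])
    return out
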