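"""Operator position traces and their synchronisation with irradiation
events.

The tracking convention follows the fixed-at-start rule: the operator's
position is frozen at the latest valid sample at or before the start of
each irradiation event (hold-last-value, no interpolation), on the
assumption that the operator does not move during the event.  For long
image acquisitions during which the operator demonstrably walks away, an
event can be subdivided into equal-duration frames, each taking the
trace position at its own start and an equal share of the event's
kerma-area product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .events import IrradiationEvent

__all__ = [
    "PositionTrace",
    "PositionUnknown",
    "load_trace",
    "write_trace",
    "position_at_event_start",
    "subdivide_event",
]

DEFAULT_MAX_GAP_S = 5.0


class PositionUnknown(Exception):
    """No valid trace sample within the allowed gap of an event start."""


@dataclass
class PositionTrace:
    """Timestamped operator positions in the room frame (metres)."""

    t: np.ndarray          # epoch seconds, strictly increasing
    xyz: np.ndarray        # [n, 3]
    valid: np.ndarray      # bool per sample
    sample_rate_hz: float = 5.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.t) == 0:
            raise ValueError("empty position trace")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 2  # 1-based row of the offender
            raise ValueError(f"non-increasing timestamp at trace row {row}")
        if not np.all(np.isfinite(self.xyz[self.valid])):
            raise ValueError("non-finite position in a sample flagged valid")

    def __len__(self) -> int:
        return len(self.t)


def load_trace(path) -> PositionTrace:
    """Read a trace CSV with columns ``t,x,y,z[,valid]``."""
    df = pd.read_csv(Path(path))
    needed = {"t", "x", "y", "z"} - set(df.columns)
    if needed:
        raise ValueError(f"{path}: missing trace columns {sorted(needed)}")
    valid = df["valid"].astype(bool).to_numpy() if "valid" in df.columns \
        else np.ones(len(df), dtype=bool)
    return PositionTrace(
        t=df["t"].to_numpy(float),
        xyz=df[["x", "y", "z"]].to_numpy(float),
        valid=valid,
    )


def write_trace(trace: PositionTrace, path) -> Path:
    df = pd.DataFrame({
        "t": trace.t,
        "x": trace.xyz[:, 0], "y": trace.xyz[:, 1], "z": trace.xyz[:, 2],
        "valid": trace.valid.astype(int),
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def position_at_event_start(
    trace: PositionTrace,
    event: IrradiationEvent,
    clock_offset: float = 0.0,
    max_gap: float = DEFAULT_MAX_GAP_S,
) -> np.ndarray:
    """Operator position frozen at the event start: the latest valid
    sample at or before ``t_start + clock_offset``.

    Raises :class:`PositionUnknown` when the nearest valid sample is more
    than ``max_gap`` seconds old (tracking dropout) or none exists; such
    events contribute no dose and are counted in the report.
    """
    t_ev = event.t_start + clock_offset
    idx = np.searchsorted(trace.t, t_ev, side="right") - 1
    while idx >= 0 and not trace.valid[idx]:
        idx -= 1
    if idx < 0 or t_ev - trace.t[idx] > max_gap:
        raise PositionUnknown(
            f"event {event.event_id!r}: no valid trace sample within "
            f"{max_gap} s before t={t_ev:.3f}"
        )
    return trace.xyz[idx].copy()


def subdivide_event(
    event: IrradiationEvent,
    trace: PositionTrace,
    n_frames: int,
    clock_offset: float = 0.0,
    max_gap: float = DEFAULT_MAX_GAP_S,
) -> list[tuple[IrradiationEvent, np.ndarray]]:
    """Split an event into ``n_frames`` equal-duration sub-events, each
    with ``p_ka`` (and ``k_air_ref``) apportioned uniformly and the trace
    position held from its own start.

    Returns ``[(sub_event, position), ...]``; sub-event durations sum to
    the parent duration and the output quantities sum exactly to the
    parent values.  When the trace cannot supply positions for all
    frames the split falls back to the largest feasible frame count,
    with a warning.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if event.duration <= 0:
        raise ValueError("cannot subdivide a zero-duration event")

    while n_frames >= 1:
        frame_dt = event.duration / n_frames
        out = []
        try:
            for k in range(n_frames):
                sub = replace(
                    event,
                    event_id=f"{event.event_id}#f{k}",
                    t_start=event.t_start + k * frame_dt,
                    duration=frame_dt,
                    p_ka=event.p_ka / n_frames,
                    k_air_ref=event.k_air_ref / n_frames,
                )
                pos = position_at_event_start(trace, sub, clock_offset, max_gap)
                out.append((sub, pos))
            return out
        except PositionUnknown:
            if n_frames == 1:
                raise
            n_frames -= 1
            warnings.warn(
                f"event {event.event_id!r}: trace cannot cover all frames; "
                f"falling back to {n_frames}", stacklevel=2,
            )
    raise AssertionError("unreachable")
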