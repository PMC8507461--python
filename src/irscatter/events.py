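"""Irradiation-event logs: the per-event exposure record of a fluoroscopy
guided procedure.

One :class:`IrradiationEvent` corresponds to one continuous fluoroscopy
run or image acquisition with fixed technique factors, as logged by the
machine's radiation dose structured report (RDSR).  Events can be read
from a DICOM RDSR or from the package's documented CSV/JSON dialect
(identical field names; see ``CSV_COLUMNS``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "IrradiationEvent",
    "ProcedureLog",
    "ValidationError",
    "parse_events",
    "write_events",
    "summarize",
    "CSV_COLUMNS",
]

CSV_COLUMNS = [
    "event_id", "t_start", "duration", "event_type", "kvp",
    "filtration_cu", "filtration_al", "ang_primary", "ang_secondary",
    "field_area", "p_ka", "k_air_ref", "table_height",
]

EVENT_TYPES = ("fluoroscopy", "acquisition")


class ValidationError(ValueError):
    """An event field violating its typed invariant."""


@dataclass(frozen=True)
class IrradiationEvent:
    """One irradiation event.

    Units: ``t_start`` epoch seconds (ms resolution), ``duration`` s,
    ``kvp`` kV, filtrations mm, angulations degrees (+RAO / -LAO primary,
    cranio-caudal secondary), ``field_area`` cm^2 at the image-receptor
    plane, ``p_ka`` Gy*cm^2, ``k_air_ref`` mGy at the interventional
    reference point, ``table_height`` cm.
    """

    event_id: str
    t_start: float
    duration: float
    event_type: str
    kvp: float
    filtration_cu: float
    p_ka: float
    k_air_ref: float
    field_area: float
    ang_primary: float = 0.0
    ang_secondary: float = 0.0
    filtration_al: float = 0.0
    table_height: Optional[float] = None

    def validate(self) -> "IrradiationEvent":
        checks = [
            ("duration", self.duration >= 0, "must be >= 0"),
            ("kvp", 40.0 <= self.kvp <= 150.0, "must lie in [40, 150] kV"),
            ("filtration_cu", self.filtration_cu >= 0, "must be >= 0"),
            ("filtration_al", self.filtration_al >= 0, "must be >= 0"),
            ("field_area", self.field_area > 0, "must be > 0"),
            ("p_ka", self.p_ka >= 0, "must be >= 0"),
            ("k_air_ref", self.k_air_ref >= 0, "must be >= 0"),
            ("event_type", self.event_type in EVENT_TYPES,
             f"must be one of {EVENT_TYPES}"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ValidationError(
                    f"event {self.event_id!r}: field {name!r} "
                    f"(value {getattr(self, name)!r}) {msg}"
                )
        return self


@dataclass
class ProcedureLog:
    """An ordered, validated collection of irradiation events."""

    events: list[IrradiationEvent]
    source_format: str = "csv"
    clock_offset: float = 0.0

    def __post_init__(self) -> None:
        ids = [e.event_id for e in self.events]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate event_ids: {dupes}")
        # stable sort: t_start, ties broken lexicographically by event_id
        self.events = sorted(self.events, key=lambda e: (e.t_start, e.event_id))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def total_pka(self) -> float:
        return sum(e.p_ka for e in self.events)

    def total_kair(self) -> float:
        return sum(e.k_air_ref for e in self.events)


def _event_from_record(rec: dict) -> IrradiationEvent:
    def opt_float(key, default=None):
        v = rec.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
            return default
        return float(v)

    ev = IrradiationEvent(
        event_id=str(rec["event_id"]),
        t_start=float(rec["t_start"]),
        duration=float(rec["duration"]),
        event_type=str(rec["event_type"]),
        kvp=float(rec["kvp"]),
        filtration_cu=float(rec["filtration_cu"]),
        filtration_al=opt_float("filtration_al", 0.0),
        ang_primary=opt_float("ang_primary", 0.0),
        ang_secondary=opt_float("ang_secondary", 0.0),
        field_area=float(rec["field_area"]),
        p_ka=float(rec["p_ka"]),
        k_air_ref=float(rec["k_air_ref"]),
        table_height=opt_float("table_height"),
    )
    return ev.validate()


def parse_events(path, dialect: str = "csv") -> ProcedureLog:
    """Read an irradiation-event log.

    ``dialect`` is one of ``csv``, ``json`` or ``rdsr_dicom``.  Every
    mandatory field must be present; optional fields fall back to the
    documented defaults.  Events failing an invariant raise
    :class:`ValidationError` naming the event and the field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{path}: not a parseable event CSV") from exc
        missing = {"event_id", "t_start", "duration", "event_type", "kvp",
                   "filtration_cu", "field_area", "p_ka", "k_air_ref"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing mandatory columns {sorted(missing)}")
        events = [_event_from_record(rec) for rec in df.to_dict("records")]
    elif dialect == "json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path}: JSON dialect expects an array of event objects")
        events = [_event_from_record(rec) for rec in records]
    elif dialect == "rdsr_dicom":
        from .rdsr import read_rdsr_events
        events = [e.validate() for e in read_rdsr_events(path)]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return ProcedureLog(events=events, source_format=dialect)


def write_events(log: ProcedureLog, path, dialect: str = "csv") -> Path:
    """Write a log so that ``parse_events(write_events(log))`` round-trips
    field-for-field.  The DICOM dialect is read-only."""
    path = Path(path)
    records = []
    for e in log.events:
        d = asdict(e)
        records.append({k: d[k] for k in CSV_COLUMNS})
    if dialect == "csv":
        # stdlib writer with repr floats: exact round-trip precision
        import csv as _csv
        with open(path, "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(CSV_COLUMNS)
            for rec in records:
                w.writerow(["" if v is None else (repr(float(v)) if isinstance(v, float) else v)
                            for v in (rec[k] for k in CSV_COLUMNS)])
    elif dialect == "json":
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"cannot write dialect {dialect!r}")
    return path


def summarize(log: ProcedureLog) -> pd.DataFrame:
    """Per-procedure technique summary: min-max of the technique factors,
    totals of the output quantities, counts by event type."""
    rows = []
    if log.events:
        df = pd.DataFrame([asdict(e) for e in log.events])
        for col in ("kvp", "filtration_cu", "field_area", "ang_primary", "ang_secondary"):
            rows.append((col, df[col].min(), df[col].max()))
        rows.append(("p_ka_total", df["p_ka"].sum(), df["p_ka"].sum()))
        rows.append(("k_air_ref_total", df["k_air_ref"].sum(), df["k_air_ref"].sum()))
        counts = df["event_type"].value_counts()
        for etype in EVENT_TYPES:
            n = int(counts.get(etype, 0))
            rows.append((f"n_{etype}", n, n))
    rows.append(("n_events", len(log.events), len(log.events)))
    return pd.DataFrame(rows, columns=["quantity", "min", "max"]).set_index("quantity")
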