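"""Reading projection X-ray irradiation events from a DICOM Radiation
Dose Structured Report (RDSR).

The reader walks the SR content tree, collects every container coded
"Irradiation Event X-Ray Data" and maps its numeric content items onto
:class:`~irscatter.events.IrradiationEvent` fields.  Unit conversions are
fixed here, at the boundary: DICOM reports dose-area product in Gy*m^2
(-> Gy*cm^2), collimated field area in m^2 (-> cm^2) and dose at the
reference point in Gy (-> mGy).  Content items are recognised by their
standard DCM code meanings, which vendor RDSRs carry verbatim.
"""

from __future__ import annotations

from datetime import datetime, timezone
from pathlib import Path

import pydicom

from .events import IrradiationEvent

__all__ = ["read_rdsr_events"]


def _walk_containers(items, meaning: str):
    for item in items:
        name = getattr(item, "ConceptNameCodeSequence", None)
        if name and name[0].CodeMeaning == meaning:
            yield item
        if hasattr(item, "ContentSequence"):
            yield from _walk_containers(item.ContentSequence, meaning)


def _numeric(item) -> float:
    return float(item.MeasuredValueSequence[0].NumericValue)


def _parse_dt(value: str) -> float:
    """DICOM DT string -> epoch seconds (UTC assumed when no offset given)."""
    base = str(value)
    fmt = "%Y%m%d%H%M%S.%f" if "." in base else "%Y%m%d%H%M%S"
    dt = datetime.strptime(base, fmt).replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _extract_event(container, index: int) -> IrradiationEvent:
    fields: dict = {
        "event_id": f"event_{index:04d}",
        "t_start": 0.0,
        "duration": 0.0,
        "event_type": "fluoroscopy",
        "kvp": 80.0,
        "filtration_cu": 0.0,
        "filtration_al": 0.0,
        "ang_primary": 0.0,
        "ang_secondary": 0.0,
        "field_area": 100.0,
        "p_ka": 0.0,
        "k_air_ref": 0.0,
    }
    filter_material = None

    def walk(items):
        nonlocal filter_material
        for item in items:
            name_seq = getattr(item, "ConceptNameCodeSequence", None)
            meaning = name_seq[0].CodeMeaning if name_seq else ""
            if meaning == "DateTime Started":
                fields["t_start"] = _parse_dt(item.DateTime)
            elif meaning == "Irradiation Duration":
                fields["duration"] = _numeric(item)
            elif meaning == "Irradiation Event Type":
                coded = item.ConceptCodeSequence[0].CodeMeaning.lower()
                fields["event_type"] = (
                    "acquisition" if "acquisition" in coded or "stationary" in coded
                    else "fluoroscopy"
                )
            elif meaning == "KVP":
                fields["kvp"] = _numeric(item)
            elif meaning == "Positioner Primary Angle":
                fields["ang_primary"] = _numeric(item)
            elif meaning == "Positioner Secondary Angle":
                fields["ang_secondary"] = _numeric(item)
            elif meaning == "Collimated Field Area":
                fields["field_area"] = _numeric(item) * 1e4  # m^2 -> cm^2
            elif meaning == "Dose Area Product":
                fields["p_ka"] = _numeric(item) * 1e4  # Gy*m^2 -> Gy*cm^2
            elif meaning == "Dose (RP)":
                fields["k_air_ref"] = _numeric(item) * 1e3  # Gy -> mGy
            elif meaning == "Irradiation Event UID":
                fields["event_id"] = str(item.UID)
            elif meaning == "Filter Material":
                filter_material = item.ConceptCodeSequence[0].CodeMeaning.lower()
            elif meaning in ("Filter Thickness Minimum", "Filter Thickness Maximum"):
                key = "filtration_cu" if (filter_material or "").startswith("cop") \
                    else "filtration_al"
                # min and max arrive as separate items; keep their mean
                fields[key] = 0.5 * fields[key] + 0.5 * _numeric(item) \
                    if fields[key] else _numeric(item)
            if hasattr(item, "ContentSequence"):
                walk(item.ContentSequence)

    walk(getattr(container, "ContentSequence", []))
    return IrradiationEvent(**fields)


def read_rdsr_events(path) -> list[IrradiationEvent]:
    """All projection irradiation events of an RDSR file, in file order."""
    ds = pydicom.dcmread(Path(path))
    containers = list(
        _walk_containers(getattr(ds, "ContentSequence", []), "Irradiation Event X-Ray Data")
    )
    return [_extract_event(c, i) for i, c in enumerate(containers)]
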