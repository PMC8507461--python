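"""Room, C-arm and patient-phantom geometry with ray-tracing primitives.

Coordinate frame (right-handed, metres, origin at the isocenter):
``+x`` = patient left, ``+y`` = patient cranial, ``+z`` = up.  The x-ray
tube sits under the table, so the unrotated source lies at
``(0, 0, -d_source_iso)`` and the image receptor above the patient.
Primary C-arm angulation (+RAO / -LAO) rotates the gantry about the
patient's longitudinal axis, positive toward the patient's right
(``-x``); secondary (cranio-caudal) angulation rotates about the lateral
axis.

The patient is modelled either as a BOMAB-type phantom -- stacked
elliptical cylinders plus an ellipsoid head, homogeneous soft tissue --
or as a rectangular prism.  Both support per-axis scaling to a patient's
real dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .physics import cross_sections

__all__ = [
    "EllipticalCylinder", "Ellipsoid", "PatientPhantom", "Shield", "Table",
    "RoomModel", "source_position", "rotation_matrix", "beam_cone", "BeamCone",
    "path_length", "shield_transmission", "default_bomab", "default_room",
    "load_room", "save_room",
]


# --------------------------------------------------------------------------
# phantom segments (internal storage in metres)

@dataclass(frozen=True)
class EllipticalCylinder:
    """Axis along y; elliptical cross-section in the x-z plane."""

    center_x: float
    center_z: float
    semi_x: float
    semi_z: float
    y_min: float
    y_max: float

    def scaled(self, s) -> "EllipticalCylinder":
        return EllipticalCylinder(
            self.center_x * s[0], self.center_z * s[2],
            self.semi_x * s[0], self.semi_z * s[2],
            self.y_min * s[1], self.y_max * s[1],
        )

    def volume(self) -> float:
        return math.pi * self.semi_x * self.semi_z * (self.y_max - self.y_min)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        dx = (pts[:, 0] - self.center_x) / self.semi_x
        dz = (pts[:, 2] - self.center_z) / self.semi_z
        return (dx**2 + dz**2 <= 1.0) & (pts[:, 1] >= self.y_min) & (pts[:, 1] <= self.y_max)

    def chord(self, origin: np.ndarray, direction: np.ndarray,
              t_max: Optional[np.ndarray] = None) -> np.ndarray:
        """Vectorised in-segment chord length (m) for rays origin + t*dir, t>=0."""
        ox = (origin[:, 0] - self.center_x) / self.semi_x
        oz = (origin[:, 2] - self.center_z) / self.semi_z
        dx = direction[:, 0] / self.semi_x
        dz = direction[:, 2] / self.semi_z
        a = dx**2 + dz**2
        b = 2.0 * (ox * dx + oz * dz)
        c = ox**2 + oz**2 - 1.0
        t0, t1 = _solve_quadratic(a, b, c)
        # clip to the y-extent of the segment
        ty0, ty1 = _axis_interval(origin[:, 1], direction[:, 1], self.y_min, self.y_max)
        lo = np.maximum(np.maximum(t0, ty0), 0.0)
        hi = np.minimum(t1, ty1)
        if t_max is not None:
            hi = np.minimum(hi, t_max)
        return np.maximum(hi - lo, 0.0)


@dataclass(frozen=True)
class Ellipsoid:
    center: tuple
    semi_axes: tuple

    def scaled(self, s) -> "Ellipsoid":
        return Ellipsoid(
            tuple(c * f for c, f in zip(self.center, s)),
            tuple(a * f for a, f in zip(self.semi_axes, s)),
        )

    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d**2).sum(axis=1) <= 1.0

    def chord(self, origin: np.ndarray, direction: np.ndarray,
              t_max: Optional[np.ndarray] = None) -> np.ndarray:
        o = (origin - np.asarray(self.center)) / np.asarray(self.semi_axes)
        d = direction / np.asarray(self.semi_axes)
        a = (d**2).sum(axis=1)
        b = 2.0 * (o * d).sum(axis=1)
        c = (o**2).sum(axis=1) - 1.0
        t0, t1 = _solve_quadratic(a, b, c)
        lo = np.maximum(t0, 0.0)
        hi = t1
        if t_max is not None:
            hi = np.minimum(hi, t_max)
        return np.maximum(hi - lo, 0.0)


def _solve_quadratic(a, b, c):
    """Entry/exit parameters of a*t^2+b*t+c=0; (inf, -inf) when no hit."""
    disc = b**2 - 4.0 * a * c
    hit = (disc > 0.0) & (a > 0.0)
    sq = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(hit, (-b - sq) / (2.0 * a), np.inf)
        t1 = np.where(hit, (-b + sq) / (2.0 * a), -np.inf)
    return t0, t1


def _axis_interval(o, d, lo, hi):
    """Parameter interval where o + t*d lies within [lo, hi]."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - o) / d
        t_hi = (hi - o) / d
    inside = (o >= lo) & (o <= hi)
    parallel = np.abs(d) < 1e-300
    a = np.where(parallel, np.where(inside, -np.inf, np.inf), np.minimum(t_lo, t_hi))
    b = np.where(parallel, np.where(inside, np.inf, -np.inf), np.maximum(t_lo, t_hi))
    return a, b


# --------------------------------------------------------------------------
# patient phantom

@dataclass
class PatientPhantom:
    """Homogeneous patient model: BOMAB-type segment stack or a prism."""

    kind: str  # "bomab" | "prism"
    segments: list = field(default_factory=list)
    prism_size: Optional[tuple] = None    # (x, y, z) metres
    prism_center: tuple = (0.0, 0.0, 0.0)
    material: str = "soft_tissue"

    def __post_init__(self) -> None:
        if self.kind not in ("bomab", "prism"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "prism":
            if self.prism_size is None or any(s <= 0 for s in self.prism_size):
                raise ValueError("prism phantom needs positive prism_size")

    # -- geometry queries (all vectorised; metres) --
    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        if self.kind == "prism":
            c = np.asarray(self.prism_center)
            h = np.asarray(self.prism_size) / 2.0
            return np.all(np.abs(pts - c) <= h, axis=1)
        out = np.zeros(len(pts), dtype=bool)
        for seg in self.segments:
            out |= seg.contains(pts)
        return out

    def chord_length_m(self, origin: np.ndarray, direction: np.ndarray,
                       t_max: Optional[np.ndarray] = None) -> np.ndarray:
        """Total in-phantom chord (m) along origin + t*dir for t in [0, t_max]."""
        origin = np.atleast_2d(origin)
        direction = np.atleast_2d(direction)
        if self.kind == "prism":
            c = np.asarray(self.prism_center)
            h = np.asarray(self.prism_size) / 2.0
            lo_all = np.full(len(origin), -np.inf)
            hi_all = np.full(len(origin), np.inf)
            for ax in range(3):
                a, b = _axis_interval(origin[:, ax], direction[:, ax],
                                      c[ax] - h[ax], c[ax] + h[ax])
                lo_all = np.maximum(lo_all, a)
                hi_all = np.minimum(hi_all, b)
            lo_all = np.maximum(lo_all, 0.0)
            if t_max is not None:
                hi_all = np.minimum(hi_all, t_max)
            return np.maximum(hi_all - lo_all, 0.0)
        total = np.zeros(len(origin))
        for seg in self.segments:
            total += seg.chord(origin, direction, t_max)
        return total

    def bounding_box(self) -> tuple:
        if self.kind == "prism":
            c = np.asarray(self.prism_center)
            h = np.asarray(self.prism_size) / 2.0
            return c - h, c + h
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for seg in self.segments:
            if isinstance(seg, EllipticalCylinder):
                slo = [seg.center_x - seg.semi_x, seg.y_min, seg.center_z - seg.semi_z]
                shi = [seg.center_x + seg.semi_x, seg.y_max, seg.center_z + seg.semi_z]
            else:
                c = np.asarray(seg.center)
                a = np.asarray(seg.semi_axes)
                slo, shi = c - a, c + a
            lo = np.minimum(lo, slo)
            hi = np.maximum(hi, shi)
        return lo, hi

    def analytic_volume_m3(self) -> float:
        if self.kind == "prism":
            return float(np.prod(self.prism_size))
        return sum(seg.volume() for seg in self.segments)


def default_bomab(scaling=(1.0, 1.0, 1.0)) -> PatientPhantom:
    """Nominal adult BOMAB-type phantom, supine along y, abdomen at the
    isocenter.  Segment dimensions are the standard adult set (nominal
    ~170 cm stature); ``scaling`` applies per-axis factors to adapt to
    the real patient."""
    cm = 0.01
    segs = [
        # trunk stack: gut centred on the isocenter
        EllipticalCylinder(0, 0, 18 * cm, 10 * cm, -10 * cm, 10 * cm),    # gut
        EllipticalCylinder(0, 0, 15 * cm, 10 * cm, 10 * cm, 50 * cm),     # chest
        EllipticalCylinder(0, 0, 6.5 * cm, 6.5 * cm, 50 * cm, 60 * cm),   # neck
        Ellipsoid((0, 70 * cm, 0), (9.5 * cm, 10 * cm, 7 * cm)),          # head
        EllipticalCylinder(0, 0, 18 * cm, 10 * cm, -30 * cm, -10 * cm),   # pelvis
        EllipticalCylinder(-8.5 * cm, 0, 7.5 * cm, 7.5 * cm, -60 * cm, -30 * cm),
        EllipticalCylinder(+8.5 * cm, 0, 7.5 * cm, 7.5 * cm, -60 * cm, -30 * cm),
        EllipticalCylinder(-7 * cm, 0, 5.5 * cm, 5.5 * cm, -90 * cm, -60 * cm),
        EllipticalCylinder(+7 * cm, 0, 5.5 * cm, 5.5 * cm, -90 * cm, -60 * cm),
        EllipticalCylinder(-24 * cm, 0, 5 * cm, 5 * cm, -20 * cm, 40 * cm),  # arms
        EllipticalCylinder(+24 * cm, 0, 5 * cm, 5 * cm, -20 * cm, 40 * cm),
    ]
    segs = [s.scaled(scaling) for s in segs]
    return PatientPhantom(kind="bomab", segments=segs)


# --------------------------------------------------------------------------
# shield / table / room

@dataclass
class Shield:
    """Ceiling-suspended protective screen: a rectangle of given lead
    equivalence between the scatter source and the operator."""

    center: tuple          # m
    axis_u: tuple          # in-plane unit vector
    axis_v: tuple          # in-plane unit vector, orthogonal to axis_u
    width: float           # m, along axis_u
    height: float          # m, along axis_v
    pb_equivalence_mm: float = 0.5

    def __post_init__(self) -> None:
        u = np.asarray(self.axis_u, dtype=float)
        v = np.asarray(self.axis_v, dtype=float)
        if abs(float(u @ v)) > 1e-9:
            raise ValueError("shield axes must be orthogonal")
        if self.pb_equivalence_mm < 0:
            raise ValueError("negative lead equivalence")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(np.asarray(self.axis_u, float), np.asarray(self.axis_v, float))

    def crosses(self, origin: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Whether segments origin->target pass through the rectangle."""
        origin = np.atleast_2d(origin).astype(float)
        target = np.atleast_2d(target).astype(float)
        c = np.asarray(self.center, float)
        n = self.normal
        d = target - origin
        denom = d @ n
        num = (c - origin) @ n
        with np.errstate(divide="ignore", invalid="ignore"):
            t = num / denom
        valid = (np.abs(denom) > 1e-300) & (t > 0.0) & (t < 1.0)
        hit = origin + t[:, None] * d
        rel = hit - c
        in_u = np.abs(rel @ np.asarray(self.axis_u, float)) <= self.width / 2.0
        in_v = np.abs(rel @ np.asarray(self.axis_v, float)) <= self.height / 2.0
        return valid & in_u & in_v


@dataclass
class Table:
    """Carbon-fibre patient table, modelled as an attenuating slab crossed
    by the primary beam (under-table tube)."""

    z_top: float = -0.12          # m, below the patient mid-plane
    al_equivalent_mm: float = 1.5
    enabled: bool = True


@dataclass
class RoomModel:
    d_source_iso: float = 0.75
    d_iso_detector: float = 0.35
    d_iso_reference: float = 0.15
    phantom: PatientPhantom = field(default_factory=default_bomab)
    table: Table = field(default_factory=Table)
    shield: Optional[Shield] = None
    isocenter: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.d_source_iso <= 0 or self.d_iso_detector <= 0:
            raise ValueError("C-arm distances must be positive")
        if not 0 < self.d_iso_reference < self.d_source_iso:
            raise ValueError("reference point must lie between isocenter and source")


def rotation_matrix(ang_primary: float, ang_secondary: float) -> np.ndarray:
    """Gantry rotation: primary about the patient axis (+RAO toward the
    patient's right, -x), then secondary (cranial positive) about x."""
    th = math.radians(ang_primary)
    ph = math.radians(ang_secondary)
    ry = np.array([[math.cos(th), 0, math.sin(th)],
                   [0, 1, 0],
                   [-math.sin(th), 0, math.cos(th)]])
    rx = np.array([[1, 0, 0],
                   [0, math.cos(ph), -math.sin(ph)],
                   [0, math.sin(ph), math.cos(ph)]])
    return rx @ ry


def source_position(room: RoomModel, ang_primary: float, ang_secondary: float) -> np.ndarray:
    """Focal-spot position for the given C-arm angulation (degrees)."""
    if abs(ang_primary) > 120 or abs(ang_secondary) > 120:
        raise ValueError("angulation beyond +/-120 degrees")
    r = rotation_matrix(ang_primary, ang_secondary)
    return np.asarray(room.isocenter) + r @ np.array([0.0, 0.0, -room.d_source_iso])


@dataclass(frozen=True)
class BeamCone:
    """Square pyramidal beam: apex at the focal spot, axis through the
    isocenter, aperture sized so the projected area at the image-receptor
    plane equals the event's collimated field area."""

    apex: np.ndarray
    axis: np.ndarray       # unit
    basis_u: np.ndarray    # unit, aperture edge direction
    basis_v: np.ndarray
    half_side_at_detector: float  # m
    d_source_detector: float      # m

    @property
    def half_angle(self) -> float:
        return math.atan2(self.half_side_at_detector, self.d_source_detector)

    def area_at(self, distance: float) -> float:
        """Projected square aperture area (m^2) at given distance from apex."""
        s = self.half_side_at_detector * distance / self.d_source_detector
        return (2.0 * s) ** 2


def beam_cone(room: RoomModel, ang_primary: float, ang_secondary: float,
              field_area_cm2: float) -> BeamCone:
    if field_area_cm2 <= 0:
        raise ValueError("field_area must be positive")
    d_sd = room.d_source_iso + room.d_iso_detector
    half_side = math.sqrt(field_area_cm2 * 1e-4) / 2.0
    if half_side >= d_sd:
        raise ValueError("aperture exceeds 90 degree half-angle")
    r = rotation_matrix(ang_primary, ang_secondary)
    apex = source_position(room, ang_primary, ang_secondary)
    axis = r @ np.array([0.0, 0.0, 1.0])
    return BeamCone(
        apex=apex, axis=axis,
        basis_u=r @ np.array([1.0, 0.0, 0.0]),
        basis_v=r @ np.array([0.0, 1.0, 0.0]),
        half_side_at_detector=half_side,
        d_source_detector=d_sd,
    )


def path_length(phantom: PatientPhantom, origin, direction) -> float:
    """Total in-phantom chord length in cm for a ray from ``origin``
    along unit vector ``direction`` (room frame, metres in, cm out)."""
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if not math.isclose(n, 1.0, rel_tol=1e-6):
        raise ValueError("direction must be a unit vector")
    out = phantom.chord_length_m(np.atleast_2d(origin), np.atleast_2d(direction))
    return float(out[0]) * 100.0


def shield_transmission(shield: Optional[Shield], energy_kev, origin, target) -> np.ndarray:
    """Broad-beam transmission factor(s) through the ceiling shield for
    segment(s) origin -> target; 1 where the segment misses the shield."""
    origin = np.atleast_2d(origin)
    n = len(origin)
    if shield is None or shield.pb_equivalence_mm == 0.0:
        return np.ones(n)
    crossing = shield.crosses(origin, np.broadcast_to(np.asarray(target, float), origin.shape))
    mu = cross_sections("lead").mu(energy_kev)  # 1/cm
    factor = np.exp(-mu * shield.pb_equivalence_mm / 10.0)
    return np.where(crossing, factor, 1.0)


# --------------------------------------------------------------------------
# room config I/O

def default_room(shield: bool = False) -> RoomModel:
    room = RoomModel()
    if shield:
        room.shield = Shield(
            center=(0.55, 0.0, 0.9), axis_u=(0.0, 1.0, 0.0), axis_v=(0.0, 0.0, 1.0),
            width=0.6, height=0.8, pb_equivalence_mm=0.5,
        )
    return room


def save_room(room: RoomModel, path) -> Path:
    data: dict = {
        "frame": "right-handed; x=patient left, y=cranial, z=up; origin at isocenter; metres",
        "d_source_iso": room.d_source_iso,
        "d_iso_detector": room.d_iso_detector,
        "d_iso_reference": room.d_iso_reference,
        "isocenter": list(room.isocenter),
        "table": {
            "z_top": room.table.z_top,
            "al_equivalent_mm": room.table.al_equivalent_mm,
            "enabled": room.table.enabled,
        },
        "phantom": {"kind": room.phantom.kind, "material": room.phantom.material},
    }
    if room.phantom.kind == "prism":
        data["phantom"]["prism_size"] = list(room.phantom.prism_size)
        data["phantom"]["prism_center"] = list(room.phantom.prism_center)
    else:
        data["phantom"]["scaling"] = [1.0, 1.0, 1.0]
    if room.shield is not None:
        s = room.shield
        data["shield"] = {
            "center": list(s.center), "axis_u": list(s.axis_u), "axis_v": list(s.axis_v),
            "width": s.width, "height": s.height,
            "pb_equivalence_mm": s.pb_equivalence_mm,
        }
    path = Path(path)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def load_room(path) -> RoomModel:
    data = yaml.safe_load(Path(path).read_text())
    ph = data.get("phantom", {})
    if ph.get("kind", "bomab") == "prism":
        phantom = PatientPhantom(
            kind="prism",
            prism_size=tuple(ph["prism_size"]),
            prism_center=tuple(ph.get("prism_center", (0, 0, 0))),
            material=ph.get("material", "soft_tissue"),
        )
    else:
        phantom = default_bomab(tuple(ph.get("scaling", (1.0, 1.0, 1.0))))
        phantom.material = ph.get("material", "soft_tissue")
    t = data.get("table", {})
    table = Table(
        z_top=t.get("z_top", -0.12),
        al_equivalent_mm=t.get("al_equivalent_mm", 1.5),
        enabled=t.get("enabled", True),
    )
    shield = None
    if "shield" in data:
        s = data["shield"]
        shield = Shield(
            center=tuple(s["center"]), axis_u=tuple(s["axis_u"]), axis_v=tuple(s["axis_v"]),
            width=s["width"], height=s["height"],
            pb_equivalence_mm=s["pb_equivalence_mm"],
        )
    return RoomModel(
        d_source_iso=data.get("d_source_iso", 0.75),
        d_iso_detector=data.get("d_iso_detector", 0.35),
        d_iso_reference=data.get("d_iso_reference", 0.15),
        phantom=phantom, table=table, shield=shield,
        isocenter=tuple(data.get("isocenter", (0, 0, 0))),
    )
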