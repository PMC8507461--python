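"""C-arm geometry, phantom ray tracing and the ceiling shield."""

import math

import numpy as np
import pytest

from irscatter.geometry import (
    EllipticalCylinder,
    PatientPhantom,
    Shield,
    beam_cone,
    default_bomab,
    default_room,
    load_room,
    path_length,
    save_room,
    shield_transmission,
    source_position,
)
from irscatter.physics import cross_sections


def test_unrotated_source_below_isocenter(bomab_room):
    src = source_position(bomab_room, 0.0, 0.0)
    assert np.allclose(src, [0.0, 0.0, -bomab_room.d_source_iso], atol=1e-15)


@pytest.mark.parametrize("ang", [(15.0, 0.0), (-35.0, 0.0), (26.0, 10.0), (0.0, -20.0)])
def test_rotation_preserves_distance_to_isocenter(bomab_room, ang):
    src = source_position(bomab_room, *ang)
    assert np.linalg.norm(src) == pytest.approx(bomab_room.d_source_iso, abs=1e-12)


def test_rao_rotation_moves_source_toward_patient_right(bomab_room):
    src = source_position(bomab_room, 15.0, 0.0)
    assert src[0] < 0  # +RAO: toward -x (patient right)


def test_opposite_rotations_compose_to_identity(bomab_room):
    from irscatter.geometry import rotation_matrix
    r = rotation_matrix(15.0, 0.0) @ rotation_matrix(-15.0, 0.0)
    assert np.allclose(r, np.eye(3), atol=1e-14)


def test_beam_cone_aperture_matches_field_area(bomab_room, case_a_event):
    cone = beam_cone(bomab_room, 0.0, 0.0, 835.0)
    side = math.sqrt(835.0) * 1e-2  # m
    assert 2 * cone.half_side_at_detector == pytest.approx(side, rel=1e-12)
    assert cone.half_angle == pytest.approx(
        math.atan(side / 2 / (bomab_room.d_source_iso + bomab_room.d_iso_detector)),
        rel=1e-12)


def test_corner_projection_recovers_field_area(bomab_room):
    """Forward ray-trace the four aperture corners to the receptor plane;
    the quadrilateral area must equal the requested field area."""
    cone = beam_cone(bomab_room, 25.0, 10.0, 600.0)
    d = cone.d_source_detector
    hs = cone.half_side_at_detector
    corners = []
    for su, sv in ((1, 1), (1, -1), (-1, -1), (-1, 1)):
        direction = d * cone.axis + su * hs * cone.basis_u + sv * hs * cone.basis_v
        direction /= np.linalg.norm(direction)
        # intersect with the receptor plane (normal = axis, distance d)
        t = d / (direction @ cone.axis)
        corners.append(cone.apex + t * direction)
    a, b, c, e = corners
    area = 0.5 * np.linalg.norm(np.cross(c - a, e - b))  # square diagonals
    assert area * 1e4 == pytest.approx(600.0, rel=1e-3)


def test_doubling_field_area_doubles_solid_angle(bomab_room):
    c1 = beam_cone(bomab_room, 0.0, 0.0, 400.0)
    c2 = beam_cone(bomab_room, 0.0, 0.0, 800.0)
    sa1 = 4 * math.atan(c1.half_side_at_detector**2 / (c1.d_source_detector * math.sqrt(
        c1.d_source_detector**2 + 2 * c1.half_side_at_detector**2)))
    sa2 = 4 * math.atan(c2.half_side_at_detector**2 / (c2.d_source_detector * math.sqrt(
        c2.d_source_detector**2 + 2 * c2.half_side_at_detector**2)))
    assert sa2 / sa1 == pytest.approx(2.0, rel=0.02)


def test_path_length_miss_is_zero():
    phantom = default_bomab()
    assert path_length(phantom, (3.0, 0.0, 0.0), (0.0, 0.0, 1.0)) == 0.0


def test_path_length_through_cylinder_center_is_full_chord():
    # gut segment: semi_z = 10 cm; vertical ray through its center
    phantom = PatientPhantom(kind="bomab", segments=[
        EllipticalCylinder(0.0, 0.0, 0.18, 0.10, -0.10, 0.10)])
    chord = path_length(phantom, (0.0, 0.0, -1.0), (0.0, 0.0, 1.0))
    assert chord == pytest.approx(20.0, rel=1e-12)  # 2*b in cm
    lateral = path_length(phantom, (-1.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    assert lateral == pytest.approx(36.0, rel=1e-12)  # 2*a in cm


def test_path_length_bounded_by_bbox_diagonal():
    phantom = default_bomab()
    lo, hi = phantom.bounding_box()
    diag_cm = np.linalg.norm(hi - lo) * 100
    rng = np.random.default_rng(42)
    for _ in range(200):
        origin = rng.uniform(-2, 2, 3)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pl = path_length(phantom, origin, d)
        assert 0.0 <= pl <= diag_cm + 1e-9


def test_path_length_symmetric_under_ray_reversal():
    phantom = default_bomab()
    origin = np.array([-1.0, 0.05, 0.02])
    d = np.array([1.0, 0.0, 0.0])
    fwd = path_length(phantom, origin, d)
    back = path_length(phantom, -origin, -d)
    assert fwd == pytest.approx(back, rel=1e-9)
    assert fwd > 0


def test_bomab_volume_matches_monte_carlo_point_sampling():
    phantom = default_bomab()
    lo, hi = phantom.bounding_box()
    rng = np.random.default_rng(7)
    n = 1_000_000
    pts = rng.uniform(lo, hi, (n, 3))
    frac = phantom.contains(pts).mean()
    mc_volume = frac * np.prod(hi - lo)
    assert mc_volume == pytest.approx(phantom.analytic_volume_m3(), rel=5e-3)


def test_scaling_scales_volume():
    base = default_bomab().analytic_volume_m3()
    scaled = default_bomab((1.1, 1.0, 1.2)).analytic_volume_m3()
    assert scaled == pytest.approx(base * 1.1 * 1.2, rel=1e-12)


# -- shield ----------------------------------------------------------------

def _shield(pb=0.5):
    return Shield(center=(0.5, 0.0, 0.5), axis_u=(0.0, 1.0, 0.0),
                  axis_v=(0.0, 0.0, 1.0), width=0.6, height=0.8,
                  pb_equivalence_mm=pb)


def test_segment_missing_shield_transmits_fully():
    t = shield_transmission(_shield(), 80.0, (0.0, 5.0, 0.0), (1.0, 5.0, 0.0))
    assert t[0] == 1.0


def test_zero_lead_shield_is_identity():
    t = shield_transmission(_shield(pb=0.0), 80.0, (0.0, 0.0, 0.5), (1.0, 0.0, 0.5))
    assert t[0] == 1.0


def test_crossing_shield_attenuates_by_lead_closed_form():
    mu = cross_sections("lead").mu(80.0)
    t = shield_transmission(_shield(0.5), 80.0, (0.0, 0.0, 0.5), (1.0, 0.0, 0.5))
    assert t[0] == pytest.approx(math.exp(-mu * 0.05), rel=1e-12)


def test_non_orthogonal_shield_axes_rejected():
    with pytest.raises(ValueError, match="orthogonal"):
        Shield(center=(0, 0, 0), axis_u=(1, 0, 0), axis_v=(1, 1, 0),
               width=1, height=1)


def test_room_yaml_round_trip(tmp_path):
    room = default_room(shield=True)
    p = save_room(room, tmp_path / "room.yaml")
    back = load_room(p)
    assert back.d_source_iso == room.d_source_iso
    assert back.shield.pb_equivalence_mm == room.shield.pb_equivalence_mm
    assert back.phantom.kind == "bomab"
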