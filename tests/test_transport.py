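"""Monte-Carlo transport: sampling kernels, next-event estimator and
whole-event simulation properties."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from irscatter.events import IrradiationEvent
from irscatter.geometry import PatientPhantom, RoomModel, Table
from irscatter.physics import cross_sections
from irscatter.transport import (
    DetectorPoint,
    analog_sphere_fluence,
    compton_energy,
    kn_diff_cross_section,
    kn_total_cross_section,
    next_event_contribution,
    run_event_simulation,
    sample_compton,
    sample_interaction,
)

from conftest import mono_spectrum


def _vacuum_room():
    phantom = PatientPhantom(kind="prism", prism_size=(1e-6, 1e-6, 1e-6),
                             prism_center=(0.0, 0.0, -5.0))
    return RoomModel(phantom=phantom, table=Table(enabled=False))


def _slab_event(kvp=80.0, field=1.0):
    return IrradiationEvent(
        event_id="slab", t_start=0.0, duration=10.0, event_type="acquisition",
        kvp=kvp, filtration_cu=0.0, field_area=field, p_ka=1.0, k_air_ref=4.0)


# -- interaction branch sampling -------------------------------------------

def test_branch_frequencies_match_partial_coefficient_ratios():
    """1e6 draws at 60 keV in soft tissue against the table-ratio oracle,
    3-sigma binomial bands."""
    rng = np.random.default_rng(123)
    n = 1_000_000
    draws = sample_interaction(60.0, "soft_tissue", rng, size=n)
    t = cross_sections("soft_tissue")
    mu = np.array([t.mu(60.0, "photoelectric"), t.mu(60.0, "compton"),
                   t.mu(60.0, "rayleigh")])
    p = mu / mu.sum()
    for branch, p_i in zip(("photoelectric", "compton", "rayleigh"), p):
        obs = (draws == branch).mean()
        sigma = math.sqrt(p_i * (1 - p_i) / n)
        assert abs(obs - p_i) < 3 * sigma


def test_fixed_seed_reproduces_branch_sequence():
    a = sample_interaction(60.0, "water", np.random.default_rng(9), size=1000)
    b = sample_interaction(60.0, "water", np.random.default_rng(9), size=1000)
    assert np.array_equal(a, b)


def test_single_draw_returns_branch_name():
    assert sample_interaction(60.0, "water", np.random.default_rng(0)) in (
        "photoelectric", "compton", "rayleigh")


# -- Compton kernel --------------------------------------------------------

def test_compton_samples_respect_kinematic_bounds():
    rng = np.random.default_rng(5)
    e = 80.0
    e_out, cos_t = sample_compton(e, rng, size=100_000)
    e_min = e / (1 + 2 * e / 510.99895)
    assert np.all(e_out >= e_min - 1e-9)
    assert np.all(e_out <= e + 1e-9)
    # energy-angle consistency via the Compton relation
    assert np.allclose(e_out, compton_energy(e, cos_t), rtol=1e-12)


def test_forward_scatter_keeps_full_energy():
    assert compton_energy(60.0, 1.0) == pytest.approx(60.0, rel=1e-14)


def test_mean_scatter_cosine_matches_klein_nishina_quadrature():
    """First angular moment of the sampled distribution at 60 keV against
    independent numerical quadrature of the Klein-Nishina kernel."""
    e = 60.0
    num, _ = quad(lambda c: c * kn_diff_cross_section(e, c) * 2 * math.pi, -1, 1)
    den, _ = quad(lambda c: kn_diff_cross_section(e, c) * 2 * math.pi, -1, 1)
    oracle = num / den
    rng = np.random.default_rng(17)
    n = 1_000_000
    _, cos_t = sample_compton(e, rng, size=n)
    sem = cos_t.std() / math.sqrt(n)
    assert abs(cos_t.mean() - oracle) < 3 * sem
    # and the closed-form total agrees with the quadrature normalisation
    assert kn_total_cross_section(e) == pytest.approx(den, rel=1e-8)


# -- next-event estimator --------------------------------------------------

def test_isotropic_point_source_in_vacuum_exact_inverse_square():
    room = _vacuum_room()
    det = DetectorPoint("d", (2.0, 0.0, 0.0))
    c, e_out = next_event_contribution((0, 0, 0), 60.0, (0, 0, 1), det, room,
                                       kind="isotropic")
    r_cm = 200.0
    assert c == pytest.approx(1.0 / (4 * math.pi * r_cm**2), rel=1e-12)
    assert e_out == 60.0


def test_doubling_distance_quarters_contribution():
    room = _vacuum_room()
    near = DetectorPoint("n", (1.0, 0.0, 0.0))
    far = DetectorPoint("f", (2.0, 0.0, 0.0))
    cn, _ = next_event_contribution((0, 0, 0), 60.0, (0, 0, 1), near, room, "isotropic")
    cf, _ = next_event_contribution((0, 0, 0), 60.0, (0, 0, 1), far, room, "isotropic")
    assert cn / cf == pytest.approx(4.0, rel=1e-12)


def test_point_detector_agrees_with_analog_sphere_on_water_slab(water_slab_room):
    """Estimator equivalence on the toy problem: 20 cm water slab, 80 kVp
    pencil beam, detector at 90 degrees and 1 m."""
    ev = _slab_event()
    det = [DetectorPoint("p90", (1.0, 0.0, 0.0))]
    t = run_event_simulation(ev, water_slab_room, det, n_histories=150_000, seed=3)
    flu = t.fluence_per_photon("p90").sum()
    g = t.mc_group_sums[:, 0, :].sum(axis=1) / t.group_counts
    sig_ne = g.std(ddof=1) / math.sqrt(len(g))
    fa, sa = analog_sphere_fluence(ev, water_slab_room, (1.0, 0.0, 0.0), 0.10,
                                   n_histories=250_000, seed=3)
    assert abs(flu - fa) < 3 * math.hypot(sig_ne, sa)


# -- event simulation ------------------------------------------------------

def test_fixed_seed_gives_bit_identical_tallies(case_a_event, bomab_room, chest_point):
    t1 = run_event_simulation(case_a_event, bomab_room, [chest_point],
                              n_histories=20_000, seed=5)
    t2 = run_event_simulation(case_a_event, bomab_room, [chest_point],
                              n_histories=20_000, seed=5)
    assert np.array_equal(t1.mc_group_sums, t2.mc_group_sums)
    assert t1.simulated_pka == t2.simulated_pka


def test_beer_lambert_uncollided_transmission(water_slab_room):
    """Monoenergetic pencil beam through 20 cm of water: uncollided
    fraction equals exp(-mu*t) within 3 sigma (binomial)."""
    ev = _slab_event(kvp=61.0)
    det = [DetectorPoint("side", (1.5, 0.0, 0.0))]
    n = 60_000
    t = run_event_simulation(ev, water_slab_room, det, n_histories=n, seed=21,
                             spectrum_override=mono_spectrum(60.0))
    p = math.exp(-cross_sections("water").mu(60.0) * 20.0)
    obs = t.n_uncollided / n
    sigma = math.sqrt(p * (1 - p) / n)
    assert abs(obs - p) < 3 * sigma


def test_no_tally_energy_above_source_spectrum(case_a_event, bomab_room, chest_point):
    t = run_event_simulation(case_a_event, bomab_room, [chest_point],
                             n_histories=20_000, seed=2)
    flu = t.fluence_per_photon("chest")
    mids = 0.5 * (t.energy_edges[:-1] + t.energy_edges[1:])
    assert np.all(flu[mids > case_a_event.kvp] == 0.0)
    assert flu.sum() > 0


def test_scatter_decreases_with_detector_distance(case_a_event, bomab_room):
    dets = [DetectorPoint("d05", (0.5, -0.2, 0.45)),
            DetectorPoint("d10", (1.0, -0.2, 0.45)),
            DetectorPoint("d20", (2.0, -0.2, 0.45))]
    t = run_event_simulation(case_a_event, bomab_room, dets,
                             n_histories=40_000, seed=4)
    f = [t.fluence_per_photon(d.point_id).sum() for d in dets]
    s = []
    for d in dets:
        i = t.point_index(d.point_id)
        g = t.mc_group_sums[:, i, :].sum(axis=1) / t.group_counts
        s.append(g.std(ddof=1) / math.sqrt(len(g)))
    assert f[0] - f[1] > 3 * math.hypot(s[0], s[1])
    assert f[1] - f[2] > 3 * math.hypot(s[1], s[2])


def test_estimator_consistent_across_history_counts(case_a_event, bomab_room, chest_point):
    t_small = run_event_simulation(case_a_event, bomab_room, [chest_point],
                                   n_histories=20_000, seed=8)
    t_big = run_event_simulation(case_a_event, bomab_room, [chest_point],
                                 n_histories=200_000, seed=9)

    def mean_sigma(t):
        g = t.mc_group_sums[:, 0, :].sum(axis=1) / t.group_counts
        return g.mean(), g.std(ddof=1) / math.sqrt(len(g))

    m1, s1 = mean_sigma(t_small)
    m2, s2 = mean_sigma(t_big)
    assert abs(m1 - m2) < 3 * math.hypot(s1, s2)


def test_tally_variance_scales_inversely_with_histories(case_a_event, bomab_room, chest_point):
    """log-log slope of var(mean) vs n over two decades: -1 +/- 0.1."""
    ns = [4_000, 40_000, 400_000]
    vs = []
    for i, n in enumerate(ns):
        t = run_event_simulation(case_a_event, bomab_room, [chest_point],
                                 n_histories=n, seed=30 + i)
        g = t.mc_group_sums[:, 0, :].sum(axis=1) / t.group_counts
        vs.append(g.var(ddof=1) / len(g))
    slope = np.polyfit(np.log(ns), np.log(vs), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.1)


def test_detector_inside_phantom_rejected(case_a_event, bomab_room):
    inside = DetectorPoint("bad", (0.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="inside"):
        run_event_simulation(case_a_event, bomab_room, [inside], 100, 0)


def test_empty_detector_list_rejected(case_a_event, bomab_room):
    with pytest.raises(ValueError):
        run_event_simulation(case_a_event, bomab_room, [], 100, 0)
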