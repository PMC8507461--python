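"""Fluence-to-Hp(10) conversion, normalisation and uncertainty budget."""

import numpy as np
import pytest

from irscatter.dose import (
    EventDose,
    combine_uncertainty,
    fluence_to_hp10,
    normalize_event,
)
from irscatter.events import IrradiationEvent
from irscatter.physics import hp10_per_fluence
from irscatter.transport import FluenceTally, run_event_simulation


def _tally_from_fluence(flu: np.ndarray, n: int = 1000) -> FluenceTally:
    """Build a tally with the given per-photon fluence and zero variance."""
    edges = np.arange(10.0, 151.0, 1.0)
    n_bins = len(edges) - 1
    groups = 32
    sums = np.tile(flu * (n / groups), (groups, 1, 1)).reshape(groups, 1, n_bins)
    return FluenceTally(
        point_ids=["p"], energy_edges=edges, n_histories=n, seed=0,
        mc_group_sums=sums, group_counts=np.full(groups, n // groups),
        primary_per_photon=np.zeros((1, n_bins)),
        simulated_pka=3.0e-13, simulated_kair_mGy=1.2e-12,
    )


def _event(p_ka=4.1, k_air=17.6):
    return IrradiationEvent(
        event_id="e", t_start=0.0, duration=10.0, event_type="fluoroscopy",
        kvp=79.0, filtration_cu=0.3, field_area=835.0, p_ka=p_ka, k_air_ref=k_air)


def test_zero_tally_gives_zero_dose_and_uncertainty():
    t = _tally_from_fluence(np.zeros(140))
    assert fluence_to_hp10(t, "p") == (0.0, 0.0)


def test_single_bin_tally_is_one_term_product():
    flu = np.zeros(140)
    flu[50] = 2.5e-7  # the 60-61 keV bin
    t = _tally_from_fluence(flu)
    hp, _ = fluence_to_hp10(t, "p")
    assert hp == pytest.approx(2.5e-7 * hp10_per_fluence(60.5), rel=1e-12)


def test_multi_bin_sum_matches_brute_force_oracle():
    rng = np.random.default_rng(1)
    flu = rng.random(140) * 1e-7
    t = _tally_from_fluence(flu)
    hp, _ = fluence_to_hp10(t, "p")
    mids = np.arange(10.5, 150.5, 1.0)
    brute = sum(float(f) * float(hp10_per_fluence(m)) for f, m in zip(flu, mids))
    assert hp == pytest.approx(brute, rel=1e-12)


def test_unknown_point_rejected():
    t = _tally_from_fluence(np.zeros(140))
    with pytest.raises(KeyError):
        fluence_to_hp10(t, "nope")


def test_zero_reported_pka_gives_zero_dose():
    t = _tally_from_fluence(np.ones(140) * 1e-8)
    hp, u = fluence_to_hp10(t, "p")
    d = normalize_event(hp, u, t, _event(p_ka=0.0), "p", "pka")
    assert d.hp10_uSv == 0.0


def test_normalisation_is_linear_in_reported_pka():
    t = _tally_from_fluence(np.ones(140) * 1e-8)
    hp, u = fluence_to_hp10(t, "p")
    d1 = normalize_event(hp, u, t, _event(p_ka=4.1), "p", "pka")
    d2 = normalize_event(hp, u, t, _event(p_ka=8.2), "p", "pka")
    assert d2.hp10_uSv == pytest.approx(2.0 * d1.hp10_uSv, rel=1e-12)


def test_single_event_normalisation_formula():
    t = _tally_from_fluence(np.ones(140) * 1e-8)
    hp, u = fluence_to_hp10(t, "p")
    d = normalize_event(hp, u, t, _event(p_ka=4.1), "p", "pka")
    assert d.hp10_uSv == pytest.approx(hp * 4.1 / t.simulated_pka * 1e-6, rel=1e-12)


def test_zero_simulated_normalisation_rejected():
    t = _tally_from_fluence(np.ones(140) * 1e-8)
    t.simulated_pka = 0.0
    with pytest.raises(ValueError, match="zero"):
        normalize_event(1.0, 0.1, t, _event(), "p", "pka")


def test_normalisation_modes_agree_for_geometry_consistent_event(
        case_a_event, bomab_room, chest_point):
    """pka and kair modes must coincide (within MC noise) when the
    event's reported Kair/PKA ratio matches the simulated geometry."""
    tally = run_event_simulation(case_a_event, bomab_room, [chest_point],
                                 n_histories=30_000, seed=13)
    ratio = tally.simulated_kair_mGy / tally.simulated_pka
    ev = IrradiationEvent(
        event_id=case_a_event.event_id, t_start=0.0, duration=10.0,
        event_type="fluoroscopy", kvp=79.0, filtration_cu=0.3, field_area=835.0,
        p_ka=4.1, k_air_ref=4.1 * ratio)
    hp, u = fluence_to_hp10(tally, "chest")
    d_pka = normalize_event(hp, u, tally, ev, "chest", "pka")
    d_kair = normalize_event(hp, u, tally, ev, "chest", "kair")
    assert d_pka.hp10_uSv == pytest.approx(d_kair.hp10_uSv, rel=1e-9)


def test_expanded_uncertainty_is_ten_percent_without_mc_noise():
    d = EventDose(event_id="e", point_id="p", hp10_uSv=7.0, u_stat_uSv=0.0)
    assert combine_uncertainty(d) / d.hp10_uSv == pytest.approx(0.10, rel=1e-12)


def test_zero_dose_has_zero_expanded_uncertainty():
    d = EventDose(event_id="e", point_id="p", hp10_uSv=0.0, u_stat_uSv=0.0)
    assert combine_uncertainty(d) == 0.0


@pytest.mark.parametrize("hp,u_stat", [(5.0, 0.1), (5.0, 2.0), (0.3, 0.01)])
def test_expanded_uncertainty_dominates_both_terms(hp, u_stat):
    d = EventDose(event_id="e", point_id="p", hp10_uSv=hp, u_stat_uSv=u_stat)
    u = combine_uncertainty(d)
    assert u >= 2.0 * u_stat - 1e-12
    assert u >= 0.10 * hp - 1e-12
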