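"""Trace ingestion, event synchronisation and movement subdivision."""

import numpy as np
import pytest

from irscatter.events import IrradiationEvent
from irscatter.tracking import (
    PositionTrace,
    PositionUnknown,
    load_trace,
    position_at_event_start,
    subdivide_event,
    write_trace,
)


def _trace(ts, xs=None, valid=None):
    ts = np.asarray(ts, float)
    xs = np.asarray(xs, float) if xs is not None else np.linspace(0.5, 1.5, len(ts))
    xyz = np.column_stack([xs, np.zeros(len(ts)), np.full(len(ts), 0.45)])
    v = np.ones(len(ts), bool) if valid is None else np.asarray(valid, bool)
    return PositionTrace(t=ts, xyz=xyz, valid=v)


def _event(t_start=10.0, duration=7.0, p_ka=1.0):
    return IrradiationEvent(
        event_id="ev1", t_start=t_start, duration=duration,
        event_type="acquisition", kvp=80.0, filtration_cu=0.3,
        field_area=600.0, p_ka=p_ka, k_air_ref=4.0)


def test_load_three_row_file(tmp_path):
    p = tmp_path / "trace.csv"
    p.write_text("t,x,y,z,valid\n0.0,0.5,0.0,0.45,1\n0.2,0.6,0.0,0.45,1\n0.4,0.7,0.0,0.45,0\n")
    tr = load_trace(p)
    assert len(tr) == 3
    assert tr.valid.tolist() == [True, True, False]


def test_duplicate_timestamp_rejected_with_row_number(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("t,x,y,z\n0.0,0,0,0\n0.2,0,0,0\n0.2,0,0,0\n")
    with pytest.raises(ValueError, match="row 3"):
        load_trace(p)


def test_trace_round_trip(tmp_path):
    tr = _trace([0.0, 0.2, 0.4], valid=[1, 0, 1])
    back = load_trace(write_trace(tr, tmp_path / "rt.csv"))
    assert np.array_equal(back.t, tr.t)
    assert np.array_equal(back.xyz, tr.xyz)
    assert np.array_equal(back.valid, tr.valid)


def test_event_starting_exactly_at_sample_uses_it():
    tr = _trace([0.0, 10.0, 20.0], xs=[0.5, 0.9, 1.3])
    pos = position_at_event_start(tr, _event(t_start=10.0))
    assert pos[0] == 0.9


def test_event_between_samples_holds_last_value():
    tr = _trace([0.0, 10.0, 20.0], xs=[0.5, 0.9, 1.3])
    pos = position_at_event_start(tr, _event(t_start=14.0))
    assert pos[0] == 0.9  # not interpolated toward 1.3


def test_all_invalid_samples_is_position_unknown():
    tr = _trace([9.0, 9.5, 10.0], valid=[0, 0, 0])
    with pytest.raises(PositionUnknown):
        position_at_event_start(tr, _event(t_start=10.0))


def test_gap_beyond_max_gap_is_position_unknown():
    tr = _trace([0.0, 1.0])
    with pytest.raises(PositionUnknown):
        position_at_event_start(tr, _event(t_start=10.0), max_gap=5.0)
    # same gap allowed with a wider tolerance
    pos = position_at_event_start(tr, _event(t_start=10.0), max_gap=20.0)
    assert pos[0] == _trace([0.0, 1.0]).xyz[1, 0]


def test_clock_offset_shifts_matching_consistently():
    tr = _trace([0.0, 10.0, 20.0], xs=[0.5, 0.9, 1.3])
    ev = _event(t_start=9.0)
    early = position_at_event_start(tr, ev, clock_offset=0.0, max_gap=20.0)
    late = position_at_event_start(tr, ev, clock_offset=2.0, max_gap=20.0)
    assert early[0] == 0.5 and late[0] == 0.9  # never matched backwards


def test_resampling_preserving_pre_event_samples_is_invariant():
    tr_coarse = _trace([0.0, 10.0], xs=[0.5, 0.9])
    tr_fine = _trace([0.0, 5.0, 10.0, 12.5], xs=[0.5, 0.5, 0.9, 1.1])
    ev = _event(t_start=11.0)
    assert position_at_event_start(tr_coarse, ev)[0] == \
        position_at_event_start(tr_fine, ev)[0]


# -- subdivision -----------------------------------------------------------

def test_single_frame_subdivision_is_static_treatment():
    tr = _trace([9.0, 12.0, 15.0], xs=[0.7, 1.0, 1.3])
    ev = _event(t_start=10.0, duration=7.0, p_ka=2.0)
    [(sub, pos)] = subdivide_event(ev, tr, 1)
    assert sub.p_ka == ev.p_ka and sub.duration == ev.duration
    assert pos[0] == position_at_event_start(tr, ev)[0]


def test_subdivision_conserves_pka_and_duration_exactly():
    tr = _trace(np.arange(0.0, 30.0, 0.2))
    ev = _event(t_start=10.0, duration=7.0, p_ka=3.3)
    parts = subdivide_event(ev, tr, 7)
    assert len(parts) == 7
    assert sum(s.p_ka for s, _ in parts) == pytest.approx(ev.p_ka, rel=1e-12)
    assert sum(s.duration for s, _ in parts) == pytest.approx(ev.duration, rel=1e-12)
    assert sum(s.k_air_ref for s, _ in parts) == pytest.approx(ev.k_air_ref, rel=1e-12)


def test_subdivision_positions_follow_trace():
    ts = 10.0 + np.arange(7)
    tr = _trace(ts, xs=np.linspace(0.7, 1.5, 7))
    ev = _event(t_start=10.0, duration=7.0)
    parts = subdivide_event(ev, tr, 7)
    xs = [pos[0] for _, pos in parts]
    assert xs == sorted(xs)
    assert xs[0] == pytest.approx(0.7) and xs[-1] == pytest.approx(1.5, rel=0.2)


def test_insufficient_trace_falls_back_with_warning():
    tr = _trace([10.0, 11.0])  # covers only the first frames within max_gap
    ev = _event(t_start=10.0, duration=30.0)
    with pytest.warns(UserWarning, match="falling back"):
        parts = subdivide_event(ev, tr, 10, max_gap=5.0)
    assert 1 <= len(parts) < 10
    assert sum(s.p_ka for s, _ in parts) == pytest.approx(ev.p_ka, rel=1e-12)


def test_zero_duration_event_cannot_be_subdivided():
    tr = _trace([0.0, 1.0])
    with pytest.raises(ValueError):
        subdivide_event(_event(duration=0.0), tr, 3)


def test_empty_trace_rejected():
    with pytest.raises(ValueError, match="empty"):
        PositionTrace(t=np.array([]), xyz=np.zeros((0, 3)), valid=np.array([], bool))
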