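import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebbtrack import synthetic_data, tides
from ebbtrack.core_data import CoverageError, SchemaError, WaterLevelSeries


# -- interpolation ---------------------------------------------------------


def test_inverse_distance_example(flat_series):
    # stations 1 km (level 2.0) and 3 km (level 4.0) from target:
    # (2.0*1 + 4.0*(1/3)) / (1 + 1/3) = 2.5
    a = flat_series("A", 1.0, 2.0)
    b = flat_series("B", 3.0, 4.0)
    assert tides.interpolate_level([a, b], 0.0, 0) == pytest.approx(2.5, abs=1e-12)


def test_station_coincides_with_target(flat_series):
    a = flat_series("A", 5.0, 1.25)
    b = flat_series("B", 9.0, 7.0)
    assert tides.interpolate_level([a, b], 5.0, 600) == 1.25


def test_equidistant_stations(flat_series):
    a = flat_series("A", 2.0, 1.0)
    b = flat_series("B", 6.0, 3.0)
    assert tides.interpolate_level([a, b], 4.0, 0) == pytest.approx(2.0)


def test_single_station_unweighted(flat_series):
    a = flat_series("A", 2.0, 1.75)
    assert tides.interpolate_level([a], 40.0, 0) == 1.75


def test_uncovered_time_raises(flat_series):
    a = flat_series("A", 2.0, 1.0)
    with pytest.raises(CoverageError):
        tides.interpolate_level([a], 2.0, 10**9)


def test_no_stations_raises():
    with pytest.raises(CoverageError):
        tides.interpolate_level([], 0.0, 0)


@settings(max_examples=100, deadline=None)
@given(
    c1=st.floats(0, 50), dc=st.floats(0.1, 50), frac=st.floats(0.01, 0.99),
    l1=st.floats(-2, 8), l2=st.floats(-2, 8),
)
def test_interpolation_bounded_by_station_levels(c1, dc, frac, l1, l2):
    t = np.array([0, 600], dtype=np.int64)
    a = WaterLevelSeries("A", c1, t, np.full(2, l1))
    b = WaterLevelSeries("B", c1 + dc, t, np.full(2, l2))
    got = tides.interpolate_level([a, b], c1 + frac * dc, 0)
    assert min(l1, l2) - 1e-9 <= got <= max(l1, l2) + 1e-9


# -- segmentation ----------------------------------------------------------


def test_symmetric_tide_durations(symmetric_tide):
    ann = tides.segment_phases(symmetric_tide)
    for iv in ann.intervals:
        if not iv.truncated:
            assert abs((iv.end - iv.start) / 3600.0 - 6.2) <= 10 / 60 + 1e-9


def test_asymmetric_tide_durations(asymmetric_tide):
    cs = tides.cycle_stats(tides.segment_phases(asymmetric_tide))
    assert cs.ebb_mean_h == pytest.approx(0.677 * 12.4, abs=10 / 60)
    assert cs.flood_mean_h == pytest.approx(0.323 * 12.4, abs=10 / 60)


def test_boom_like_tide():
    cfg = synthetic_data.SimConfig(
        seed=2, duration_days=10.0, ebb_frac_mouth=0.573, ebb_frac_upstream=0.573,
        station_chainages=(50.0,), tide_noise_sigma=0.0,
    )
    s = synthetic_data.simulate_tides(cfg)[0]
    cs = tides.cycle_stats(tides.segment_phases(s))
    assert cs.ebb_mean_h == pytest.approx(7.105, abs=10 / 60)
    assert cs.flood_mean_h == pytest.approx(5.295, abs=10 / 60)


def test_monotone_ramp_raises():
    t = np.arange(0, 86400, 600, dtype=np.int64)
    s = WaterLevelSeries("ramp", 10.0, t, np.linspace(0, 5, t.size))
    with pytest.raises(SchemaError):
        tides.segment_phases(s)


def test_partition_and_alternation(symmetric_tide):
    ann = tides.segment_phases(symmetric_tide)
    ivs = ann.intervals
    for a, b in zip(ivs[:-1], ivs[1:]):
        assert a.end == b.start  # abut exactly
        assert a.phase != b.phase  # alternate


def test_ebb_starts_at_high_water(symmetric_tide):
    ann = tides.segment_phases(symmetric_tide)
    levels = dict(zip(symmetric_tide.times.tolist(), symmetric_tide.levels.tolist()))
    for iv in ann.intervals:
        if iv.phase == tides.EBB and not iv.truncated:
            assert iv.hw_time == iv.start
            # start level is a local max of the raw series
            assert levels[iv.start] >= levels[iv.start + 600]


def test_phase_at_high_water_is_ebb_zero(symmetric_tide):
    ann = tides.segment_phases(symmetric_tide)
    hw = next(iv for iv in ann.intervals if iv.phase == tides.EBB and not iv.truncated)
    phase, hsh = ann.phase_at(hw.start)
    assert phase == tides.EBB
    assert hsh == 0.0


def test_phase_at_flood_keeps_counting_from_hw(asymmetric_tide):
    ann = tides.segment_phases(asymmetric_tide)
    ebb = next(iv for iv in ann.intervals if iv.phase == tides.EBB and not iv.truncated)
    t = ebb.hw_time + int(10.0 * 3600)  # past the ~8.4 h ebb, into flood
    phase, hsh = ann.phase_at(t)
    assert phase == tides.FLOOD
    assert hsh == pytest.approx(10.0, abs=1e-9)


def test_phase_at_outside_span_raises(symmetric_tide):
    ann = tides.segment_phases(symmetric_tide)
    with pytest.raises(CoverageError):
        ann.phase_at(ann.start - 86400)


def test_cycle_stats_conservation(asymmetric_tide):
    cs = tides.cycle_stats(tides.segment_phases(asymmetric_tide))
    assert cs.ebb_mean_h + cs.flood_mean_h == pytest.approx(cs.cycle_mean_h, abs=0.2)
    assert cs.cycle_mean_h == pytest.approx(12.4, abs=10 / 60)
    assert cs.ebb_sd_h <= 10 / 60 + 1e-9  # deterministic tide


def test_cycle_stats_needs_two_cycles():
    cfg = synthetic_data.SimConfig(
        seed=2, duration_days=0.8, station_chainages=(50.0,), tide_noise_sigma=0.0
    )
    s = synthetic_data.simulate_tides(cfg)[0]
    with pytest.raises(SchemaError):
        tides.cycle_stats(tides.segment_phases(s))


def test_truncated_intervals_excluded_from_stats(symmetric_tide):
    ann = tides.segment_phases(symmetric_tide)
    assert any(iv.truncated for iv in ann.intervals)
    cs = tides.cycle_stats(ann)
    complete = [iv for iv in ann.intervals if not iv.truncated]
    n_ebb = sum(1 for iv in complete if iv.phase == tides.EBB)
    assert cs.n_cycles <= n_ebb


def test_annotate_receivers_unavailable_outside_tidal_zone(dataset):
    anns = tides.annotate_receivers(
        dataset.water_level_series(), dataset.receivers, dataset.config
    )
    rx = dataset.receivers.set_index("receiver_id")
    for rid, ann in anns.items():
        if rx.loc[rid, "zone"] == "tidal":
            assert ann is not None
        else:
            assert ann is None
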