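import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebbtrack import selectivity
from ebbtrack.tides import TidalCycleStats


def _cs(ebb_h, flood_h):
    return TidalCycleStats(ebb_h, 0.1, flood_h, 0.1, ebb_h + flood_h, 0.1, 10)


def test_props_from_durations_single_date():
    # 12 h day / 10.5 h night / 1.5 h twilight -> direct division by 24
    props = selectivity.props_from_durations([[12.0, 10.5, 1.5]])
    assert props == pytest.approx([0.5, 0.4375, 0.0625])


def test_props_weighted_mean_three_to_one():
    a = [12.0, 10.0, 2.0]
    b = [8.0, 14.0, 2.0]
    props = selectivity.props_from_durations([a, a, a, b])
    want = 0.75 * np.array(a) / 24 + 0.25 * np.array(b) / 24
    assert props == pytest.approx(want)


def test_props_sum_to_one_random():
    rng = np.random.default_rng(0)
    rows = rng.uniform(0.5, 12, (20, 3))
    assert selectivity.props_from_durations(rows).sum() == pytest.approx(1.0, abs=1e-12)


def test_expected_tidal_props_antwerp_like():
    # single receiver, ebb 6.9 h / flood 5.5 h -> ebb prop = 6.9 / 12.4
    ev = pd.DataFrame({"receiver_id": ["R1"] * 5, "departure_tidal": ["ebb"] * 5})
    props = selectivity.expected_tidal_props(ev, "departure", {"R1": _cs(6.9, 5.5)})
    assert props[0] == pytest.approx(6.9 / 12.4, abs=1e-12)
    assert props[0] == pytest.approx(0.5565, abs=5e-4)


def test_expected_tidal_props_receiver_weighted():
    # ebb fractions 0.55 and 0.65 weighted 1:3 -> 0.625
    cstats = {"A": _cs(5.5, 4.5), "B": _cs(6.5, 3.5)}
    ev = pd.DataFrame(
        {"receiver_id": ["A", "B", "B", "B"], "departure_tidal": ["ebb"] * 4}
    )
    props = selectivity.expected_tidal_props(ev, "departure", cstats)
    assert props[0] == pytest.approx(0.625, abs=1e-12)


def test_expected_tidal_props_symmetric():
    ev = pd.DataFrame({"receiver_id": ["R1"], "arrival_tidal": ["flood"]})
    props = selectivity.expected_tidal_props(ev, "arrival", {"R1": _cs(6.2, 6.2)})
    assert props == pytest.approx([0.5, 0.5])


def test_gof_perfect_fit():
    res = selectivity.gof_test([50, 30, 20], [0.5, 0.3, 0.2])
    assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_gof_hand_example():
    # chi2 = 100/50 + 25/30 + 25/20 = 4.0833...
    res = selectivity.gof_test([60, 25, 15], [0.5, 0.3, 0.2])
    assert res["chi2"] == pytest.approx(100 / 50 + 25 / 30 + 25 / 20, abs=1e-12)
    assert res["df"] == 2


def test_gof_two_phases_df1():
    res = selectivity.gof_test([100, 51], [0.55, 0.45])
    assert res["df"] == 1


def test_gof_zero_expected_rejected():
    with pytest.raises(ValueError):
        selectivity.gof_test([10, 5], [1.0, 0.0])


@settings(max_examples=200, deadline=None)
@given(
    obs=st.lists(st.integers(1, 200), min_size=2, max_size=6),
    raw=st.lists(st.floats(0.05, 1.0), min_size=6, max_size=6),
)
def test_gof_matches_direct_formula(obs, raw):
    k = len(obs)
    props = np.array(raw[:k])
    props = props / props.sum()
    res = selectivity.gof_test(obs, props)
    n = sum(obs)
    want = sum((o - n * p) ** 2 / (n * p) for o, p in zip(obs, props))
    assert res["chi2"] == pytest.approx(want, abs=1e-10)


def test_props_invariant_to_order_and_duplication():
    cstats = {"A": _cs(5.5, 4.5), "B": _cs(6.5, 3.5)}
    ev = pd.DataFrame(
        {"receiver_id": ["A", "B", "B"], "arrival_tidal": ["ebb", "flood", "ebb"]}
    )
    p1 = selectivity.expected_tidal_props(ev, "arrival", cstats)
    p2 = selectivity.expected_tidal_props(ev.iloc[::-1], "arrival", cstats)
    p3 = selectivity.expected_tidal_props(pd.concat([ev, ev]), "arrival", cstats)
    assert p1 == pytest.approx(p2)
    assert p1 == pytest.approx(p3)


def _toy_events():
    rows = []
    t0 = pd.Timestamp("2020-11-10T00:00Z")
    for i, (zone, rid) in enumerate(
        [("non_tidal", "RN"), ("transition", "RX"), ("tidal", "RT")]
    ):
        for k in range(6):
            t = t0 + pd.Timedelta(hours=3 * k + i)
            rows.append(
                {
                    "tag_id": f"T{k}",
                    "receiver_id": rid,
                    "zone": zone,
                    "arrival_t": t,
                    "departure_t": t + pd.Timedelta(hours=1),
                    "arrival_circadian": ["day", "night", "twilight"][k % 3],
                    "departure_circadian": ["day", "night", "twilight"][(k + 1) % 3],
                    "arrival_tidal": ("ebb" if k % 2 else "flood") if zone == "tidal" else "unavailable",
                    "departure_tidal": ("ebb" if k % 2 else "flood") if zone == "tidal" else "unavailable",
                    "arrival_hsh": 0.5 * k if zone == "tidal" else np.nan,
                    "departure_hsh": 0.5 * k if zone == "tidal" else np.nan,
                    "n_detections": 2,
                }
            )
    return pd.DataFrame(rows)


def _toy_receivers():
    return pd.DataFrame(
        {
            "receiver_id": ["RN", "RX", "RT"],
            "lat": [51.15, 51.2, 51.3],
            "lon": [4.8, 4.6, 4.1],
            "chainage_km": [150.0, 130.0, 60.0],
            "zone": ["non_tidal", "transition", "tidal"],
        }
    )


def test_run_selectivity_emits_eight_tests():
    res = selectivity.run_selectivity(
        _toy_events(), _toy_receivers(), {"RT": _cs(6.9, 5.5)}
    )
    assert len(res) == 8
    strata = [(r.event_type, r.stratum) for r in res]
    assert ("arrival", "tidal_pooled") in strata
    assert ("departure", "non_tidal") in strata
    circ = [r for r in res if r.stratum != "tidal_pooled"]
    assert all(r.df == len(r.phases) - 1 for r in circ if r.n > 0)
    tidal = [r for r in res if r.stratum == "tidal_pooled"]
    assert all(r.df == 1 for r in tidal if r.n > 0)
    for r in res:
        if r.n > 0:
            assert sum(r.observed) == r.n
            assert sum(r.expected_props) == pytest.approx(1.0, abs=1e-9)


def test_run_selectivity_empty_stratum_skipped():
    ev = _toy_events()
    ev = ev[ev["zone"] != "transition"]
    res = selectivity.run_selectivity(ev, _toy_receivers(), {"RT": _cs(6.9, 5.5)})
    skipped = [r for r in res if r.stratum == "transition"]
    assert len(skipped) == 2
    assert all(r.n == 0 and not r.significant for r in skipped)


def test_rose_bins_diel():
    ev = _toy_events()
    bins = selectivity.rose_bins(ev, "diel")
    assert bins["count"].sum() == 2 * len(ev)
    ev1 = ev.iloc[:1].copy()
    ev1["arrival_t"] = pd.Timestamp("2020-11-10T13:20Z")
    b1 = selectivity.rose_bins(ev1, "diel")
    row = b1[(b1["event_type"] == "arrival") & (b1["bin_start"] == 13.0)]
    assert int(row["count"].iloc[0]) == 1


def test_rose_bins_tidal():
    ev = _toy_events()
    bins = selectivity.rose_bins(ev, "tidal")
    n_tidal = (ev["arrival_tidal"] != "unavailable").sum()
    assert bins[bins["event_type"] == "arrival"]["count"].sum() == n_tidal
    ev1 = ev[ev["zone"] == "tidal"].iloc[1:2].copy()
    ev1["arrival_hsh"] = 0.4
    b1 = selectivity.rose_bins(ev1, "tidal")
    row = b1[(b1["event_type"] == "arrival") & (b1["bin_start"] == 0.0)]
    assert int(row["count"].iloc[0]) == 1


def test_rose_bins_bad_mode():
    with pytest.raises(ValueError):
        selectivity.rose_bins(_toy_events(), "lunar")


def test_holm_correction_flag():
    from ebbtrack.core_data import AnalysisConfig

    cfg = AnalysisConfig(multiple_testing=True)
    res = selectivity.run_selectivity(
        _toy_events(), _toy_receivers(), {"RT": _cs(6.9, 5.5)}, cfg
    )
    tested = [r for r in res if r.n > 0]
    assert all(r.p_adj is not None for r in tested)
    assert all(r.p_adj >= r.p - 1e-15 for r in tested)  # adjustment never lowers p
    # uncorrected run leaves p_adj unset
    res0 = selectivity.run_selectivity(_toy_events(), _toy_receivers(), {"RT": _cs(6.9, 5.5)})
    assert all(r.p_adj is None for r in res0)
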