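import filecmp

import numpy as np
import pandas as pd
import pytest

from ebbtrack import solar, synthetic_data
from ebbtrack.core_data import ConfigError


def _cfg(**kw):
    base = dict(seed=3, duration_days=10.0, station_chainages=(50.0,))
    base.update(kw)
    return synthetic_data.SimConfig(**base)


# -- config validation -----------------------------------------------------


@pytest.mark.parametrize("bad", [{"ebb_frac_mouth": 0.0}, {"ebb_frac_upstream": 1.0}])
def test_bad_ebb_fraction_rejected(bad):
    with pytest.raises(ConfigError):
        _cfg(**bad)


def test_bad_release_range_rejected():
    with pytest.raises(ConfigError):
        _cfg(release_chainage_range_km=(10.0, 500.0))


def test_bad_detection_range_rejected():
    with pytest.raises(ConfigError):
        _cfg(detection_range_m=50.0)


# -- tides -----------------------------------------------------------------


def test_symmetric_ebb_fraction_of_samples():
    cfg = _cfg(ebb_frac_mouth=0.5, ebb_frac_upstream=0.5)
    s = synthetic_data.simulate_tides(cfg)[0]
    falling = np.diff(s.levels) < 0
    assert abs(falling.mean() - 0.5) < 0.02


def test_asymmetric_ebb_fraction_of_samples():
    cfg = _cfg(ebb_frac_mouth=0.677, ebb_frac_upstream=0.677)
    s = synthetic_data.simulate_tides(cfg)[0]
    falling = np.diff(s.levels) < 0
    assert abs(falling.mean() - 0.677) < 0.02


def test_noise_free_turning_points_at_phase_boundaries():
    cfg = _cfg(tide_noise_sigma=0.0)
    s = synthetic_data.simulate_tides(cfg)[0]
    # phase 0 (series start) is an analytic high water: level = mean + amplitude
    assert s.levels[0] == pytest.approx(
        cfg.tide_mean_level + float(cfg.amplitude(50.0)), abs=1e-9
    )


# -- crabs -----------------------------------------------------------------


def test_nonselective_displacement_expectation():
    cfg = _cfg(
        behaviour={"tidal": "nonselective", "transition": "nonselective", "non_tidal": "nonselective"},
        base_speed_km_day={"tidal": 4.8, "transition": 4.8, "non_tidal": 4.8},
        speed_jitter_sigma=0.0,
        spawning_chainage_km=0.0,
        release_chainage_range_km=(60.0, 60.0),
        release_window_days=0.0,
        n_crabs=3,
    )
    _, traj = synthetic_data.simulate_crabs(cfg)
    for _, tr in traj.groupby("tag_id"):
        disp = tr["chainage_km"].iloc[0] - tr["chainage_km"].iloc[-1]
        assert disp == pytest.approx(48.0, abs=0.5)


def test_stst_long_run_speed_is_ebb_fraction_of_base():
    f = 0.6
    cfg = _cfg(
        duration_days=20.0,
        ebb_frac_mouth=f, ebb_frac_upstream=f,
        behaviour={"tidal": "stst", "transition": "stst", "non_tidal": "stst"},
        base_speed_km_day={"tidal": 5.0, "transition": 5.0, "non_tidal": 5.0},
        speed_jitter_sigma=0.0,
        spawning_chainage_km=0.0,
        release_chainage_range_km=(120.0, 120.0),
        release_window_days=0.0,
        n_crabs=2,
    )
    _, traj = synthetic_data.simulate_crabs(cfg)
    for _, tr in traj.groupby("tag_id"):
        days = (tr["t_epoch"].iloc[-1] - tr["t_epoch"].iloc[0]) / 86400.0
        realized = (tr["chainage_km"].iloc[0] - tr["chainage_km"].iloc[-1]) / days
        assert realized == pytest.approx(f * 5.0, rel=0.05)


def test_trajectory_monotone_and_conserved():
    cfg = _cfg(n_crabs=4)
    _, traj = synthetic_data.simulate_crabs(cfg)
    for _, tr in traj.groupby("tag_id"):
        c = tr["chainage_km"].to_numpy()
        steps = np.diff(c)
        assert (steps <= 1e-12).all()  # downstream-only
        assert c[0] - c[-1] == pytest.approx(-steps.sum())


def test_gate_fidelity_stst_never_moves_during_flood():
    cfg = _cfg(
        behaviour={"tidal": "stst", "transition": "stst", "non_tidal": "stst"},
        release_chainage_range_km=(100.0, 120.0),
        n_crabs=3,
    )
    _, traj = synthetic_data.simulate_crabs(cfg)
    for _, tr in traj.groupby("tag_id"):
        t = tr["t_epoch"].to_numpy()[:-1]
        c = tr["chainage_km"].to_numpy()
        moved = np.diff(c) < -1e-12
        phase = cfg.true_tidal_phase(t[moved], c[:-1][moved])
        assert (np.asarray(phase) == "ebb").all()
        # resting steps leave the position unchanged
        resting = ~tr["moving"].to_numpy()[:-1]
        assert np.all(np.diff(c)[resting] == 0.0)


def test_gate_fidelity_nocturnal_never_moves_during_day():
    cfg = _cfg(
        behaviour={"tidal": "nocturnal", "transition": "nocturnal", "non_tidal": "nocturnal"},
        release_chainage_range_km=(140.0, 160.0),
        n_crabs=3,
        start="2020-12-01T00:00:00Z",
    )
    _, traj = synthetic_data.simulate_crabs(cfg)
    for _, tr in traj.groupby("tag_id"):
        t = tr["t_epoch"].to_numpy()[:-1]
        c = tr["chainage_km"].to_numpy()
        moved = np.diff(c) < -1e-12
        lat, lon = cfg.latlon(c[:-1][moved])
        alt = solar.solar_altitude(t[moved], lat, lon)
        assert (np.asarray(alt) <= solar.DAY_SET_ALT).all()


def test_nocturnal_winter_displacement_mostly_dark():
    # December at ~51 N: most displacement accrues between sunset and sunrise
    cfg = _cfg(
        behaviour={"tidal": "nocturnal", "transition": "nocturnal", "non_tidal": "nocturnal"},
        release_chainage_range_km=(150.0, 160.0),
        n_crabs=2,
        start="2020-12-01T00:00:00Z",
        spawning_chainage_km=0.0,
    )
    _, traj = synthetic_data.simulate_crabs(cfg)
    tr = traj[traj["tag_id"] == "T01"]
    steps = -np.diff(tr["chainage_km"].to_numpy())
    t = tr["t_epoch"].to_numpy()[:-1]
    lat, lon = cfg.latlon(tr["chainage_km"].to_numpy()[:-1])
    alt = np.asarray(solar.solar_altitude(t, lat, lon))
    dark = alt <= solar.DAY_SET_ALT
    assert steps[dark].sum() / steps.sum() > 0.6


def test_movement_stops_at_spawning_chainage():
    cfg = _cfg(
        duration_days=30.0,
        behaviour={"tidal": "nonselective", "transition": "nonselective", "non_tidal": "nonselective"},
        base_speed_km_day={"tidal": 10.0, "transition": 10.0, "non_tidal": 10.0},
        spawning_chainage_km=40.0,
        release_chainage_range_km=(60.0, 70.0),
        n_crabs=2,
    )
    _, traj = synthetic_data.simulate_crabs(cfg)
    assert traj["chainage_km"].min() >= 40.0 - 1e-9
    last = traj.groupby("tag_id")["chainage_km"].last()
    assert np.allclose(last, 40.0)


# -- detections ------------------------------------------------------------


def _stationary_world(p_det=1.0, offset_km=0.15):
    cfg = synthetic_data.SimConfig(
        seed=9, duration_days=1.0 / 24.0, station_chainages=(50.0,),
        n_crabs=1, n_sensor_crabs=0, p_det=p_det,
        release_chainage_range_km=(30.0 + offset_km, 30.0 + offset_km),
        release_window_days=0.0,
        behaviour={"tidal": "stst", "transition": "stst", "non_tidal": "stst"},
        base_speed_km_day={"tidal": 0.001, "transition": 0.001, "non_tidal": 0.001},
    )
    receivers = pd.DataFrame(
        {"receiver_id": ["R01"], "lat": [51.3], "lon": [4.2],
         "chainage_km": [30.0], "zone": ["tidal"]}
    )
    crabs, traj = synthetic_data.simulate_crabs(cfg)
    return cfg, receivers, crabs, traj


def test_stationary_crab_detection_count():
    # 1 h of pings every 90-150 s, 150 m from a 500 m-range receiver
    cfg, receivers, crabs, traj = _stationary_world()
    det = synthetic_data.simulate_detections(traj, receivers, crabs, cfg)
    assert 24 <= len(det) <= 40


def test_out_of_range_crab_undetected():
    cfg, receivers, crabs, traj = _stationary_world(offset_km=2.0)
    det = synthetic_data.simulate_detections(traj, receivers, crabs, cfg)
    assert len(det) == 0


def test_p_det_zero_yields_empty_table():
    cfg, receivers, crabs, traj = _stationary_world(p_det=0.0)
    det = synthetic_data.simulate_detections(traj, receivers, crabs, cfg)
    assert len(det) == 0


def test_empty_receiver_list_rejected():
    cfg, receivers, crabs, traj = _stationary_world()
    with pytest.raises(ConfigError):
        synthetic_data.simulate_detections(traj, receivers.iloc[:0], crabs, cfg)


def test_sensor_payload_only_for_sensor_tags(dataset):
    sensors = set(dataset.crabs.loc[dataset.crabs["sensor_tag"], "tag_id"])
    det = dataset.detections
    with_payload = det[det["accel_ms2"].notna() | det["depth_m"].notna()]
    assert set(with_payload["tag_id"]) <= sensors
    no_payload = det[~det["tag_id"].isin(sensors)]
    assert no_payload["accel_ms2"].isna().all()


# -- fixtures --------------------------------------------------------------


def test_fixture_determinism(tmp_path):
    a = tmp_path / "a"
    b = tmp_path / "b"
    for d in (a, b):
        synthetic_data.make_fixture(d, seed=7, profile="small", duration_days=5.0)
    for name in ("detections.csv", "receivers.csv", "crabs.csv", "waterlevels.csv",
                 "truth_trajectories.csv"):
        assert filecmp.cmp(a / name, b / name, shallow=False), name


def test_different_seeds_differ(tmp_path):
    a = tmp_path / "a"
    b = tmp_path / "b"
    synthetic_data.make_fixture(a, seed=7, profile="small", duration_days=5.0)
    synthetic_data.make_fixture(b, seed=8, profile="small", duration_days=5.0)
    assert (a / "detections.csv").read_bytes() != (b / "detections.csv").read_bytes()


def test_paper_like_profile_shape(tmp_path):
    cfg = synthetic_data.profile_config(1, "paper_like")
    assert cfg.duration_days == pytest.approx(90.0)
    assert cfg.n_crabs == 10
    assert cfg.n_sensor_crabs >= 1


def test_true_events_match_trajectory_crossings():
    cfg = _cfg(
        n_crabs=2,
        behaviour={"tidal": "nonselective", "transition": "nonselective", "non_tidal": "nonselective"},
        base_speed_km_day={"tidal": 8.0, "transition": 8.0, "non_tidal": 8.0},
        release_chainage_range_km=(55.0, 60.0),
        spawning_chainage_km=2.0,
    )
    receivers = synthetic_data.default_receivers(cfg)
    _, traj = synthetic_data.simulate_crabs(cfg)
    ev = synthetic_data.true_events(traj, receivers, cfg.detection_range_m)
    assert (ev["arrival_t"] <= ev["departure_t"]).all()
    # a moving crab passes receivers in decreasing-chainage order
    chain = receivers.set_index("receiver_id")["chainage_km"]
    for _, sub in ev.groupby("tag_id"):
        c = sub.sort_values("arrival_t")["receiver_id"].map(chain).to_numpy()
        assert (np.diff(c) < 0).all()
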