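"""Property-based acceptance checks, each runnable standalone.

Every runner exercises the package's public path end to end (simulate ->
annotate -> test/fit) and returns a metrics dict; thresholds are asserted
by the caller. Oracles used for exactness checks are deliberately
independent re-derivations (brute-force formulas, a separate ephemeris
formulation) rather than calls into the code under test.
"""

from __future__ import annotations

import filecmp
import math
from pathlib import Path

import numpy as np
import pandas as pd

from ebbtrack import events as events_mod
from ebbtrack import inference, kinematics, selectivity, synthetic_data, tides
from ebbtrack.core_data import AnalysisConfig, WaterLevelSeries
from ebbtrack.pipeline import run_pipeline
from ebbtrack import solar


# --------------------------------------------------------------------------
# shared setup for the event-selectivity criteria


def _selectivity_world(seed: int, mode: str, base_speed: float, duration_days: float):
    """Fixed tidal river with irregular receiver spacing; crabs vary per rep."""
    rng = np.random.default_rng([seed, 100])
    chain = np.linspace(8.0, 110.0, 10) + rng.uniform(-3.5, 3.5, 10)
    config = synthetic_data.SimConfig(
        seed=seed,
        duration_days=duration_days,
        receiver_chainages=tuple(np.round(np.sort(chain), 3)),
        station_chainages=(20.0, 100.0),
        behaviour={"tidal": mode, "transition": mode, "non_tidal": mode},
        base_speed_km_day={"tidal": base_speed, "transition": base_speed, "non_tidal": base_speed},
        speed_jitter_sigma=0.8,
        speed_jitter_tau_h=10.0,
        spawning_chainage_km=2.0,
        release_chainage_range_km=(110.0, 124.0),
        release_window_days=8.0,
        n_crabs=15,
        n_sensor_crabs=0,
    )
    receivers = synthetic_data.default_receivers(config)
    series = synthetic_data.simulate_tides(config)
    acfg = AnalysisConfig()
    annotations = tides.annotate_receivers(series, receivers, acfg)
    cstats = {rid: tides.cycle_stats(a) for rid, a in annotations.items() if a is not None}
    return config, receivers, annotations, cstats


def _tidal_departure_test(config, receivers, annotations, cstats, alpha=0.05):
    crabs, traj = synthetic_data.simulate_crabs(config)
    ev = synthetic_data.true_events(traj, receivers, config.detection_range_m)
    ann = events_mod.annotate_events(ev, receivers, annotations)
    sub = ann[ann["departure_tidal"] != tides.UNAVAILABLE]
    props = selectivity.expected_tidal_props(sub, "departure", cstats)
    obs = np.array(
        [int((sub["departure_tidal"] == ph).sum()) for ph in selectivity.TIDAL_PHASES]
    )
    res = selectivity.gof_test(obs, props, alpha=alpha)
    res["observed_ebb_prop"] = float(obs[0] / obs.sum())
    res["expected_ebb_prop"] = float(props[0])
    return res


def run_null_calibration(seed: int, n_reps: int = 500) -> dict:
    """Criterion 1: type-I error of the tidal GOF test under nonselective migration."""
    config, receivers, annotations, cstats = _selectivity_world(
        seed, "nonselective", base_speed=8.0, duration_days=22.0
    )
    rejections = 0
    ns = []
    for rep in range(n_reps):
        cfg = synthetic_data.SimConfig(**{**config.to_dict(), "seed": seed * 100003 + rep})
        res = _tidal_departure_test(cfg, receivers, annotations, cstats)
        rejections += int(res["significant"])
        ns.append(res["n"])
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "mean_events": float(np.mean(ns)),
    }


def run_stst_power(seed: int, n_reps: int = 200) -> dict:
    """Criterion 2: power and effect direction under a pure ebb gate."""
    config, receivers, annotations, cstats = _selectivity_world(
        seed, "stst", base_speed=13.0, duration_days=22.0
    )
    rejections = 0
    excess = 0
    ns = []
    for rep in range(n_reps):
        cfg = synthetic_data.SimConfig(**{**config.to_dict(), "seed": seed * 100019 + rep})
        res = _tidal_departure_test(cfg, receivers, annotations, cstats)
        rejections += int(res["significant"])
        excess += int(res["observed_ebb_prop"] > res["expected_ebb_prop"])
        ns.append(res["n"])
    return {
        "rejection_rate": rejections / n_reps,
        "ebb_excess_rate": excess / n_reps,
        "n_reps": n_reps,
        "mean_events": float(np.mean(ns)),
    }


def run_tide_segmentation(seed: int) -> dict:
    """Criterion 3: recovered ebb/flood durations on noise-free distorted tides."""
    out = {}
    for f in (0.50, 0.573, 0.677):
        cfg = synthetic_data.SimConfig(
            seed=seed,
            duration_days=10.0,
            ebb_frac_mouth=f,
            ebb_frac_upstream=f,
            station_chainages=(50.0,),
            tide_noise_sigma=0.0,
        )
        series = synthetic_data.simulate_tides(cfg)[0]
        cs = tides.cycle_stats(tides.segment_phases(series))
        out[f] = {
            "ebb_mean_h": cs.ebb_mean_h,
            "flood_mean_h": cs.flood_mean_h,
            "ebb_err_min": (cs.ebb_mean_h - f * cfg.tide_period_h) * 60.0,
            "flood_err_min": (cs.flood_mean_h - (1 - f) * cfg.tide_period_h) * 60.0,
        }
    return out


def run_exactness(seed: int, n_instances: int = 1000) -> dict:
    """Criterion 4: agreement with brute-force oracles to 1e-9."""
    rng = np.random.default_rng([seed, 4])
    t0 = 1_600_000_000 // 600 * 600

    max_err_interp = 0.0
    for _ in range(n_instances):
        c1, c2 = np.sort(rng.uniform(0.0, 100.0, 2))
        target = rng.uniform(c1 + 1e-3, c2 - 1e-3) if c2 - c1 > 2e-3 else c1
        l1, l2 = rng.uniform(-1.0, 5.0, 2)
        ser = [
            WaterLevelSeries("A", c1, np.array([t0, t0 + 600]), np.array([l1, l1])),
            WaterLevelSeries("B", c2, np.array([t0, t0 + 600]), np.array([l2, l2])),
        ]
        got = tides.interpolate_level(ser, target, t0)
        d1, d2 = abs(c1 - target), abs(c2 - target)
        if d1 == 0.0:
            want = l1
        else:
            w1, w2 = 1.0 / d1, 1.0 / d2
            want = (w1 * l1 + w2 * l2) / (w1 + w2)
        max_err_interp = max(max_err_interp, abs(got - want))

    max_err_chi2 = 0.0
    for _ in range(n_instances):
        k = int(rng.integers(2, 6))
        obs = rng.integers(1, 60, k).astype(float)
        props = rng.uniform(0.1, 1.0, k)
        props = props / props.sum()
        res = selectivity.gof_test(obs, props)
        n = obs.sum()
        want = sum((o - n * p) ** 2 / (n * p) for o, p in zip(obs, props))
        max_err_chi2 = max(max_err_chi2, abs(res["chi2"] - want))

    max_err_speed = 0.0
    acfg = AnalysisConfig()
    for _ in range(n_instances):
        n_ev = int(rng.integers(2, 6))
        chain = rng.uniform(0.0, 160.0, n_ev)
        receivers = pd.DataFrame(
            {
                "receiver_id": [f"R{i}" for i in range(n_ev)],
                "lat": 51.2,
                "lon": 4.4,
                "chainage_km": chain,
                "zone": [acfg.zone_of(c) for c in chain],
            }
        )
        times = t0 + np.sort(rng.integers(0, 10 * 86400, 2 * n_ev))
        ev = pd.DataFrame(
            {
                "tag_id": "T1",
                "receiver_id": [f"R{i}" for i in range(n_ev)],
                "arrival_t": pd.to_datetime(times[0::2], unit="s", utc=True),
                "departure_t": pd.to_datetime(times[1::2], unit="s", utc=True),
                "n_detections": 1,
            }
        )
        got_df = kinematics.migration_speeds(ev, receivers, acfg)
        want_rows = []
        for i in range(n_ev - 1):
            if chain[i] == chain[i + 1]:
                continue
            dist = abs(chain[i + 1] - chain[i])
            elapsed = (times[2 * (i + 1)] - times[2 * i + 1]) / 86400.0
            if elapsed <= 0:
                continue
            want_rows.append(dist / elapsed)
        got = got_df["speed_km_day"].to_numpy()
        if len(got) != len(want_rows):
            raise AssertionError("speed oracle row-count mismatch")
        if want_rows:
            max_err_speed = max(
                max_err_speed, float(np.max(np.abs(got - np.array(want_rows))))
            )
    return {
        "max_err_interp": max_err_interp,
        "max_err_chi2": max_err_chi2,
        "max_err_speed": max_err_speed,
        "n_instances": n_instances,
    }


def run_accel_recovery(seed: int, n_reps: int = 100) -> dict:
    """Criterion 5: mixed-model recovery of the ebb/flood acceleration ratio."""
    true_ratio = 0.25 / 0.11
    log_true = math.log(true_ratio)
    ratios, covered, retained = [], 0, 0
    for rep in range(n_reps):
        obs = synthetic_data.make_sensor_fixture(seed=seed * 100057 + rep)
        crabs = obs[["tag_id", "sex"]].drop_duplicates()
        fr = inference.fit_acceleration_models(obs, crabs)["tidal"]
        has_tidal = any("C(tidal)" in t for t in fr.retained_terms)
        retained += int(has_tidal)
        if not has_tidal:
            continue
        row = fr.contrasts[
            (fr.contrasts["factor"] == "tidal") & (fr.contrasts["contrast"] == "ebb - flood")
        ]
        if row.empty:
            lev = fr.group_means[fr.group_means["factor"] == "tidal"].set_index("level")
            est = float(
                lev.loc["ebb", "mean_log"] - lev.loc["flood", "mean_log"]
            )
            se = float("nan")
        else:
            est = float(row["estimate"].iloc[0])
            se = float(row["se"].iloc[0])
        ratios.append(math.exp(est))
        if np.isfinite(se) and abs(est - log_true) <= inference.Z975 * se:
            covered += 1
    return {
        "true_ratio": true_ratio,
        "mean_ratio": float(np.mean(ratios)),
        "ci_coverage": covered / max(len(ratios), 1),
        "retained_rate": retained / n_reps,
        "n_reps": n_reps,
    }


def run_speed_recovery(seed: int, n_reps: int = 100) -> dict:
    """Criterion 6: Tukey contrasts of the speed model under known zone means."""
    sig_tidal = 0
    sig_null = 0
    for rep in range(n_reps):
        sp = synthetic_data.make_speed_fixture(seed=seed * 100069 + rep)
        crabs = sp[["tag_id", "sex"]].drop_duplicates()
        fr = inference.fit_speed_model(sp, crabs)
        ct = fr.contrasts[fr.contrasts["factor"] == "zone"].set_index("contrast")
        if "non_tidal - tidal" in ct.index and ct.loc["non_tidal - tidal", "p"] < 0.05:
            sig_tidal += 1
        if (
            "non_tidal - transition" in ct.index
            and ct.loc["non_tidal - transition", "p"] < 0.05
        ):
            sig_null += 1
    return {
        "tidal_contrast_power": sig_tidal / n_reps,
        "null_contrast_rate": sig_null / n_reps,
        "n_reps": n_reps,
    }


# --------------------------------------------------------------------------
# independent solar oracle (Astronomical Almanac low-precision formulation:
# right ascension + sidereal time, no equation-of-time shortcut)


def oracle_solar_altitude(t_epoch, lat: float, lon: float):
    t = np.asarray(t_epoch, dtype=float)
    n = t / 86400.0 + 2440587.5 - 2451545.0
    L = np.mod(280.460 + 0.9856474 * n, 360.0)
    g = np.deg2rad(np.mod(357.528 + 0.9856003 * n, 360.0))
    lam = np.deg2rad(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.deg2rad(23.439 - 0.0000004 * n)
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    dec = np.arcsin(np.sin(eps) * np.sin(lam))
    gmst_h = np.mod(18.697374558 + 24.06570982441908 * n, 24.0)
    ha = np.deg2rad(gmst_h * 15.0 + lon) - ra
    phi = np.deg2rad(lat)
    alt = np.arcsin(np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(ha))
    return np.rad2deg(alt)


def _oracle_crossings(day, lat, lon, threshold):
    start = int(pd.Timestamp(day, tz="UTC").value // 10**9)
    grid = start + 60 * np.arange(1441)
    f = oracle_solar_altitude(grid, lat, lon) - threshold
    idx = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    # linear interpolation within the minute is plenty at these slopes
    return [float(grid[i] - 60.0 * f[i] / (f[i + 1] - f[i])) for i in idx]


def run_solar_partition(seed: int, lat: float = 51.2, lon: float = 4.4) -> dict:
    """Criterion 7: daily partition, midsummer night=0, oracle crossing agreement."""
    days = pd.date_range("2020-10-01", "2021-08-31", freq="D")
    max_partition_err_s = 0.0
    max_crossing_err_s = 0.0
    n_crossings = 0
    june_nights = []
    for day in days:
        d = solar.phase_durations(day, lat, lon)
        max_partition_err_s = max(
            max_partition_err_s, abs((d.day_h + d.night_h + d.twilight_h) - 24.0) * 3600.0
        )
        if pd.Timestamp("2021-06-14") <= day <= pd.Timestamp("2021-06-28"):
            june_nights.append(d.night_h)
        for thr in (solar.DAY_SET_ALT, solar.NIGHT_SET_ALT):
            got = solar.threshold_crossings(day.date(), lat, lon, thr)
            want = _oracle_crossings(day.date(), lat, lon, thr)
            if len(got) != len(want):
                raise AssertionError(f"crossing count mismatch on {day.date()} thr={thr}")
            for g, w in zip(got, want):
                n_crossings += 1
                max_crossing_err_s = max(max_crossing_err_s, abs(g - w))
    return {
        "max_partition_err_s": max_partition_err_s,
        "max_crossing_err_s": max_crossing_err_s,
        "n_days": len(days),
        "n_crossings": n_crossings,
        "max_june_night_h": float(max(june_nights)),
    }


def run_determinism(seed: int, workdir: str | Path) -> dict:
    """Criterion 8: byte-identical outputs for identical seed/config."""
    workdir = Path(workdir)
    paths = {}
    for run in ("a", "b"):
        data = workdir / f"data_{run}"
        out = workdir / f"out_{run}"
        synthetic_data.make_fixture(data, seed=seed, profile="small", duration_days=10.0)
        run_pipeline(data, out, AnalysisConfig(seed=seed))
        paths[run] = (data, out)
    mismatches = []
    for sub in (0, 1):
        a_dir, b_dir = paths["a"][sub], paths["b"][sub]
        names = sorted(p.name for p in a_dir.iterdir() if p.suffix in {".csv", ".json", ".txt"})
        names_b = sorted(p.name for p in b_dir.iterdir() if p.suffix in {".csv", ".json", ".txt"})
        if names != names_b:
            mismatches.append(f"file sets differ: {names} vs {names_b}")
            continue
        for name in names:
            if not filecmp.cmp(a_dir / name, b_dir / name, shallow=False):
                mismatches.append(str(a_dir / name))
    return {"identical": not mismatches, "mismatches": mismatches, "n_files_compared": len(names) * 2}
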