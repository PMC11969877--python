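"""Synthetic river / tide / crab / detection simulator with known ground truth.

Geometry is a 1-D chainage axis (km upstream from the estuarine mouth,
default 166 km) split into a tidal zone (< 125 km), a micro-tidal
transition zone (125-136 km) and non-tidal headwaters (>= 136 km). Tides
are piecewise-sinusoidal distorted so the falling (ebb) limb occupies a
configurable fraction of the period, increasing upstream. Crabs step
downstream at a zone-dependent base speed whenever their behavioural
gate is open (``nonselective``, ``nocturnal``, ``stst`` = ebb-selective,
or ``nocturnal+stst``) and stop permanently at the spawning chainage.
Receivers log tag pings within a configurable along-channel range.

Behavioural gates are evaluated against the simulator's own analytic
phases, not the analysis pipeline's annotations, so recovery tests are
non-circular.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ebbtrack import solar
from ebbtrack.core_data import ConfigError, WaterLevelSeries

MODES = ("nonselective", "nocturnal", "stst", "nocturnal+stst")


@dataclass
class SimConfig:
    """Full parameterization of river, tide, behaviour and detection."""

    seed: int = 0
    start: str = "2020-10-05T00:00:00Z"
    duration_days: float = 30.0
    step_minutes: int = 10

    river_length_km: float = 166.0
    tidal_max_km: float = 125.0
    transition_max_km: float = 136.0

    n_receivers: int = 20
    receiver_chainages: tuple[float, ...] | None = None
    station_chainages: tuple[float, ...] = (20.0, 100.0)

    tide_period_h: float = 12.4
    tide_mean_level: float = 2.0
    amp_mouth_m: float = 2.5
    amp_tidal_max_m: float = 1.0
    amp_transition_m: float = 0.5
    ebb_frac_mouth: float = 0.508
    ebb_frac_upstream: float = 0.677
    tide_lag_h_per_km: float = 0.0
    tide_noise_sigma: float = 0.0

    behaviour: dict = field(
        default_factory=lambda: {
            "non_tidal": "nocturnal",
            "transition": "nocturnal",
            "tidal": "stst",
        }
    )
    base_speed_km_day: dict = field(
        default_factory=lambda: {"non_tidal": 4.65, "transition": 4.71, "tidal": 1.29}
    )
    speed_jitter_sigma: float = 0.3
    speed_jitter_tau_h: float = 24.0  # jitter redrawn per tau-block, not per step
    spawning_chainage_km: float = 45.0

    n_crabs: int = 10
    n_sensor_crabs: int = 2
    release_chainage_range_km: tuple[float, float] = (60.0, 160.0)
    release_window_days: float = 5.0

    detection_range_m: float = 500.0
    p_det: float = 1.0
    ping_min_s: float = 90.0
    ping_max_s: float = 150.0

    accel_moving: float = 0.25
    accel_resting: float = 0.11
    accel_noise_sigma: float = 0.3
    depth_noise_sigma: float = 0.05

    # coordinate anchors: (chainage 0) -> (river_length)
    anchor_mouth: tuple[float, float] = (51.44, 3.60)
    anchor_head: tuple[float, float] = (51.13, 4.90)

    def __post_init__(self) -> None:
        for f in (self.ebb_frac_mouth, self.ebb_frac_upstream):
            if not 0.0 < f < 1.0:
                raise ConfigError(f"ebb fraction {f} outside (0, 1)")
        for zone, v in self.base_speed_km_day.items():
            if v <= 0:
                raise ConfigError(f"base speed for {zone} must be > 0")
        for zone, m in self.behaviour.items():
            if m not in MODES:
                raise ConfigError(f"unknown behaviour mode {m!r} for {zone}")
        lo, hi = self.release_chainage_range_km
        if not (0.0 <= lo <= hi <= self.river_length_km):
            raise ConfigError("release chainage range outside river")
        if not (300.0 <= self.detection_range_m <= 1005.0):
            raise ConfigError("detection range must lie in [300, 1005] m")
        if not self.station_chainages:
            raise ConfigError("need at least one water-level station")

    # -- derived geometry ------------------------------------------------
    @property
    def start_epoch(self) -> int:
        return int(pd.Timestamp(self.start).tz_convert("UTC").value // 10**9)

    @property
    def period_s(self) -> float:
        return self.tide_period_h * 3600.0

    def zone_of(self, chainage):
        c = np.asarray(chainage, dtype=float)
        out = np.where(
            c < self.tidal_max_km,
            "tidal",
            np.where(c < self.transition_max_km, "transition", "non_tidal"),
        )
        return out if out.ndim else str(out)

    def ebb_fraction(self, chainage):
        c = np.clip(np.asarray(chainage, dtype=float), 0.0, self.tidal_max_km)
        return self.ebb_frac_mouth + (self.ebb_frac_upstream - self.ebb_frac_mouth) * (
            c / self.tidal_max_km
        )

    def amplitude(self, chainage):
        c = np.asarray(chainage, dtype=float)
        tidal = self.amp_mouth_m + (self.amp_tidal_max_m - self.amp_mouth_m) * (
            np.clip(c, 0, self.tidal_max_km) / self.tidal_max_km
        )
        trans_w = np.clip(
            (self.transition_max_km - c) / (self.transition_max_km - self.tidal_max_km),
            0.0,
            1.0,
        )
        return np.where(c < self.tidal_max_km, tidal, self.amp_transition_m * trans_w)

    def latlon(self, chainage):
        w = np.clip(np.asarray(chainage, dtype=float) / self.river_length_km, 0, 1)
        lat = self.anchor_mouth[0] + (self.anchor_head[0] - self.anchor_mouth[0]) * w
        lon = self.anchor_mouth[1] + (self.anchor_head[1] - self.anchor_mouth[1]) * w
        return lat, lon

    def depth_profile(self, chainage):
        c = np.asarray(chainage, dtype=float)
        tidal_depth = 12.3 + (4.76 - 12.3) * (np.clip(c, 0, self.tidal_max_km) / self.tidal_max_km)
        return np.where(c < self.tidal_max_km, tidal_depth,
                        np.where(c < self.transition_max_km, 3.11, 0.97))

    # -- analytic tide ---------------------------------------------------
    def tide_phase_fraction(self, t_epoch, chainage):
        """Position within the tidal cycle in [0, 1); 0 = high water."""
        lag = self.tide_lag_h_per_km * np.asarray(chainage, dtype=float) * 3600.0
        return np.mod((np.asarray(t_epoch, dtype=float) - self.start_epoch - lag), self.period_s) / self.period_s

    def true_tidal_phase(self, t_epoch, chainage):
        """Ground-truth ebb/flood from the analytic tide (not segmentation)."""
        phi = self.tide_phase_fraction(t_epoch, chainage)
        f = self.ebb_fraction(chainage)
        out = np.where(phi < f, "ebb", "flood")
        return out if out.ndim else str(out)

    def tide_level(self, t_epoch, chainage):
        phi = self.tide_phase_fraction(t_epoch, chainage)
        f = self.ebb_fraction(chainage)
        theta = np.where(
            phi < f,
            np.pi * phi / f,
            np.pi + np.pi * (phi - f) / (1.0 - f),
        )
        return self.tide_mean_level + self.amplitude(chainage) * np.cos(theta)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["receiver_chainages"] = (
            list(d["receiver_chainages"]) if d["receiver_chainages"] else None
        )
        d["station_chainages"] = list(d["station_chainages"])
        return d


_STREAMS = {"tides": 1, "crabs": 2, "detections": 3}


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[name]])


def time_grid(config: SimConfig) -> np.ndarray:
    """Epoch-second 10-min grid spanning the simulation."""
    n = int(round(config.duration_days * 86400 / (config.step_minutes * 60))) + 1
    return config.start_epoch + (config.step_minutes * 60) * np.arange(n, dtype=np.int64)


def simulate_tides(config: SimConfig) -> list[WaterLevelSeries]:
    """One 10-min water-level series per configured station."""
    rng = _stream(config, "tides")
    grid = time_grid(config)
    out = []
    for i, c in enumerate(config.station_chainages):
        levels = np.asarray(config.tide_level(grid, c), dtype=float)
        if config.tide_noise_sigma > 0:
            levels = levels + rng.normal(0.0, config.tide_noise_sigma, levels.size)
        out.append(WaterLevelSeries(f"S{i + 1:02d}", float(c), grid.copy(), levels))
    return out


def default_receivers(config: SimConfig) -> pd.DataFrame:
    """Receivers evenly spread along the river (interior positions)."""
    if config.receiver_chainages is not None:
        chain = np.asarray(config.receiver_chainages, dtype=float)
    else:
        chain = np.linspace(
            0.03 * config.river_length_km, 0.97 * config.river_length_km, config.n_receivers
        )
    lat, lon = config.latlon(chain)
    return pd.DataFrame(
        {
            "receiver_id": [f"R{i + 1:02d}" for i in range(chain.size)],
            "lat": np.round(lat, 5),
            "lon": np.round(lon, 5),
            "chainage_km": np.round(chain, 3),
            "zone": config.zone_of(chain),
        }
    )


def simulate_crabs(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Crab metadata and ground-truth trajectories.

    Returns (crabs, trajectories); trajectories has one row per
    (tag, step) with chainage at the step start and whether the crab
    moved during that step. Chainage is non-increasing (downstream-only)
    and freezes once the spawning chainage is reached.
    """
    rng = _stream(config, "crabs")
    n = config.n_crabs
    lo, hi = config.release_chainage_range_km
    release_chain = np.round(rng.uniform(lo, hi, n), 3)
    release_offsets = rng.uniform(0, config.release_window_days * 86400, n)
    release_epoch = config.start_epoch + np.round(release_offsets).astype(np.int64)
    crabs = pd.DataFrame(
        {
            "tag_id": [f"T{i + 1:02d}" for i in range(n)],
            "sex": ["female" if i % 2 == 0 else "male" for i in range(n)],
            "cw_mm": np.round(rng.uniform(56.0, 82.0, n), 2),
            "mass_g": np.round(rng.uniform(90.0, 210.0, n), 2),
            "release_datetime_utc": pd.to_datetime(release_epoch, unit="s", utc=True),
            "release_chainage_km": release_chain,
            "sensor_tag": [i < config.n_sensor_crabs for i in range(n)],
            "ping_min_s": config.ping_min_s,
            "ping_max_s": config.ping_max_s,
        }
    )

    grid = time_grid(config)
    dt_days = config.step_minutes * 60 / 86400.0
    n_steps = grid.size
    pos = np.empty((n_steps, n), dtype=float)
    moving = np.zeros((n_steps, n), dtype=bool)
    cur = release_chain.astype(float).copy()
    sig = config.speed_jitter_sigma

    def per_zone(c, mapping):
        return np.where(
            c < config.tidal_max_km,
            mapping["tidal"],
            np.where(c < config.transition_max_km, mapping["transition"], mapping["non_tidal"]),
        )

    sun_flag = {z: ("nocturnal" in m) for z, m in config.behaviour.items()}
    tide_flag = {z: ("stst" in m) for z, m in config.behaviour.items()}
    steps_per_block = max(1, int(round(config.speed_jitter_tau_h * 3600 / (config.step_minutes * 60))))
    n_blocks = n_steps // steps_per_block + 1
    if sig > 0:
        jitter_blocks = np.exp(rng.normal(-0.5 * sig**2, sig, (n_blocks, n)))
    else:
        jitter_blocks = np.ones((n_blocks, n))
    for k in range(n_steps):
        t = grid[k]
        pos[k] = cur
        active = (t >= release_epoch) & (cur > config.spawning_chainage_km)
        gate = np.ones(n, dtype=bool)
        need_sun = per_zone(cur, sun_flag).astype(bool)
        if need_sun.any():
            lat, lon = config.latlon(cur)
            alt = solar.solar_altitude(float(t), lat, lon)
            is_day = np.asarray(alt) > solar.DAY_SET_ALT
            gate &= ~(need_sun & is_day)
        need_tide = per_zone(cur, tide_flag).astype(bool)
        if need_tide.any():
            phi = config.tide_phase_fraction(float(t), cur)
            is_ebb = phi < config.ebb_fraction(cur)
            gate &= ~need_tide | is_ebb
        mv = active & gate
        moving[k] = mv
        if mv.any() and k < n_steps - 1:
            speeds = per_zone(cur, config.base_speed_km_day)
            jitter = jitter_blocks[k // steps_per_block]
            step = speeds * jitter * dt_days
            nxt = np.where(mv, cur - step, cur)
            nxt = np.maximum(nxt, config.spawning_chainage_km)
            cur = nxt
    traj = pd.DataFrame(
        {
            "tag_id": np.repeat(crabs["tag_id"].to_numpy(), n_steps),
            "t_epoch": np.tile(grid, n),
            "chainage_km": pos.T.ravel(),
            "moving": moving.T.ravel(),
        }
    )
    # steps before release are not part of the trajectory
    rel = np.repeat(release_epoch, n_steps)
    traj = traj[traj["t_epoch"] >= rel].reset_index(drop=True)
    return crabs, traj


def _positions_at(
    traj_one: pd.DataFrame, t_epoch: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Chainage and moving flag at arbitrary times (piecewise-constant steps)."""
    times = traj_one["t_epoch"].to_numpy()
    idx = np.clip(np.searchsorted(times, t_epoch, side="right") - 1, 0, times.size - 1)
    return (
        traj_one["chainage_km"].to_numpy()[idx],
        traj_one["moving"].to_numpy()[idx],
    )


def simulate_detections(
    trajectories: pd.DataFrame,
    receivers: pd.DataFrame,
    crabs: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Acoustic detection process over ground-truth trajectories.

    Pings at uniform-random intervals in [ping_min, ping_max]; every
    receiver within the along-channel detection range logs each ping with
    probability ``p_det``. Sensor tags carry acceleration (moving ->
    ``accel_moving``, resting -> ``accel_resting``, multiplicative
    lognormal noise) and depth from the chainage depth profile plus the
    tidal level offset inside the tidal zone.
    """
    if receivers.empty:
        raise ConfigError("empty receiver list")
    rng = _stream(config, "detections")
    rx_chain = receivers["chainage_km"].to_numpy(float)
    rx_ids = receivers["receiver_id"].to_numpy()
    range_km = config.detection_range_m / 1000.0
    end_epoch = config.start_epoch + int(config.duration_days * 86400)
    frames = []
    for crab in crabs.itertuples():
        tr = trajectories[trajectories["tag_id"] == crab.tag_id]
        if tr.empty:
            continue
        t0 = int(crab.release_datetime_utc.value // 10**9)
        horizon = end_epoch - t0
        if horizon <= 0:
            continue
        n_max = int(horizon / config.ping_min_s) + 2
        intervals = rng.uniform(config.ping_min_s, config.ping_max_s, n_max)
        pings = t0 + np.round(np.cumsum(intervals)).astype(np.int64)
        pings = pings[pings <= end_epoch]
        pos, mov = _positions_at(tr, pings)
        dist = np.abs(pos[:, None] - rx_chain[None, :])
        hit = dist <= range_km
        if config.p_det < 1.0:
            hit &= rng.random(hit.shape) < config.p_det
        ping_idx, rx_idx = np.nonzero(hit)
        if ping_idx.size == 0:
            continue
        frame = pd.DataFrame(
            {
                "tag_id": crab.tag_id,
                "receiver_id": rx_ids[rx_idx],
                "datetime_utc": pd.to_datetime(pings[ping_idx], unit="s", utc=True),
                "accel_ms2": np.nan,
                "depth_m": np.nan,
            }
        )
        if crab.sensor_tag:
            level = np.where(mov[ping_idx], config.accel_moving, config.accel_resting)
            noise = np.exp(rng.normal(0.0, config.accel_noise_sigma, ping_idx.size))
            frame["accel_ms2"] = np.round(level * noise, 4)
            base_depth = np.asarray(config.depth_profile(pos[ping_idx]), dtype=float)
            zone = config.zone_of(pos[ping_idx])
            tide_off = np.where(
                zone == "tidal",
                np.asarray(config.tide_level(pings[ping_idx], pos[ping_idx]))
                - config.tide_mean_level,
                0.0,
            )
            dn = rng.normal(0.0, config.depth_noise_sigma, ping_idx.size)
            frame["depth_m"] = np.round(np.maximum(base_depth + tide_off + dn, 0.05), 3)
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=["tag_id", "receiver_id", "datetime_utc", "accel_ms2", "depth_m"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["tag_id", "datetime_utc", "receiver_id"], kind="mergesort").reset_index(
        drop=True
    )


def true_events(
    trajectories: pd.DataFrame, receivers: pd.DataFrame, range_m: float
) -> pd.DataFrame:
    """Ground-truth visit events: first/last step within receiver range."""
    range_km = range_m / 1000.0
    rows = []
    for tag, tr in trajectories.groupby("tag_id", sort=True):
        t = tr["t_epoch"].to_numpy()
        pos = tr["chainage_km"].to_numpy()
        for rid, c in zip(receivers["receiver_id"], receivers["chainage_km"]):
            inside = np.abs(pos - float(c)) <= range_km
            if not inside.any():
                continue
            idx = np.nonzero(inside)[0]
            rows.append(
                {
                    "tag_id": tag,
                    "receiver_id": rid,
                    "arrival_t": pd.Timestamp(int(t[idx[0]]), unit="s", tz="UTC"),
                    "departure_t": pd.Timestamp(int(t[idx[-1]]), unit="s", tz="UTC"),
                    "n_detections": int(idx.size),
                }
            )
    df = pd.DataFrame(
        rows, columns=["tag_id", "receiver_id", "arrival_t", "departure_t", "n_detections"]
    )
    return df.sort_values(["tag_id", "arrival_t"], kind="mergesort").reset_index(drop=True)


PROFILES = {
    "small": dict(duration_days=20.0, n_crabs=10, n_receivers=20, n_sensor_crabs=2,
                  release_chainage_range_km=(60.0, 160.0)),
    "paper_like": dict(duration_days=90.0, n_crabs=10, n_receivers=20, n_sensor_crabs=2,
                       release_chainage_range_km=(100.0, 160.0)),
}


def profile_config(seed: int, profile: str = "small", **overrides) -> SimConfig:
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}")
    kwargs = dict(PROFILES[profile])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)


def _fmt_time(epochs: np.ndarray) -> pd.Series:
    return pd.to_datetime(epochs, unit="s", utc=True).strftime("%Y-%m-%dT%H:%M:%SZ")


def make_fixture(out_dir: str | Path, seed: int, profile: str = "small", **overrides) -> SimConfig:
    """Write a complete on-disk Dataset plus ground-truth tables.

    Emits detections.csv, receivers.csv, crabs.csv, waterlevels.csv and
    truth_trajectories.csv / truth_config.json. Byte-deterministic for a
    fixed (seed, profile, overrides).
    """
    config = profile_config(seed, profile, **overrides)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    series = simulate_tides(config)
    receivers = default_receivers(config)
    crabs, traj = simulate_crabs(config)
    detections = simulate_detections(traj, receivers, crabs, config)

    wl = pd.concat(
        [
            pd.DataFrame(
                {
                    "station_id": s.station_id,
                    "chainage_km": s.chainage_km,
                    "datetime_utc": _fmt_time(s.times),
                    "level_mtaw": np.round(s.levels, 4),
                }
            )
            for s in series
        ],
        ignore_index=True,
    )

    det_out = detections.copy()
    det_out["datetime_utc"] = det_out["datetime_utc"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    crabs_out = crabs.copy()
    crabs_out["release_datetime_utc"] = crabs_out["release_datetime_utc"].dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    traj_out = traj.copy()
    traj_out["datetime_utc"] = _fmt_time(traj_out.pop("t_epoch").to_numpy())
    traj_out["chainage_km"] = np.round(traj_out["chainage_km"], 4)
    traj_out = traj_out[["tag_id", "datetime_utc", "chainage_km", "moving"]]

    kw = dict(index=False, float_format="%.10g", lineterminator="\n")
    det_out.to_csv(out_dir / "detections.csv", **kw)
    receivers.to_csv(out_dir / "receivers.csv", **kw)
    crabs_out.to_csv(out_dir / "crabs.csv", **kw)
    wl.to_csv(out_dir / "waterlevels.csv", **kw)
    traj_out.to_csv(out_dir / "truth_trajectories.csv", **kw)
    (out_dir / "truth_config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    return config


# -- direct fixtures for the inference stage ---------------------------------


def make_sensor_fixture(
    seed: int,
    n_tags: int = 6,
    n_receivers: int = 3,
    n_obs_per_cell: int = 20,
    accel_ebb: float = 0.25,
    accel_flood: float = 0.11,
    resid_sigma: float = 0.5,
    tag_sigma: float = 0.15,
    receiver_sigma: float = 0.10,
    zone: str = "tidal",
) -> pd.DataFrame:
    """Annotated sensor observations with a known ebb/flood accel ratio.

    Geometric-mean acceleration is ``accel_ebb`` during ebb and
    ``accel_flood`` during flood (true log-ratio log(ebb/flood)), with
    per-tag and per-tag:receiver random intercepts and iid lognormal
    residual noise; circadian phase and sex carry no true effect.
    """
    rng = np.random.default_rng([seed, 11])
    rows = []
    circ = ["day", "night", "twilight"]
    t0 = pd.Timestamp("2021-12-01T00:00:00Z").value // 10**9
    counter = 0
    for i in range(n_tags):
        tag = f"T{i + 1:02d}"
        sex = "female" if i % 2 == 0 else "male"
        u_tag = rng.normal(0.0, tag_sigma)
        for j in range(n_receivers):
            rid = f"R{j + 1:02d}"
            u_rx = rng.normal(0.0, receiver_sigma)
            for tide, level in (("ebb", accel_ebb), ("flood", accel_flood)):
                for k in range(n_obs_per_cell):
                    log_a = (
                        np.log(level) + u_tag + u_rx + rng.normal(0.0, resid_sigma)
                    )
                    rows.append(
                        {
                            "tag_id": tag,
                            "receiver_id": rid,
                            "datetime_utc": pd.Timestamp(t0 + 600 * counter, unit="s", tz="UTC"),
                            "accel_ms2": float(np.exp(log_a)),
                            "depth_m": np.nan,
                            "zone": zone,
                            "circadian": circ[int(rng.integers(0, 3))],
                            "tidal": tide,
                            "sex": sex,
                        }
                    )
                    counter += 1
    return pd.DataFrame(rows)


def make_speed_fixture(
    seed: int,
    n_tags: int = 12,
    n_per_zone: int = 4,
    zone_means: dict | None = None,
    resid_sigma: float = 0.45,
    tag_sigma: float = 0.15,
    receiver_sigma: float = 0.10,
) -> pd.DataFrame:
    """Speed records with known geometric zone means and random effects."""
    zone_means = zone_means or {"non_tidal": 4.65, "transition": 4.71, "tidal": 1.29}
    rng = np.random.default_rng([seed, 12])
    zones = list(zone_means)
    rx_effects = {
        f"{z}_{k}": rng.normal(0.0, receiver_sigma)
        for z in zones
        for k in range(n_per_zone + 1)
    }
    rows = []
    for i in range(n_tags):
        tag = f"T{i + 1:02d}"
        sex = "female" if i % 2 == 0 else "male"
        u_tag = rng.normal(0.0, tag_sigma)
        for z in zones:
            for k in range(n_per_zone):
                rid = f"{z}_{k + (i % 2)}"
                log_s = (
                    np.log(zone_means[z]) + u_tag + rx_effects[rid]
                    + rng.normal(0.0, resid_sigma)
                )
                speed = float(np.exp(log_s))
                elapsed = float(rng.uniform(0.5, 3.0))
                rows.append(
                    {
                        "tag_id": tag,
                        "from_receiver": f"{rid}_from",
                        "to_receiver": rid,
                        "distance_km": speed * elapsed,
                        "elapsed_days": elapsed,
                        "speed_km_day": speed,
                        "zone": z,
                        "direction": "downstream",
                        "sex": sex,
                    }
                )
    return pd.DataFrame(rows)
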