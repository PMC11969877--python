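"""Migration speeds, per-zone depth summaries, and sensor-phase linkage.

Speed between consecutive distinct receivers in a tag's event sequence:
distance = |chainage difference| along the river axis, elapsed = time
from departure at the first receiver to arrival at the next. Upstream
displacements are flagged and excluded from the speed model by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ebbtrack import solar
from ebbtrack.core_data import AnalysisConfig, CoverageError
from ebbtrack.tides import UNAVAILABLE, TidalAnnotation

logger = logging.getLogger(__name__)

SPEED_COLUMNS = [
    "tag_id", "from_receiver", "to_receiver", "distance_km", "elapsed_days",
    "speed_km_day", "zone", "direction",
]


def migration_speeds(
    events: pd.DataFrame,
    receivers: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Speed records between consecutive distinct-receiver events per tag.

    Zero-distance pairs (revisits under split_gap) are skipped; pairs
    with non-positive elapsed time (overlapping detection ranges / clock
    anomalies) are dropped and logged. The segment's zone comes from the
    midpoint chainage.
    """
    config = config or AnalysisConfig()
    chain = receivers.set_index("receiver_id")["chainage_km"]
    rows = []
    n_dropped = 0
    for tag, sub in events.sort_values(["tag_id", "arrival_t"]).groupby("tag_id", sort=True):
        sub = sub.reset_index(drop=True)
        for i in range(len(sub) - 1):
            a, b = sub.iloc[i], sub.iloc[i + 1]
            if a["receiver_id"] == b["receiver_id"]:
                continue
            c0, c1 = float(chain[a["receiver_id"]]), float(chain[b["receiver_id"]])
            distance = abs(c1 - c0)
            elapsed = (b["arrival_t"] - a["departure_t"]).total_seconds() / 86400.0
            if elapsed <= 0:
                n_dropped += 1
                continue
            rows.append(
                {
                    "tag_id": tag,
                    "from_receiver": a["receiver_id"],
                    "to_receiver": b["receiver_id"],
                    "distance_km": distance,
                    "elapsed_days": elapsed,
                    "speed_km_day": distance / elapsed,
                    "zone": config.zone_of((c0 + c1) / 2.0),
                    "direction": "downstream" if c1 < c0 else "upstream",
                }
            )
    if n_dropped:
        logger.info("dropped %d speed records with non-positive elapsed time", n_dropped)
    return pd.DataFrame(rows, columns=SPEED_COLUMNS)


def depth_summary(sensor_obs: pd.DataFrame) -> pd.DataFrame:
    """Per-zone depth summaries over pressure-sensor observations."""
    obs = sensor_obs.dropna(subset=["depth_m"])
    if obs.empty:
        raise ValueError("no depth observations")
    rows = []
    for zone, grp in obs.groupby("zone", sort=True):
        rows.append(
            {
                "zone": zone,
                "n_crabs": int(grp["tag_id"].nunique()),
                "n_observations": int(len(grp)),
                "depth_mean_m": float(grp["depth_m"].mean()),
                "depth_sd_m": float(grp["depth_m"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "depth_min_m": float(grp["depth_m"].min()),
                "depth_max_m": float(grp["depth_m"].max()),
            }
        )
    return pd.DataFrame(rows)


def link_sensor_phases(
    detections: pd.DataFrame,
    receivers: pd.DataFrame,
    annotations: dict[str, TidalAnnotation | None],
) -> pd.DataFrame:
    """Annotate every sensor-bearing detection with circadian/tidal phase.

    Timestamps are rounded to the nearest 10 min for the tidal lookup, as
    for events. Non-sensor detections yield no rows.
    """
    mask = detections["accel_ms2"].notna() | detections["depth_m"].notna()
    obs = detections.loc[mask].copy()
    if obs.empty:
        return pd.DataFrame(
            columns=[
                "tag_id", "receiver_id", "datetime_utc", "accel_ms2", "depth_m",
                "zone", "circadian", "tidal",
            ]
        )
    rx = receivers.set_index("receiver_id")
    obs["zone"] = obs["receiver_id"].map(rx["zone"])
    lat = obs["receiver_id"].map(rx["lat"]).to_numpy(float)
    lon = obs["receiver_id"].map(rx["lon"]).to_numpy(float)
    t_epoch = obs["datetime_utc"].astype("int64").to_numpy() // 10**9
    obs["circadian"] = solar._phase_from_altitude(solar.solar_altitude(t_epoch, lat, lon))
    tidal = []
    for ts, rid in zip(obs["datetime_utc"], obs["receiver_id"]):
        ann = annotations.get(rid)
        if ann is None:
            tidal.append(UNAVAILABLE)
        else:
            try:
                ph, _ = ann.phase_at(ts)
            except CoverageError as exc:
                raise CoverageError(f"sensor ping ({rid}, {ts}) uncovered: {exc}") from exc
            tidal.append(ph)
    obs["tidal"] = tidal
    return obs[
        ["tag_id", "receiver_id", "datetime_utc", "accel_ms2", "depth_m",
         "zone", "circadian", "tidal"]
    ].reset_index(drop=True)
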