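"""Reduce detections to per-crab per-receiver visit events and annotate them.

A visit is arrival (first detection) to departure (last detection) of a
tag at a receiver. Default mode emits one event per (tag, receiver)
pair; ``split_gap`` mode splits runs separated by long silences and is
intended for sensitivity analysis only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ebbtrack.core_data import CoverageError, ReferentialIntegrityError
from ebbtrack import solar
from ebbtrack.tides import UNAVAILABLE, TidalAnnotation

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["tag_id", "receiver_id", "arrival_t", "departure_t", "n_detections"]


def extract_visits(
    detections: pd.DataFrame, split_gap: float | None = None
) -> pd.DataFrame:
    """Visit events per (tag, receiver): arrival/departure timestamps.

    With ``split_gap`` (hours), detections at a receiver are grouped into
    runs separated by gaps > split_gap, one event per run.
    """
    if detections.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    d = detections.sort_values(["tag_id", "receiver_id", "datetime_utc"], kind="mergesort")
    if split_gap is None:
        grouped = d.groupby(["tag_id", "receiver_id"], sort=True)
        events = grouped["datetime_utc"].agg(arrival_t="first", departure_t="last")
        events["n_detections"] = grouped.size()
        events = events.reset_index()
    else:
        gap = pd.Timedelta(hours=split_gap)
        d = d.copy()
        within = d.groupby(["tag_id", "receiver_id"])["datetime_utc"]
        new_run = within.diff() > gap
        d["run"] = new_run.groupby([d["tag_id"], d["receiver_id"]]).cumsum()
        grouped = d.groupby(["tag_id", "receiver_id", "run"], sort=True)
        events = grouped["datetime_utc"].agg(arrival_t="first", departure_t="last")
        events["n_detections"] = grouped.size()
        events = events.reset_index().drop(columns="run")
    events = events.sort_values(["tag_id", "arrival_t"], kind="mergesort").reset_index(drop=True)
    return events[EVENT_COLUMNS]


def exclude_release_day(detections: pd.DataFrame, crabs: pd.DataFrame) -> pd.DataFrame:
    """Drop detections falling in each tag's release UTC calendar day."""
    unknown = set(detections["tag_id"]) - set(crabs["tag_id"])
    if unknown:
        raise ReferentialIntegrityError(f"unknown tag_id(s) {sorted(unknown)}")
    release_day = crabs.set_index("tag_id")["release_datetime_utc"].dt.floor("D")
    det_day = detections["datetime_utc"].dt.floor("D")
    keep = det_day != detections["tag_id"].map(release_day)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("release-day filter dropped %d detections", n_dropped)
    kept_tags = set(detections.loc[keep, "tag_id"])
    for tag in sorted(set(detections["tag_id"]) - kept_tags):
        logger.info("tag %s detected only on release day; untracked", tag)
    return detections.loc[keep].reset_index(drop=True)


def annotate_events(
    events: pd.DataFrame,
    receivers: pd.DataFrame,
    annotations: dict[str, TidalAnnotation | None],
) -> pd.DataFrame:
    """Attach zone, circadian and tidal phase columns to visit events.

    Circadian phase is evaluated at the receiver's coordinates. Tidal
    phase and hours-since-high-water come from the receiver's
    interpolated-level annotation; receivers without one (transition and
    non-tidal zones) get ``unavailable`` and NaN.
    """
    rx = receivers.set_index("receiver_id")
    out = events.copy()
    out["zone"] = out["receiver_id"].map(rx["zone"])
    lat = out["receiver_id"].map(rx["lat"]).to_numpy(float)
    lon = out["receiver_id"].map(rx["lon"]).to_numpy(float)

    for kind in ("arrival", "departure"):
        t = out[f"{kind}_t"]
        t_epoch = t.astype("int64").to_numpy() // 10**9
        alt = solar.solar_altitude(t_epoch, lat, lon)  # broadcasts over events
        out[f"{kind}_circadian"] = solar._phase_from_altitude(alt) if len(out) else []
        phases = []
        hshs = []
        for ts, rid in zip(t, out["receiver_id"]):
            ann = annotations.get(rid)
            if ann is None:
                phases.append(UNAVAILABLE)
                hshs.append(np.nan)
            else:
                try:
                    ph, hsh = ann.phase_at(ts)
                except CoverageError as exc:
                    raise CoverageError(
                        f"event ({rid}, {kind} at {ts}) outside tidal annotation: {exc}"
                    ) from exc
                phases.append(ph)
                hshs.append(hsh)
        out[f"{kind}_tidal"] = phases
        out[f"{kind}_hsh"] = hshs
    return out
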