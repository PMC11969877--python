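"""Domain types, CSV schemas and validated readers/writers.

All timestamps are timezone-aware UTC. Chainage is measured in km upstream
from the estuarine mouth, so downstream movement means decreasing chainage.
Zone membership (``tidal`` / ``transition`` / ``non_tidal``) is a property
of the receiver, fixed by the configured chainage cut-offs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ZONES = ("tidal", "transition", "non_tidal")

DETECTIONS_COLUMNS = ["tag_id", "receiver_id", "datetime_utc", "accel_ms2", "depth_m"]
RECEIVERS_COLUMNS = ["receiver_id", "lat", "lon", "chainage_km", "zone"]
CRABS_COLUMNS = [
    "tag_id",
    "sex",
    "cw_mm",
    "mass_g",
    "release_datetime_utc",
    "release_chainage_km",
    "sensor_tag",
    "ping_min_s",
    "ping_max_s",
]
WATERLEVELS_COLUMNS = ["station_id", "chainage_km", "datetime_utc", "level_mtaw"]

WATER_LEVEL_SPACING_S = 600


class SchemaError(ValueError):
    """A CSV does not match its documented schema."""


class ReferentialIntegrityError(ValueError):
    """A detection references an unknown tag or receiver."""


class CoverageError(ValueError):
    """A timestamp falls outside the span of an annotation or series."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass
class AnalysisConfig:
    """Parameters of the analysis pipeline.

    ``tidal_max_km`` / ``transition_max_km`` are the chainage cut-offs:
    tidal < tidal_max_km <= transition < transition_max_km <= non_tidal.
    """

    tidal_max_km: float = 125.0
    transition_max_km: float = 136.0
    smooth_window: int = 7
    min_half_cycle_h: float = 3.0
    split_gap_h: float | None = None
    alpha: float = 0.05
    seed: int = 0
    multiple_testing: bool = False
    include_upstream_speeds: bool = False

    def zone_of(self, chainage_km: float) -> str:
        if chainage_km < self.tidal_max_km:
            return "tidal"
        if chainage_km < self.transition_max_km:
            return "transition"
        return "non_tidal"

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WaterLevelSeries:
    """Water levels at one station on a strict 10-min grid.

    ``times`` is an int64 array of epoch seconds (UTC); ``levels`` is float
    mTAW. Gaps (spacing != 600 s) are flagged in ``gap_indices`` but never
    silently filled.
    """

    station_id: str
    chainage_km: float
    times: np.ndarray
    levels: np.ndarray
    gap_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.size != self.levels.size:
            raise SchemaError("times and levels length mismatch")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise SchemaError(
                f"station {self.station_id}: timestamps not strictly increasing"
            )
        self.gap_indices = np.nonzero(dt != WATER_LEVEL_SPACING_S)[0]
        if self.gap_indices.size:
            logger.warning(
                "station %s: %d spacing gaps flagged", self.station_id, self.gap_indices.size
            )

    def level_at(self, t_epoch: int) -> float:
        """Level at an exact grid timestamp; CoverageError if absent."""
        i = np.searchsorted(self.times, t_epoch)
        if i >= self.times.size or self.times[i] != t_epoch:
            raise CoverageError(
                f"station {self.station_id}: no sample at epoch {t_epoch}"
            )
        return float(self.levels[i])

    def covers(self, t_epoch: int) -> bool:
        i = np.searchsorted(self.times, t_epoch)
        return bool(i < self.times.size and self.times[i] == t_epoch)


@dataclass
class Dataset:
    """Validated bundle of the four input tables."""

    detections: pd.DataFrame
    receivers: pd.DataFrame
    crabs: pd.DataFrame
    water_levels: pd.DataFrame
    config: AnalysisConfig

    def water_level_series(self) -> list[WaterLevelSeries]:
        out = []
        for sid, grp in self.water_levels.groupby("station_id", sort=True):
            grp = grp.sort_values("datetime_utc")
            out.append(
                WaterLevelSeries(
                    station_id=str(sid),
                    chainage_km=float(grp["chainage_km"].iloc[0]),
                    times=grp["datetime_utc"].astype("int64").to_numpy() // 10**9,
                    levels=grp["level_mtaw"].to_numpy(),
                )
            )
        return out


def _read_csv(directory: Path, name: str, columns: list[str]) -> pd.DataFrame:
    path = directory / name
    if not path.exists():
        raise FileNotFoundError(f"missing input file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    return df


def _parse_utc(df: pd.DataFrame, column: str, name: str) -> pd.DataFrame:
    try:
        df[column] = pd.to_datetime(df[column], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{name}: column {column} is not ISO-8601 datetime") from exc
    return df


def read_dataset(directory: str | Path, config: AnalysisConfig | None = None) -> Dataset:
    """Read and validate detections/receivers/crabs/waterlevels CSVs.

    Detections are sorted by (tag_id, datetime_utc); duplicate
    (tag_id, receiver_id, datetime_utc) triples are dropped keeping the
    first, with the count logged. Unknown tag or receiver IDs raise
    :class:`ReferentialIntegrityError`.
    """
    directory = Path(directory)
    config = config or AnalysisConfig()

    detections = _read_csv(directory, "detections.csv", DETECTIONS_COLUMNS)
    receivers = _read_csv(directory, "receivers.csv", RECEIVERS_COLUMNS)
    crabs = _read_csv(directory, "crabs.csv", CRABS_COLUMNS)
    water_levels = _read_csv(directory, "waterlevels.csv", WATERLEVELS_COLUMNS)

    detections = _parse_utc(detections, "datetime_utc", "detections.csv")
    crabs = _parse_utc(crabs, "release_datetime_utc", "crabs.csv")
    water_levels = _parse_utc(water_levels, "datetime_utc", "waterlevels.csv")

    for col in ("tag_id", "receiver_id"):
        detections[col] = detections[col].astype(str)
    receivers["receiver_id"] = receivers["receiver_id"].astype(str)
    crabs["tag_id"] = crabs["tag_id"].astype(str)
    water_levels["station_id"] = water_levels["station_id"].astype(str)
    crabs["sensor_tag"] = crabs["sensor_tag"].astype(bool)

    bad_zone = set(receivers["zone"]) - set(ZONES)
    if bad_zone:
        raise SchemaError(f"receivers.csv: unknown zone value(s) {sorted(bad_zone)}")
    if receivers["chainage_km"].duplicated().any():
        raise SchemaError("receivers.csv: chainage_km must be unique per receiver")
    expected_zone = receivers["chainage_km"].map(config.zone_of)
    mismatched = receivers.loc[receivers["zone"] != expected_zone, "receiver_id"]
    if len(mismatched):
        raise SchemaError(
            "receivers.csv: zone inconsistent with chainage cut-offs for "
            f"{sorted(mismatched)}"
        )

    bad_sex = set(crabs["sex"]) - {"female", "male"}
    if bad_sex:
        raise SchemaError(f"crabs.csv: unknown sex value(s) {sorted(bad_sex)}")

    unknown_tags = set(detections["tag_id"]) - set(crabs["tag_id"])
    if unknown_tags:
        raise ReferentialIntegrityError(
            f"detections reference unknown tag_id(s) {sorted(unknown_tags)}"
        )
    unknown_rx = set(detections["receiver_id"]) - set(receivers["receiver_id"])
    if unknown_rx:
        raise ReferentialIntegrityError(
            f"detections reference unknown receiver_id(s) {sorted(unknown_rx)}"
        )

    n_before = len(detections)
    detections = detections.drop_duplicates(
        subset=["tag_id", "receiver_id", "datetime_utc"], keep="first"
    )
    n_dup = n_before - len(detections)
    if n_dup:
        logger.info("dropped %d duplicate detection triples", n_dup)

    detections = detections.sort_values(
        ["tag_id", "datetime_utc", "receiver_id"], kind="mergesort"
    ).reset_index(drop=True)
    receivers = receivers.sort_values("receiver_id", kind="mergesort").reset_index(drop=True)
    crabs = crabs.sort_values("tag_id", kind="mergesort").reset_index(drop=True)
    water_levels = water_levels.sort_values(
        ["station_id", "datetime_utc"], kind="mergesort"
    ).reset_index(drop=True)

    ds = Dataset(detections, receivers, crabs, water_levels, config)
    ds.water_level_series()  # validates monotone timestamps, flags gaps
    return ds


def _format_frame(df: pd.DataFrame) -> str:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    return out.to_csv(index=False, float_format="%.10g", lineterminator="\n")


def write_results(
    results: Mapping[str, pd.DataFrame],
    directory: str | Path,
    config: AnalysisConfig | None = None,
    extra_manifest: dict | None = None,
) -> dict:
    """Write one CSV per result table plus a JSON manifest.

    Output is deterministic: re-running on identical inputs yields
    byte-identical CSVs (fixed float formatting, fixed timestamp format,
    no wall-clock fields in the manifest).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tables": {},
        "config": config.to_dict() if config is not None else None,
        "versions": {
            "ebbtrack": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra_manifest:
        manifest.update(extra_manifest)
    for name in sorted(results):
        df = results[name]
        text = _format_frame(df)
        path = directory / f"{name}.csv"
        path.write_text(text)
        manifest["tables"][name] = {
            "rows": int(len(df)),
            "sha256": hashlib.sha256(text.encode()).hexdigest(),
        }
        if len(df) == 0:
            logger.info("result table %s has zero rows", name)
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _version() -> str:
    from ebbtrack import __version__

    return __version__


def round_10min(t: pd.Timestamp | np.ndarray) -> pd.Timestamp | np.ndarray:
    """Round to the nearest 10-min grid point; exact ties round up."""
    if isinstance(t, pd.Timestamp):
        s = t.value // 10**9
        return pd.Timestamp((s + 300) // 600 * 600, unit="s", tz="UTC")
    s = np.asarray(t, dtype=np.int64)
    return (s + 300) // 600 * 600
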