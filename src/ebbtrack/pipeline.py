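"""End-to-end orchestration: events -> annotation -> selectivity -> kinematics -> models."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from ebbtrack import events as events_mod
from ebbtrack import inference, kinematics, selectivity, tides
from ebbtrack.core_data import AnalysisConfig, Dataset, read_dataset, write_results

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(name, exc) from exc

        return wrapper

    return deco


def analyse(dataset: Dataset) -> dict[str, object]:
    """Run all analysis stages on a validated dataset; returns result objects."""
    config = dataset.config
    det = _stage("release_day_filter")(events_mod.exclude_release_day)(
        dataset.detections, dataset.crabs
    )
    series = dataset.water_level_series()
    annotations = _stage("tidal_annotation")(tides.annotate_receivers)(
        series, dataset.receivers, config
    )
    cstats = {
        rid: tides.cycle_stats(ann) for rid, ann in annotations.items() if ann is not None
    }
    visits = _stage("events")(events_mod.extract_visits)(det, config.split_gap_h)
    annotated = _stage("event_annotation")(events_mod.annotate_events)(
        visits, dataset.receivers, annotations
    )
    sel = _stage("selectivity")(selectivity.run_selectivity)(
        annotated, dataset.receivers, cstats, config
    )
    rose_diel = selectivity.rose_bins(annotated, "diel")
    rose_tidal = selectivity.rose_bins(annotated, "tidal")
    speeds = _stage("kinematics")(kinematics.migration_speeds)(
        annotated, dataset.receivers, config
    )
    sensor_obs = _stage("sensor_linkage")(kinematics.link_sensor_phases)(
        det, dataset.receivers, annotations
    )
    out: dict[str, object] = {
        "events": annotated,
        "selectivity": sel,
        "rose_diel": rose_diel,
        "rose_tidal": rose_tidal,
        "speeds": speeds,
        "sensor_obs": sensor_obs,
        "cycle_stats": cstats,
        "depth_summary": None,
        "accel_models": {},
        "speed_model": None,
    }
    if sensor_obs["depth_m"].notna().any():
        out["depth_summary"] = kinematics.depth_summary(sensor_obs)
    if sensor_obs["accel_ms2"].notna().any():
        try:
            out["accel_models"] = inference.fit_acceleration_models(
                sensor_obs, dataset.crabs, config
            )
        except ValueError as exc:
            logger.warning("acceleration models skipped: %s", exc)
    else:
        logger.warning("no sensor tags; acceleration inference skipped")
    if len(speeds):
        try:
            out["speed_model"] = inference.fit_speed_model(speeds, dataset.crabs, config)
        except ValueError as exc:
            logger.warning("speed model skipped: %s", exc)
    return out


def _model_tables(results: dict[str, object]) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}

    def add(prefix: str, fr: inference.FitResult) -> None:
        for attr in ("coef", "omnibus", "contrasts", "group_means"):
            df = getattr(fr, attr).copy()
            df.insert(0, "stratum", fr.stratum)
            key = f"{prefix}_{attr}"
            tables[key] = pd.concat([tables[key], df]) if key in tables else df

    for fr in results["accel_models"].values():
        add("model_accel", fr)
    if results["speed_model"] is not None:
        add("model_speed", results["speed_model"])
    return {k: v.reset_index(drop=True) for k, v in tables.items()}


def _summary_text(results: dict[str, object]) -> str:
    lines = ["ebbtrack analysis summary", "=" * 26, ""]
    lines.append("Selectivity (chi-squared GOF vs continuous-migration null):")
    for r in results["selectivity"]:
        if r.n == 0:
            lines.append(f"  {r.event_type:9s} {r.stratum:12s} skipped (n=0)")
            continue
        mark = "*" if r.significant else " "
        lines.append(
            f"  {r.event_type:9s} {r.stratum:12s} n={r.n:4d} chi2={r.chi2:7.2f} "
            f"df={r.df} p={r.p:.4g} {mark}"
        )
    speeds = results["speeds"]
    lines.append("")
    lines.append("Migration speed (km/day) by zone:")
    if len(speeds):
        down = speeds[speeds["direction"] == "downstream"]
        for zone, grp in down.groupby("zone"):
            lines.append(
                f"  {zone:12s} n={len(grp):4d} mean={grp['speed_km_day'].mean():6.2f} "
                f"sd={grp['speed_km_day'].std(ddof=1) if len(grp) > 1 else 0.0:6.2f} "
                f"max={grp['speed_km_day'].max():6.2f}"
            )
    if results["depth_summary"] is not None:
        lines.append("")
        lines.append("Depth (m) by zone:")
        for row in results["depth_summary"].itertuples():
            lines.append(
                f"  {row.zone:12s} n_crabs={row.n_crabs} n_obs={row.n_observations:5d} "
                f"mean={row.depth_mean_m:6.2f} sd={row.depth_sd_m:5.2f}"
            )
    for zone, fr in results["accel_models"].items():
        lines.append("")
        lines.append(f"Acceleration model [{zone}]: {fr.formula}")
        for t in fr.omnibus.itertuples():
            lines.append(f"  {t.term:28s} chi2={t.chi2:8.2f} df={t.df} p={t.p:.4g}")
    if results["speed_model"] is not None:
        fr = results["speed_model"]
        lines.append("")
        lines.append(f"Speed model: {fr.formula}")
        for t in fr.omnibus.itertuples():
            lines.append(f"  {t.term:28s} chi2={t.chi2:8.2f} df={t.df} p={t.p:.4g}")
        for c in fr.contrasts.itertuples():
            lines.append(
                f"  contrast {c.contrast:28s} est={c.estimate:7.3f} p={c.p:.4g} ({c.adjust})"
            )
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    dataset_dir: str | Path,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
) -> Path:
    """simulate-independent entry point: load a dataset directory, analyse, write results."""
    config = config or AnalysisConfig()
    dataset = _stage("read_dataset")(read_dataset)(dataset_dir, config)
    results = analyse(dataset)

    tables: dict[str, pd.DataFrame] = {
        "events": _events_export(results["events"]),
        "selectivity": selectivity.selectivity_table(results["selectivity"]),
        "rose_diel": results["rose_diel"],
        "rose_tidal": results["rose_tidal"],
        "speeds": results["speeds"],
        "sensor_obs": results["sensor_obs"],
    }
    if results["depth_summary"] is not None:
        tables["depth_summary"] = results["depth_summary"]
    tables.update(_model_tables(results))

    out_dir = Path(out_dir)
    import hashlib

    input_hashes = {}
    for name in ("detections.csv", "receivers.csv", "crabs.csv", "waterlevels.csv"):
        input_hashes[name] = hashlib.sha256((Path(dataset_dir) / name).read_bytes()).hexdigest()
    extra = {
        "input_hashes": input_hashes,
        "selection_paths": {
            f"accel_{z}": fr.selection_path for z, fr in results["accel_models"].items()
        }
    }
    if results["speed_model"] is not None:
        extra["selection_paths"]["speed"] = results["speed_model"].selection_path
    write_results(tables, out_dir, config=config, extra_manifest=extra)
    (out_dir / "summary.txt").write_text(_summary_text(results))
    return out_dir


def _events_export(events: pd.DataFrame) -> pd.DataFrame:
    out = events.copy()
    for col in ("arrival_hsh", "departure_hsh"):
        out[col] = out[col].round(6)
    return out
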