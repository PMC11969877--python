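"""Ebb/flood segmentation of water-level series and level interpolation.

Tidal phase is derived from changes in water level: local maxima (high
water, HW) start an ebb interval, local minima (low water, LW) start a
flood interval. Intervals are half-open ``[turning point, next turning
point)`` so an instant exactly at HW belongs to the starting ebb.

Extrema are located on a centred-moving-average smoothed copy of the
series but timed on the raw 10-min grid. Levels between stations are
interpolated by inverse distance over the two chainage-closest stations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from ebbtrack.core_data import (
    AnalysisConfig,
    CoverageError,
    SchemaError,
    WaterLevelSeries,
    round_10min,
)

logger = logging.getLogger(__name__)

EBB = "ebb"
FLOOD = "flood"
UNAVAILABLE = "unavailable"


@dataclass(frozen=True)
class TidalInterval:
    start: int  # epoch s, inclusive
    end: int  # epoch s, exclusive
    phase: str  # "ebb" | "flood"
    hw_time: int | None  # preceding high water, epoch s; None if unknown
    truncated: bool = False  # touches the series boundary


@dataclass
class TidalAnnotation:
    """Alternating ebb/flood intervals for one location."""

    location: str
    chainage_km: float
    intervals: list[TidalInterval] = field(default_factory=list)
    _starts: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def start(self) -> int:
        return self.intervals[0].start

    @property
    def end(self) -> int:
        return self.intervals[-1].end

    def phase_at(self, t) -> tuple[str, float]:
        """Phase and hours since preceding HW at time ``t``.

        ``t`` is rounded to the nearest 10 min before lookup. Returns
        (phase, hours_since_high_water); the second element is NaN when
        the preceding HW is unknown (truncated leading interval).
        """
        if isinstance(t, pd.Timestamp):
            t_epoch = int(round_10min(t).value // 10**9)
        else:
            t_epoch = int(round_10min(int(t)))
        if t_epoch < self.start or t_epoch >= self.end:
            raise CoverageError(
                f"{self.location}: t={t_epoch} outside annotated span "
                f"[{self.start}, {self.end})"
            )
        if self._starts is None:
            self._starts = np.array([iv.start for iv in self.intervals], dtype=np.int64)
        i = int(np.searchsorted(self._starts, t_epoch, side="right")) - 1
        iv = self.intervals[i]
        hsh = (t_epoch - iv.hw_time) / 3600.0 if iv.hw_time is not None else float("nan")
        return iv.phase, hsh

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location": self.location,
                "start": pd.to_datetime([iv.start for iv in self.intervals], unit="s", utc=True),
                "end": pd.to_datetime([iv.end for iv in self.intervals], unit="s", utc=True),
                "phase": [iv.phase for iv in self.intervals],
                "hw_time": pd.to_datetime(
                    [iv.hw_time if iv.hw_time is not None else pd.NaT for iv in self.intervals],
                    unit="s",
                    utc=True,
                ),
                "truncated": [iv.truncated for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class TidalCycleStats:
    ebb_mean_h: float
    ebb_sd_h: float
    flood_mean_h: float
    flood_sd_h: float
    cycle_mean_h: float
    cycle_sd_h: float
    n_cycles: int


def interpolate_level(
    series_list: list[WaterLevelSeries], target_chainage: float, t
) -> float:
    """Inverse-distance weighted level at a chainage and time.

    Uses the two chainage-closest stations that cover ``t`` (after
    rounding to the 10-min grid), weights 1/|chainage_i - target|. A
    station exactly at the target returns its level directly; a single
    covering station is used unweighted.
    """
    if not series_list:
        raise CoverageError("no water-level stations supplied")
    if isinstance(t, pd.Timestamp):
        t_epoch = int(round_10min(t).value // 10**9)
    else:
        t_epoch = int(round_10min(int(t)))
    covering = [s for s in series_list if s.covers(t_epoch)]
    if not covering:
        raise CoverageError(f"no station covers epoch {t_epoch}")
    covering.sort(key=lambda s: (abs(s.chainage_km - target_chainage), s.station_id))
    nearest = covering[:2]
    d0 = abs(nearest[0].chainage_km - target_chainage)
    if d0 == 0.0 or len(nearest) == 1:
        return nearest[0].level_at(t_epoch)
    w = np.array([1.0 / abs(s.chainage_km - target_chainage) for s in nearest])
    levels = np.array([s.level_at(t_epoch) for s in nearest])
    return float(np.dot(w, levels) / w.sum())


def interpolate_series(
    series_list: list[WaterLevelSeries], target_chainage: float, location: str
) -> WaterLevelSeries:
    """Inverse-distance interpolated series at ``target_chainage``.

    Restricted to the common time grid of the two chainage-closest
    stations (or the single station if only one exists).
    """
    if not series_list:
        raise CoverageError("no water-level stations supplied")
    ranked = sorted(
        series_list, key=lambda s: (abs(s.chainage_km - target_chainage), s.station_id)
    )
    nearest = ranked[:2]
    if len(nearest) == 1 or abs(nearest[0].chainage_km - target_chainage) == 0.0:
        s = nearest[0]
        return WaterLevelSeries(location, target_chainage, s.times.copy(), s.levels.copy())
    a, b = nearest
    common, ia, ib = np.intersect1d(a.times, b.times, return_indices=True)
    if common.size == 0:
        raise CoverageError(f"stations {a.station_id}/{b.station_id} share no timestamps")
    wa = 1.0 / abs(a.chainage_km - target_chainage)
    wb = 1.0 / abs(b.chainage_km - target_chainage)
    levels = (wa * a.levels[ia] + wb * b.levels[ib]) / (wa + wb)
    return WaterLevelSeries(location, target_chainage, common, levels)


def _alternating_extrema(
    levels: np.ndarray, smooth_window: int, min_sep_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of alternating maxima/minima on the smoothed series.

    Returns (indices, is_max). Same-type neighbours are merged keeping
    the more extreme one; opposite-type pairs closer than the minimum
    half-cycle separation are removed as spurious wiggles.
    """
    sm = (
        pd.Series(levels)
        .rolling(smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    imax = argrelextrema(sm, np.greater_equal, order=2)[0]
    imin = argrelextrema(sm, np.less_equal, order=2)[0]
    # edge guard: partial smoothing windows fabricate extrema near boundaries
    lo_ok, hi_ok = smooth_window, levels.size - smooth_window
    imax = imax[(imax >= lo_ok) & (imax < hi_ok)]
    imin = imin[(imin >= lo_ok) & (imin < hi_ok)]
    # collapse flat-top plateaus to one representative index
    cand = sorted(
        [(int(i), True) for i in imax] + [(int(i), False) for i in imin]
    )
    merged: list[tuple[int, bool]] = []
    for idx, ismax in cand:
        if merged and merged[-1][1] == ismax:
            prev = merged[-1][0]
            if idx - prev <= 2:  # plateau continuation: keep the earlier index
                continue
            keep_new = (sm[idx] > sm[prev]) if ismax else (sm[idx] < sm[prev])
            if keep_new:
                merged[-1] = (idx, ismax)
            continue
        merged.append((idx, ismax))
    # drop opposite-type pairs violating the minimum half-cycle separation
    changed = True
    while changed:
        changed = False
        for i in range(len(merged) - 1):
            if merged[i + 1][0] - merged[i][0] < min_sep_samples:
                del merged[i : i + 2]
                changed = True
                break
        # re-enforce alternation after a removal
        i = 1
        while i < len(merged):
            if merged[i][1] == merged[i - 1][1]:
                prev, cur = merged[i - 1], merged[i]
                keep_new = (sm[cur[0]] > sm[prev[0]]) if cur[1] else (sm[cur[0]] < sm[prev[0]])
                del merged[i if not keep_new else i - 1]
                changed = True
            else:
                i += 1
    for a, b in zip(merged[:-1], merged[1:]):
        if a[1] == b[1]:
            raise RuntimeError("non-alternating extrema after filtering")
    # smoothing shifts extrema of asymmetric tides; re-time on the raw series
    w = smooth_window
    refined = []
    for i, ismax in merged:
        lo, hi = max(0, i - w), min(levels.size, i + w + 1)
        seg = levels[lo:hi]
        j = lo + (int(np.argmax(seg)) if ismax else int(np.argmin(seg)))
        refined.append((j, ismax))
    refined.sort()
    for a, b in zip(refined[:-1], refined[1:]):
        if a[1] == b[1] or b[0] <= a[0]:
            raise RuntimeError("non-alternating extrema after raw refinement")
    idx = np.array([m[0] for m in refined], dtype=int)
    ismax = np.array([m[1] for m in refined], dtype=bool)
    return idx, ismax


def segment_phases(
    series: WaterLevelSeries,
    min_half_cycle: float = 3.0,
    smooth_window: int = 7,
    include_truncated: bool = True,
) -> TidalAnnotation:
    """Segment a water-level series into alternating ebb/flood intervals.

    max->min intervals are ebb, min->max flood. Leading/trailing partial
    intervals (series boundary to first/last extremum) are included with
    ``truncated=True`` so nearby events stay covered, but are excluded
    from cycle statistics.
    """
    if series.times.size < 3:
        raise SchemaError(f"{series.station_id}: series too short to segment")
    span_h = (series.times[-1] - series.times[0]) / 3600.0
    min_sep = max(1, int(round(min_half_cycle * 3600 / 600)))
    idx, ismax = _alternating_extrema(series.levels, smooth_window, min_sep)
    if idx.size < 2:
        raise SchemaError(
            f"{series.station_id}: no full tidal cycle found in {span_h:.1f} h span"
        )
    times = series.times
    intervals: list[TidalInterval] = []

    if include_truncated and idx[0] > 0:
        # rising toward a max => flood; falling toward a min => ebb
        phase = FLOOD if ismax[0] else EBB
        intervals.append(
            TidalInterval(int(times[0]), int(times[idx[0]]), phase, None, truncated=True)
        )
    last_hw: int | None = None
    for k in range(idx.size - 1):
        t0, t1 = int(times[idx[k]]), int(times[idx[k + 1]])
        if ismax[k]:
            last_hw = t0
            intervals.append(TidalInterval(t0, t1, EBB, t0))
        else:
            intervals.append(TidalInterval(t0, t1, FLOOD, last_hw))
    if include_truncated and idx[-1] < times.size - 1:
        t0 = int(times[idx[-1]])
        if ismax[-1]:
            last_hw = t0
            phase = EBB
        else:
            phase = FLOOD
        intervals.append(
            TidalInterval(t0, int(times[-1]) + 600, phase, last_hw, truncated=True)
        )
    return TidalAnnotation(series.station_id, series.chainage_km, intervals)


def cycle_stats(annotation: TidalAnnotation) -> TidalCycleStats:
    """Mean/SD ebb, flood and HW-to-HW cycle durations (complete intervals only)."""
    complete = [iv for iv in annotation.intervals if not iv.truncated]
    ebbs = np.array([(iv.end - iv.start) / 3600.0 for iv in complete if iv.phase == EBB])
    floods = np.array([(iv.end - iv.start) / 3600.0 for iv in complete if iv.phase == FLOOD])
    hw_times = np.array([iv.start for iv in complete if iv.phase == EBB], dtype=float)
    cycles = np.diff(hw_times) / 3600.0
    if cycles.size < 2:
        raise SchemaError(
            f"{annotation.location}: need >= 2 complete cycles, found {cycles.size}"
        )
    return TidalCycleStats(
        ebb_mean_h=float(ebbs.mean()),
        ebb_sd_h=float(ebbs.std(ddof=1)) if ebbs.size > 1 else 0.0,
        flood_mean_h=float(floods.mean()),
        flood_sd_h=float(floods.std(ddof=1)) if floods.size > 1 else 0.0,
        cycle_mean_h=float(cycles.mean()),
        cycle_sd_h=float(cycles.std(ddof=1)) if cycles.size > 1 else 0.0,
        n_cycles=int(cycles.size),
    )


def annotate_receivers(
    series_list: list[WaterLevelSeries],
    receivers: pd.DataFrame,
    config: AnalysisConfig,
) -> dict[str, TidalAnnotation | None]:
    """Per-receiver tidal annotations (None where unavailable).

    Follows interpolation-then-phase order: levels are first interpolated
    to the receiver chainage, then segmented. Receivers outside the tidal
    zone, or with fewer than two usable stations, get None — tidal
    patterns cannot be analysed there.
    """
    out: dict[str, TidalAnnotation | None] = {}
    for row in receivers.itertuples():
        if row.zone != "tidal" or len(series_list) < 2:
            out[row.receiver_id] = None
            continue
        series = interpolate_series(series_list, float(row.chainage_km), str(row.receiver_id))
        out[row.receiver_id] = segment_phases(
            series,
            min_half_cycle=config.min_half_cycle_h,
            smooth_window=config.smooth_window,
        )
    return out
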