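"""Continuous-migration null model and chi-squared goodness-of-fit tests.

Under continuous migration, arrivals/departures are expected in each
phase proportionally to that phase's share of the diel or tidal cycle.
Expected proportions are weighted means of per-event phase-duration
fractions: circadian fractions vary by date (winter-summer), tidal
fractions by location, so each event contributes its own date's (or
receiver's) fraction vector — equivalent to weighting by the number of
occurrences of each date (or receiver) in the dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ebbtrack import solar
from ebbtrack.core_data import AnalysisConfig
from ebbtrack.tides import EBB, FLOOD, UNAVAILABLE, TidalCycleStats

logger = logging.getLogger(__name__)

CIRCADIAN_PHASES = ("day", "night", "twilight")
TIDAL_PHASES = (EBB, FLOOD)


@dataclass(frozen=True)
class SelectivityResult:
    event_type: str  # "arrival" | "departure"
    stratum: str  # zone name for circadian tests; "tidal_pooled" for tidal
    phases: tuple[str, ...]
    observed: tuple[int, ...]
    expected_props: tuple[float, ...]
    n: int
    chi2: float
    df: int
    p: float
    significant: bool
    p_adj: float | None = None  # Holm-adjusted, only when correction enabled

    def as_row(self) -> dict:
        return {
            "event_type": self.event_type,
            "stratum": self.stratum,
            "phases": ";".join(self.phases),
            "observed": ";".join(str(o) for o in self.observed),
            "expected_props": ";".join(f"{p:.6f}" for p in self.expected_props),
            "n": self.n,
            "chi2": self.chi2,
            "df": self.df,
            "p": self.p,
            "p_adj": self.p_adj if self.p_adj is not None else np.nan,
            "significant": self.significant,
        }


def props_from_durations(duration_rows: np.ndarray) -> np.ndarray:
    """Mean of per-event daily fraction vectors (rows sum to the cycle)."""
    rows = np.asarray(duration_rows, dtype=float)
    fracs = rows / rows.sum(axis=1, keepdims=True)
    return fracs.mean(axis=0)


def expected_circadian_props(
    events: pd.DataFrame, event_type: str, receivers: pd.DataFrame
) -> np.ndarray:
    """Expected (day, night, twilight) proportions for the given events.

    Each event contributes the phase-duration fractions of its own UTC
    date at its receiver's coordinates; the expectation is their mean.
    """
    if events.empty:
        raise ValueError("no events in stratum")
    rx = receivers.set_index("receiver_id")
    rows = []
    cache: dict[tuple, tuple] = {}
    for ts, rid in zip(events[f"{event_type}_t"], events["receiver_id"]):
        lat, lon = float(rx.loc[rid, "lat"]), float(rx.loc[rid, "lon"])
        key = (ts.date(), round(lat, 4), round(lon, 4))
        if key not in cache:
            d = solar.phase_durations(ts.date(), lat, lon)
            cache[key] = (d.day_h, d.night_h, d.twilight_h)
        rows.append(cache[key])
    return props_from_durations(np.array(rows))


def expected_tidal_props(
    events: pd.DataFrame, event_type: str, cycle_stats_by_receiver: dict[str, TidalCycleStats]
) -> np.ndarray:
    """Expected (ebb, flood) proportions, receiver-occurrence weighted.

    Each event contributes its receiver's mean ebb/flood duration divided
    by the mean cycle duration (mean ebb + mean flood) at that receiver.
    """
    annotated = events[events[f"{event_type}_tidal"] != UNAVAILABLE]
    if annotated.empty:
        raise ValueError("no tidal-annotated events")
    rows = []
    for rid in annotated["receiver_id"]:
        cs = cycle_stats_by_receiver[rid]
        rows.append((cs.ebb_mean_h, cs.flood_mean_h))
    return props_from_durations(np.array(rows))


def gof_test(observed_counts, expected_props, alpha: float = 0.05) -> dict:
    """Pearson chi-squared goodness-of-fit of counts against proportions.

    chi2 = sum (O_i - n p_i)^2 / (n p_i), df = k - 1, upper-tail p.
    """
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(props <= 0):
        raise ValueError("expected proportions must be strictly positive")
    n = obs.sum()
    if n < 1:
        raise ValueError("need at least one observation")
    props = props / props.sum()
    chi2, p = stats.chisquare(obs, f_exp=n * props)
    return {
        "chi2": float(chi2),
        "df": int(obs.size - 1),
        "p": float(p),
        "n": int(round(n)),
        "significant": bool(p < alpha),
    }


def _count(series: pd.Series, phases: tuple[str, ...]) -> np.ndarray:
    vc = series.value_counts()
    return np.array([int(vc.get(ph, 0)) for ph in phases])


def run_selectivity(
    events: pd.DataFrame,
    receivers: pd.DataFrame,
    cycle_stats_by_receiver: dict[str, TidalCycleStats],
    config: AnalysisConfig | None = None,
) -> list[SelectivityResult]:
    """All selectivity tests: 2 event types x 3 zones circadian + 2 tidal.

    Circadian tests are stratified by tidal class; tidal tests pool all
    tidal-zone events with a usable annotation. Phases whose expected
    proportion is zero in a stratum are dropped with df reduced. Empty
    strata are emitted with n = 0 and the test skipped.
    """
    config = config or AnalysisConfig()
    results: list[SelectivityResult] = []
    for event_type in ("arrival", "departure"):
        for zone in ("non_tidal", "transition", "tidal"):
            sub = events[events["zone"] == zone]
            if sub.empty:
                logger.info("no %s events in zone %s; test skipped", event_type, zone)
                results.append(
                    SelectivityResult(
                        event_type, zone, CIRCADIAN_PHASES, (0, 0, 0),
                        (np.nan, np.nan, np.nan), 0, np.nan, 2, np.nan, False,
                    )
                )
                continue
            props = expected_circadian_props(sub, event_type, receivers)
            observed = _count(sub[f"{event_type}_circadian"], CIRCADIAN_PHASES)
            phases = CIRCADIAN_PHASES
            keep = props > 0
            if not keep.all():
                phases = tuple(np.array(CIRCADIAN_PHASES)[keep])
                observed = observed[keep]
                props = props[keep] / props[keep].sum()
            res = gof_test(observed, props, alpha=config.alpha)
            results.append(
                SelectivityResult(
                    event_type, zone, phases, tuple(int(o) for o in observed),
                    tuple(float(p) for p in props), res["n"], res["chi2"],
                    res["df"], res["p"], res["significant"],
                )
            )
    for event_type in ("arrival", "departure"):
        sub = events[
            (events["zone"] == "tidal") & (events[f"{event_type}_tidal"] != UNAVAILABLE)
        ]
        if sub.empty:
            logger.info("no annotated tidal %s events; test skipped", event_type)
            results.append(
                SelectivityResult(
                    event_type, "tidal_pooled", TIDAL_PHASES, (0, 0),
                    (np.nan, np.nan), 0, np.nan, 1, np.nan, False,
                )
            )
            continue
        props = expected_tidal_props(sub, event_type, cycle_stats_by_receiver)
        observed = _count(sub[f"{event_type}_tidal"], TIDAL_PHASES)
        res = gof_test(observed, props, alpha=config.alpha)
        results.append(
            SelectivityResult(
                event_type, "tidal_pooled", TIDAL_PHASES,
                tuple(int(o) for o in observed), tuple(float(p) for p in props),
                res["n"], res["chi2"], res["df"], res["p"], res["significant"],
            )
        )
    if config.multiple_testing:
        results = _holm_adjust(results, config.alpha)
    return results


def _holm_adjust(results: list[SelectivityResult], alpha: float) -> list[SelectivityResult]:
    """Holm step-down correction across the family of performed tests."""
    import dataclasses

    tested = [i for i, r in enumerate(results) if r.n > 0 and np.isfinite(r.p)]
    m = len(tested)
    order = sorted(tested, key=lambda i: results[i].p)
    adj = {}
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * results[i].p))
        adj[i] = running
    out = list(results)
    for i in tested:
        out[i] = dataclasses.replace(
            results[i], p_adj=adj[i], significant=bool(adj[i] < alpha)
        )
    return out


def selectivity_table(results: list[SelectivityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def rose_bins(events: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Binned event counts for rose diagrams.

    ``diel``: counts per 1-h clock bin (UTC hour of day). ``tidal``:
    counts per 0.5-h hours-since-high-water bin, annotated tidal-zone
    events only.
    """
    rows = []
    if mode == "diel":
        for event_type in ("arrival", "departure"):
            hours = events[f"{event_type}_t"].dt.hour
            vc = hours.value_counts()
            for h in range(24):
                rows.append(
                    {"event_type": event_type, "bin_start": float(h),
                     "bin_end": float(h + 1), "count": int(vc.get(h, 0))}
                )
    elif mode == "tidal":
        for event_type in ("arrival", "departure"):
            hsh = events.loc[
                events[f"{event_type}_tidal"] != UNAVAILABLE, f"{event_type}_hsh"
            ].dropna()
            if len(hsh):
                edges = np.arange(0.0, np.ceil(hsh.max() * 2 + 1) / 2 + 0.5, 0.5)
            else:
                edges = np.array([0.0, 0.5])
            counts, _ = np.histogram(hsh, bins=edges)
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                rows.append(
                    {"event_type": event_type, "bin_start": float(lo),
                     "bin_end": float(hi), "count": int(c)}
                )
    else:
        raise ValueError(f"unknown rose mode {mode!r}")
    return pd.DataFrame(rows)
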