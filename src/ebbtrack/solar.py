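"""Circadian phase assignment from solar altitude.

Phases partition every instant at a position into ``day`` (sun centre
above -0.833 deg, the refraction-corrected rise/set convention),
``twilight`` (between -18 deg and -0.833 deg; dawn and dusk pooled) and
``night`` (below -18 deg, past the end of astronomical twilight).

The solar position follows the NOAA general solar calculations
(Meeus-derived low-precision series), accurate to well under a minute of
time for threshold crossings at mid-latitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date

import numpy as np
import pandas as pd

DAY_SET_ALT = -0.833  # deg, sunrise/sunset with standard refraction
NIGHT_SET_ALT = -18.0  # deg, astronomical twilight boundary

PHASES = ("day", "night", "twilight")

_UNIX_JD0 = 2440587.5


def solar_altitude(t_epoch, lat: float, lon: float):
    """Geometric solar altitude (degrees) at epoch seconds UTC.

    Vectorized over ``t_epoch``. No refraction term is applied; the phase
    thresholds already encode the horizon convention.
    """
    t = np.asarray(t_epoch, dtype=float)
    jd = t / 86400.0 + _UNIX_JD0
    T = (jd - 2451545.0) / 36525.0

    L0 = np.mod(280.46646 + T * (36000.76983 + T * 0.0003032), 360.0)
    M = np.deg2rad(357.52911 + T * (35999.05029 - T * 0.0001537))
    e = 0.016708634 - T * (0.000042037 + T * 0.0000001267)

    C = (
        np.sin(M) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(2 * M) * (0.019993 - 0.000101 * T)
        + np.sin(3 * M) * 0.000289
    )
    true_long = L0 + C
    omega = np.deg2rad(125.04 - 1934.136 * T)
    lam = np.deg2rad(true_long - 0.00569 - 0.00478 * np.sin(omega))

    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0
    eps = np.deg2rad(eps0 + 0.00256 * np.cos(omega))

    decl = np.arcsin(np.sin(eps) * np.sin(lam))

    y = np.tan(eps / 2.0) ** 2
    L0r = np.deg2rad(L0)
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * L0r)
        - 2.0 * e * np.sin(M)
        + 4.0 * e * y * np.sin(M) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * e * e * np.sin(2 * M)
    )  # minutes

    minutes_utc = np.mod(t, 86400.0) / 60.0
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    ha = np.deg2rad(tst / 4.0 - 180.0)

    phi = np.deg2rad(lat)
    alt = np.arcsin(np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.cos(ha))
    return np.rad2deg(alt)


def _phase_from_altitude(alt):
    alt = np.asarray(alt)
    out = np.where(alt > DAY_SET_ALT, "day", np.where(alt > NIGHT_SET_ALT, "twilight", "night"))
    return out


def circadian_phase(t, lat: float, lon: float):
    """Circadian phase at UTC time(s) ``t`` (Timestamp, array, or epoch s)."""
    scalar = np.isscalar(t) or isinstance(t, pd.Timestamp)
    t_epoch = _to_epoch(t)
    phase = _phase_from_altitude(solar_altitude(t_epoch, lat, lon))
    if scalar:
        return str(phase.item() if phase.ndim == 0 else phase[0])
    return phase


def _to_epoch(t):
    if isinstance(t, pd.Timestamp):
        return t.value // 10**9
    if isinstance(t, (pd.Series, pd.DatetimeIndex)):
        return np.asarray(t.astype("int64")) // 10**9
    arr = np.asarray(t)
    if np.issubdtype(arr.dtype, np.datetime64):
        return arr.astype("datetime64[s]").astype(np.int64)
    return arr


@dataclass(frozen=True)
class DailyPhaseDurations:
    """Hours of day/night/twilight within one UTC calendar day."""

    date: _date
    lat: float
    lon: float
    day_h: float
    night_h: float
    twilight_h: float

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "day": self.day_h / 24.0,
            "night": self.night_h / 24.0,
            "twilight": self.twilight_h / 24.0,
        }


def threshold_crossings(day: _date, lat: float, lon: float, threshold: float) -> list[float]:
    """Epoch-second times in the UTC day where altitude crosses ``threshold``.

    Found by sign change on a 1-min grid and refined by bisection to < 1 s.
    """
    start = int(pd.Timestamp(day, tz="UTC").value // 10**9)
    grid = start + 60 * np.arange(1441)
    f = solar_altitude(grid, lat, lon) - threshold
    out = []
    sign_change = np.nonzero(np.sign(f[:-1]) * np.sign(f[1:]) < 0)[0]
    for i in sign_change:
        lo, hi = float(grid[i]), float(grid[i + 1])
        flo = f[i]
        for _ in range(12):  # 60 s / 2^12 < 0.02 s
            mid = 0.5 * (lo + hi)
            fm = solar_altitude(mid, lat, lon) - threshold
            if np.sign(fm) == np.sign(flo):
                lo, flo = mid, fm
            else:
                hi = mid
        out.append(0.5 * (lo + hi))
    exact = np.nonzero(f == 0)[0]
    out.extend(float(grid[i]) for i in exact)
    return sorted(out)


def phase_durations(day: _date | pd.Timestamp, lat: float, lon: float) -> DailyPhaseDurations:
    """Durations of the three phases over one UTC day.

    Built from the crossing times of the two altitude thresholds, so the
    three durations partition exactly 24 h. At ~51 N near the June
    solstice the sun never reaches -18 deg: night is 0 h and twilight
    absorbs the whole dark period.
    """
    if isinstance(day, pd.Timestamp):
        day = day.date()
    start = int(pd.Timestamp(day, tz="UTC").value // 10**9)
    end = start + 86400
    cuts = sorted(
        set(
            [float(start), float(end)]
            + threshold_crossings(day, lat, lon, DAY_SET_ALT)
            + threshold_crossings(day, lat, lon, NIGHT_SET_ALT)
        )
    )
    totals = {"day": 0.0, "night": 0.0, "twilight": 0.0}
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        phase = str(_phase_from_altitude(solar_altitude(mid, lat, lon)))
        totals[phase] += (b - a) / 3600.0
    return DailyPhaseDurations(
        date=day,
        lat=lat,
        lon=lon,
        day_h=totals["day"],
        night_h=totals["night"],
        twilight_h=totals["twilight"],
    )
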