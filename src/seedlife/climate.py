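"""Daily climate series, hourly interpolation, and day length.

Everything downstream (thermal-time accumulation, maturation and imbibition
temperatures) is driven by daily minimum / mean / maximum air temperature.
Photothermal models need hourly resolution, so daily records are expanded to
24 hourly values with a fixed rule: the daily minimum is assumed between
21:00 and 02:00, the daily maximum between 09:00 and 14:00, and the daily
mean for the remaining hours.  Hour windows are half-open on hour starts,
which partitions the day into 5 minimum-, 5 maximum- and 14 mean-hours.

Sunrise and sunset are computed from a standard solar-position formula
rather than read from tables; only coarse day length matters here because
daylight enters the photothermal accumulator as a binary per-hour flag.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DailyClimateRecord",
    "ClimateSeries",
    "HOURS_AT_MIN",
    "HOURS_AT_MAX",
    "interpolate_hourly",
    "hourly_series",
    "day_length",
    "build_climatology",
    "shift_series",
    "extend_cyclic",
]

#: Hour starts assigned the daily minimum temperature (21:00-02:00, half-open).
HOURS_AT_MIN = frozenset({21, 22, 23, 0, 1})
#: Hour starts assigned the daily maximum temperature (09:00-14:00, half-open).
HOURS_AT_MAX = frozenset({9, 10, 11, 12, 13})


class ClimateError(ValueError):
    """Raised for invalid climate records or series."""


@dataclass(frozen=True)
class DailyClimateRecord:
    """One day of daily minimum / mean / maximum temperature (degC).

    ``sunrise`` and ``sunset`` are optional local clock times in fractional
    hours (e.g. 6.5 for 06:30); when absent they are derived from latitude
    and day of year.
    """

    date: _dt.date
    t_min: float
    t_mean: float
    t_max: float
    sunrise: float | None = None
    sunset: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_min", "t_mean", "t_max"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ClimateError(f"{self.date}: missing or non-finite {name}")
        if not (self.t_min <= self.t_mean <= self.t_max):
            raise ClimateError(
                f"{self.date}: require t_min <= t_mean <= t_max, got "
                f"({self.t_min}, {self.t_mean}, {self.t_max})"
            )


@dataclass
class ClimateSeries:
    """An ordered, gap-free sequence of :class:`DailyClimateRecord`.

    Parameters
    ----------
    records
        Daily records with strictly increasing, contiguous dates.
    latitude, longitude
        Site coordinates in decimal degrees (north / east positive).
    label
        Free-text identifier carried through outputs.
    """

    records: Sequence[DailyClimateRecord]
    latitude: float = 52.0
    longitude: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if not self.records:
            raise ClimateError("empty climate series")
        dates = [r.date for r in self.records]
        for prev, cur in zip(dates, dates[1:]):
            if cur <= prev:
                raise ClimateError(f"dates not strictly increasing at {cur}")
            if (cur - prev).days != 1:
                raise ClimateError(f"gap in series between {prev} and {cur}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def start(self) -> _dt.date:
        return self.records[0].date

    @property
    def end(self) -> _dt.date:
        return self.records[-1].date

    def record_for(self, date: _dt.date) -> DailyClimateRecord:
        idx = (date - self.start).days
        if idx < 0 or idx >= len(self.records):
            raise KeyError(f"{date} outside series [{self.start}, {self.end}]")
        return self.records[idx]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns date, tmin, tmean, tmax[, sunrise, sunset]."""
        df = pd.DataFrame(
            {
                "date": [r.date for r in self.records],
                "tmin": [r.t_min for r in self.records],
                "tmean": [r.t_mean for r in self.records],
                "tmax": [r.t_max for r in self.records],
            }
        )
        if any(r.sunrise is not None for r in self.records):
            df["sunrise"] = [r.sunrise for r in self.records]
            df["sunset"] = [r.sunset for r in self.records]
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        latitude: float = 52.0,
        longitude: float = 0.0,
        label: str = "",
    ) -> "ClimateSeries":
        recs = []
        has_sun = "sunrise" in df.columns and "sunset" in df.columns
        for row in df.itertuples(index=False):
            d = row.date
            if isinstance(d, pd.Timestamp):
                d = d.date()
            elif isinstance(d, str):
                d = _dt.date.fromisoformat(d)
            recs.append(
                DailyClimateRecord(
                    date=d,
                    t_min=float(row.tmin),
                    t_mean=float(row.tmean),
                    t_max=float(row.tmax),
                    sunrise=float(row.sunrise) if has_sun and pd.notna(row.sunrise) else None,
                    sunset=float(row.sunset) if has_sun and pd.notna(row.sunset) else None,
                )
            )
        return cls(recs, latitude=latitude, longitude=longitude, label=label)


def _hourly_temps(record: DailyClimateRecord) -> np.ndarray:
    temps = np.full(24, record.t_mean, dtype=float)
    temps[list(HOURS_AT_MIN)] = record.t_min
    temps[list(HOURS_AT_MAX)] = record.t_max
    return temps


def interpolate_hourly(record: DailyClimateRecord) -> pd.DataFrame:
    """Expand one daily record into 24 hourly rows.

    Returns a frame with columns ``time`` (hour start), ``temp`` (degC, one
    of the day's three temperatures) and ``daylight`` (bool, hour start
    within [sunrise, sunset)).  Sunrise/sunset default to 06:00/18:00 when
    the record carries none; callers with a known latitude should use
    :func:`hourly_series`, which fills them from :func:`day_length`.
    """
    sunrise = record.sunrise if record.sunrise is not None else 6.0
    sunset = record.sunset if record.sunset is not None else 18.0
    hours = np.arange(24)
    base = _dt.datetime.combine(record.date, _dt.time())
    return pd.DataFrame(
        {
            "time": [base + _dt.timedelta(hours=int(h)) for h in hours],
            "temp": _hourly_temps(record),
            "daylight": (hours >= sunrise) & (hours < sunset),
        }
    )


def hourly_series(series: ClimateSeries, start: _dt.date | None = None) -> pd.DataFrame:
    """Hourly expansion of a whole series (columns time/temp/daylight).

    Sunrise and sunset come from each record when present, otherwise from
    the series latitude via :func:`day_length`.
    """
    if start is None:
        start = series.start
    recs = [r for r in series.records if r.date >= start]
    if not recs:
        raise ClimateError(f"series does not cover {start}")
    n = len(recs)
    temps = np.empty(n * 24)
    daylight = np.empty(n * 24, dtype=bool)
    hours = np.arange(24)
    for i, rec in enumerate(recs):
        if rec.sunrise is not None and rec.sunset is not None:
            sr, ss = rec.sunrise, rec.sunset
        else:
            sr, ss, _ = day_length(series.latitude, rec.date.timetuple().tm_yday)
        temps[i * 24 : (i + 1) * 24] = _hourly_temps(rec)
        daylight[i * 24 : (i + 1) * 24] = (hours >= sr) & (hours < ss)
    times = pd.date_range(
        _dt.datetime.combine(recs[0].date, _dt.time()), periods=n * 24, freq="h"
    )
    return pd.DataFrame({"time": times, "temp": temps, "daylight": daylight})


def day_length(latitude: float, day_of_year: int) -> tuple[float, float, float]:
    """Sunrise, sunset (fractional clock hours) and day length for a site.

    Uses the standard sunrise equation with solar declination
    ``delta = -23.44 deg * cos(2*pi*(N+10)/365)``.  The hour angle is
    clamped so polar day / polar night return 24 h / 0 h rather than
    erroring.  Times are symmetric about 12:00 local; the model only needs
    day length and a coarse daylight window, so the equation of time and
    longitude correction are ignored (worst case well under an hour).
    """
    decl = np.radians(-23.44 * np.cos(2 * np.pi * (day_of_year + 10) / 365.0))
    lat = np.radians(latitude)
    cos_h = -np.tan(lat) * np.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    half = np.degrees(np.arccos(cos_h)) / 15.0  # half day length, hours
    return 12.0 - half, 12.0 + half, 2.0 * half


def build_climatology(series: ClimateSeries, label: str | None = None) -> ClimateSeries:
    """Average a multi-year series into one synthetic 365-day year.

    For each day of year the across-year means of tmin/tmean/tmax are taken;
    Feb 29 rows are folded into Feb 28 before averaging.  The result is
    dated in a fixed non-leap year (2001) and is intended to be recycled
    with :func:`extend_cyclic`.
    """
    df = series.to_frame()[["date", "tmin", "tmean", "tmax"]].copy()
    md = pd.DataFrame(
        {
            "month": [d.month for d in df["date"]],
            "day": [d.day for d in df["date"]],
        }
    )
    leap = (md["month"] == 2) & (md["day"] == 29)
    md.loc[leap, "day"] = 28
    df = pd.concat([df.drop(columns="date"), md], axis=1)
    mean = df.groupby(["month", "day"], as_index=False).mean()
    if len(mean) < 365:
        raise ClimateError(
            f"need at least one complete year to build a climatology "
            f"(only {len(mean)} distinct days of year present)"
        )
    recs = []
    for d in pd.date_range("2001-01-01", "2001-12-31"):
        row = mean[(mean["month"] == d.month) & (mean["day"] == d.day)].iloc[0]
        recs.append(
            DailyClimateRecord(
                date=d.date(),
                t_min=float(row["tmin"]),
                t_mean=float(row["tmean"]),
                t_max=float(row["tmax"]),
            )
        )
    return ClimateSeries(
        recs,
        latitude=series.latitude,
        longitude=series.longitude,
        label=label if label is not None else f"{series.label} climatology",
    )


def shift_series(series: ClimateSeries, delta: float) -> ClimateSeries:
    """Offset every daily temperature by ``delta`` degC (warming scenario)."""
    recs = [
        replace(r, t_min=r.t_min + delta, t_mean=r.t_mean + delta, t_max=r.t_max + delta)
        for r in series.records
    ]
    label = series.label
    if delta:
        label = f"{label} {delta:+g}degC".strip()
    return ClimateSeries(recs, latitude=series.latitude, longitude=series.longitude, label=label)


def extend_cyclic(
    climatology: ClimateSeries, start: _dt.date, n_days: int
) -> ClimateSeries:
    """Replicate a 365-day climatology over real calendar dates.

    ``start`` may be any date; each output day takes the climatology values
    for its (month, day), with Feb 29 of leap years borrowing Feb 28.  Used
    to build the multi-year horizon life-history simulations need.
    """
    if len(climatology) != 365:
        raise ClimateError("extend_cyclic expects a 365-day climatology")
    by_md = {(r.date.month, r.date.day): r for r in climatology.records}
    recs = []
    for i in range(n_days):
        d = start + _dt.timedelta(days=i)
        key = (d.month, 28 if (d.month == 2 and d.day == 29) else d.day)
        src = by_md[key]
        recs.append(replace(src, date=d))
    return ClimateSeries(
        recs,
        latitude=climatology.latitude,
        longitude=climatology.longitude,
        label=climatology.label,
    )
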