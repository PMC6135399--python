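"""Daily weather records and thermal-time (growing degree day) accumulation.

Thermal time is the physiological clock of the analysis: every growth curve
and growth index is expressed against accumulated growing degree days (ADD)
from sowing, computed with the De Candolle rule

    GDD_i = max(0, Tmean_i - Tb),    ADD_k = sum_{i<=k} GDD_i

with base temperature Tb = 10 degC for chia.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_TBASE = 10.0  # degC, base development temperature for chia

#: Canonical phenology stage codes, in developmental order:
#: emergence, branching, flowering, grain filling, maturity/harvest.
STAGES = ("E", "B", "F", "G", "M")

WEATHER_COLUMNS = [
    "date", "tmin", "tmax", "tmean", "rh_mean", "ea", "u2", "rn", "g", "pressure",
]


@dataclass(frozen=True)
class WeatherDay:
    """One day of meteorological drivers for GDD and ETo computation.

    Temperatures in degC, humidity in %, vapour pressure in kPa, wind at
    2 m in m s^-1, net radiation and soil heat flux in MJ m^-2 d^-1,
    atmospheric pressure in kPa.  ``tmean`` defaults to the arithmetic
    midrange (tmin + tmax) / 2 when not supplied.
    """

    date: dt.date
    tmin: float
    tmax: float
    u2: float
    rn: float
    g: float = 0.0
    tmean: float | None = None
    rh_mean: float | None = None
    ea: float | None = None
    pressure: float | None = None

    def __post_init__(self) -> None:
        for name in ("tmin", "tmax", "u2", "rn", "g"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)!r}")
        if self.tmax < self.tmin:
            raise ValueError(f"tmax ({self.tmax}) < tmin ({self.tmin}) on {self.date}")
        if self.tmean is not None and not (self.tmin <= self.tmean <= self.tmax):
            raise ValueError(
                f"tmean ({self.tmean}) outside [tmin, tmax] on {self.date}"
            )
        if self.rh_mean is not None and not (0.0 <= self.rh_mean <= 100.0):
            raise ValueError(f"rh_mean must be in [0, 100], got {self.rh_mean}")
        if self.u2 < 0:
            raise ValueError(f"u2 must be >= 0, got {self.u2}")

    @property
    def tmean_filled(self) -> float:
        """Mean temperature, defaulting to (tmin + tmax) / 2."""
        if self.tmean is not None:
            return self.tmean
        return 0.5 * (self.tmin + self.tmax)


@dataclass
class ThermalTimeSeries:
    """Accumulated growing degree days from sowing.

    ``das`` is the day index with entry 0 at the sowing date; ``add`` is the
    running (non-decreasing) cumulative sum of the clamped daily GDD values.
    """

    start_date: dt.date
    das: np.ndarray
    daily_gdd: np.ndarray
    add: np.ndarray
    tbase: float = DEFAULT_TBASE

    def __post_init__(self) -> None:
        self.das = np.asarray(self.das, dtype=int)
        self.daily_gdd = np.asarray(self.daily_gdd, dtype=float)
        self.add = np.asarray(self.add, dtype=float)
        if not (len(self.das) == len(self.daily_gdd) == len(self.add)):
            raise ValueError("das, daily_gdd and add must have equal length")
        if (self.daily_gdd < 0).any():
            raise ValueError("daily_gdd entries must be >= 0")
        if (np.diff(self.add) < -1e-9).any():
            raise ValueError("add must be non-decreasing")

    def __len__(self) -> int:
        return len(self.das)

    def das_to_add(self, das: float | Sequence[float]) -> float | np.ndarray:
        """Thermal time at a (possibly fractional) days-after-sowing value.

        Linear interpolation between the daily cumulative values; raises
        ``ValueError`` outside the covered range.
        """
        q = np.asarray(das, dtype=float)
        lo, hi = self.das[0], self.das[-1]
        if (q < lo).any() or (q > hi).any():
            raise ValueError(f"das out of range [{lo}, {hi}]")
        out = np.interp(q, self.das, self.add)
        return float(out) if np.isscalar(das) else out

    def to_frame(self) -> pd.DataFrame:
        dates = [self.start_date + dt.timedelta(days=int(d)) for d in self.das]
        return pd.DataFrame(
            {"date": dates, "das": self.das, "daily_gdd": self.daily_gdd, "add": self.add}
        )


@dataclass(frozen=True)
class PhenologyRecord:
    """One phenological event located on both time axes (DAS and ADD)."""

    stage: str
    das: int
    add: float

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")


def daily_gdd(tmean: float, tbase: float = DEFAULT_TBASE) -> float:
    """Daily growing degree days: max(0, tmean - tbase).

    Days colder than the base temperature contribute zero rather than
    negative thermal time (the clamping is applied per day, before any
    accumulation).
    """
    if not math.isfinite(tmean):
        raise ValueError(f"tmean must be finite, got {tmean!r}")
    if not math.isfinite(tbase):
        raise ValueError(f"tbase must be finite, got {tbase!r}")
    return max(0.0, tmean - tbase)


def accumulate_gdd(
    weather: Iterable[WeatherDay],
    tbase: float = DEFAULT_TBASE,
    start_date: dt.date | None = None,
    tceiling: float | None = None,
) -> ThermalTimeSeries:
    """Accumulate clamped daily GDD from sowing over a contiguous record.

    Parameters
    ----------
    weather
        Daily records sorted by date covering ``start_date`` onward with no
        gaps; entry 0 of the result corresponds to the sowing day.
    tbase
        Base development temperature (degC).
    start_date
        Sowing date; defaults to the first record's date.  Records before
        it are dropped.
    tceiling
        Optional upper temperature cutoff: tmean is capped at this value
        before the base subtraction.  Off by default.

    Raises
    ------
    ValueError
        If the record has a gap (the first missing date is named) or does
        not cover the sowing date.
    """
    days = sorted(weather, key=lambda w: w.date)
    if start_date is None:
        if not days:
            raise ValueError("empty weather record")
        start_date = days[0].date
    days = [w for w in days if w.date >= start_date]
    if not days or days[0].date != start_date:
        raise ValueError(f"weather record does not cover sowing date {start_date}")
    gdd = np.empty(len(days))
    for i, w in enumerate(days):
        expected = start_date + dt.timedelta(days=i)
        if w.date != expected:
            raise ValueError(f"gap in weather record: missing {expected}")
        t = w.tmean_filled
        if tceiling is not None:
            t = min(t, tceiling)
        gdd[i] = daily_gdd(t, tbase)
    return ThermalTimeSeries(
        start_date=start_date,
        das=np.arange(len(days)),
        daily_gdd=gdd,
        add=np.cumsum(gdd),
        tbase=tbase,
    )


def stage_table(
    series: ThermalTimeSeries, stage_das: Mapping[str, int]
) -> list[PhenologyRecord]:
    """Locate phenological stages on the thermal-time axis.

    ``stage_das`` maps stage codes (E, B, F, G, M) to their observed days
    after sowing; the ADD value is looked up in the accumulated series.
    Stages must appear in developmental order with strictly increasing DAS.
    """
    unknown = set(stage_das) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stage_das]
    das_vals = [stage_das[s] for s in ordered]
    if any(b <= a for a, b in zip(das_vals, das_vals[1:])):
        raise ValueError(f"stage DAS values must be strictly increasing: {das_vals}")
    records = []
    for stage, das in zip(ordered, das_vals):
        add = float(series.das_to_add(float(das)))
        records.append(PhenologyRecord(stage=stage, das=int(das), add=add))
    return records


def weather_to_frame(weather: Sequence[WeatherDay]) -> pd.DataFrame:
    """Tabulate weather records with the canonical CSV column order."""
    rows = []
    for w in weather:
        rows.append(
            {
                "date": w.date,
                "tmin": w.tmin,
                "tmax": w.tmax,
                "tmean": w.tmean,
                "rh_mean": w.rh_mean,
                "ea": w.ea,
                "u2": w.u2,
                "rn": w.rn,
                "g": w.g,
                "pressure": w.pressure,
            }
        )
    return pd.DataFrame(rows, columns=WEATHER_COLUMNS)


def frame_to_weather(frame: pd.DataFrame) -> list[WeatherDay]:
    """Inverse of :func:`weather_to_frame`; empty cells become ``None``."""
    out = []
    for row in frame.itertuples(index=False):
        date = row.date
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        elif isinstance(date, pd.Timestamp):
            date = date.date()

        def opt(v):
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        out.append(
            WeatherDay(
                date=date,
                tmin=float(row.tmin),
                tmax=float(row.tmax),
                tmean=opt(getattr(row, "tmean", None)),
                rh_mean=opt(getattr(row, "rh_mean", None)),
                ea=opt(getattr(row, "ea", None)),
                u2=float(row.u2),
                rn=float(row.rn),
                g=float(getattr(row, "g", 0.0) or 0.0),
                pressure=opt(getattr(row, "pressure", None)),
            )
        )
    return out
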