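"""FAO-56 Penman-Monteith reference evapotranspiration and irrigation dosing.

The crop coefficient (kc) of chia is unknown, so the trial irrigates on the
reference demand itself: daily ETo is accumulated and, each time the running
sum reaches a trigger depth (5-10 mm band, 8 mm by default), the plot
receives ``fraction`` x the accumulated depth as litres per square metre
(1 mm of water = 1 L m^-2).  The well-watered treatment uses fraction 1.0,
the deficit treatment 0.4.

ETo (mm d^-1) follows the FAO-56 formulation

    ETo = [0.408 Delta (Rn - G) + gamma 900/(T+273) u2 (es - ea)]
          / [Delta + gamma (1 + 0.34 u2)]
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chiagrow.weather import WeatherDay

DEFAULT_PRESSURE_KPA = 101.3
DEFAULT_TRIGGER_MM = 8.0


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapour pressure es(T) in kPa (Tetens/FAO-56 form)."""
    if t <= -237.3:
        raise ValueError(f"temperature {t} degC is at or below the formula pole")
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def slope_svp(t: float) -> float:
    """Slope Delta of the saturation vapour pressure curve, kPa degC^-1."""
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def psychrometric_constant(pressure: float = DEFAULT_PRESSURE_KPA) -> float:
    """Psychrometric constant gamma = 0.000665 * P, kPa degC^-1."""
    return 0.000665 * pressure


def pressure_at_elevation(z: float) -> float:
    """Barometric pressure (kPa) at elevation z (m), FAO-56 simplification."""
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


@dataclass(frozen=True)
class EToInputs:
    """The terms of the Penman-Monteith combination equation for one day."""

    delta: float  # slope of SVP curve, kPa degC^-1
    gamma: float  # psychrometric constant, kPa degC^-1
    rn: float     # net radiation, MJ m^-2 d^-1
    g: float      # soil heat flux, MJ m^-2 d^-1
    t: float      # mean air temperature at 2 m, degC
    u2: float     # wind speed at 2 m, m s^-1
    es: float     # saturation vapour pressure, kPa
    ea: float     # actual vapour pressure, kPa

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.u2 < 0:
            raise ValueError(f"u2 must be >= 0, got {self.u2}")
        if self.ea < 0 or self.es < self.ea:
            raise ValueError(f"need es >= ea >= 0, got es={self.es}, ea={self.ea}")

    @classmethod
    def from_weather(
        cls, day: WeatherDay, pressure: float | None = None
    ) -> "EToInputs":
        """Assemble the combination-equation terms from a weather record.

        Missing fields follow the FAO-56 fallbacks: tmean from the daily
        midrange, es as the mean of es(tmax) and es(tmin), ea from mean
        relative humidity applied to es(tmean), pressure from the record or
        the sea-level default.
        """
        t = day.tmean_filled
        es = 0.5 * (
            saturation_vapor_pressure(day.tmax) + saturation_vapor_pressure(day.tmin)
        )
        if day.ea is not None:
            ea = day.ea
        elif day.rh_mean is not None:
            ea = day.rh_mean / 100.0 * saturation_vapor_pressure(t)
        else:
            # dew point assumed at tmin when no humidity record exists
            ea = saturation_vapor_pressure(day.tmin)
        ea = min(ea, es)
        p = pressure if pressure is not None else (day.pressure or DEFAULT_PRESSURE_KPA)
        return cls(
            delta=slope_svp(t),
            gamma=psychrometric_constant(p),
            rn=day.rn,
            g=day.g,
            t=t,
            u2=day.u2,
            es=es,
            ea=ea,
        )


def eto_penman_monteith(inputs: EToInputs, clamp_negative: bool = False) -> float:
    """Daily reference evapotranspiration (mm d^-1).

    The value can be negative on days where available energy is negative
    and the vapour pressure deficit is nil; by default it is returned as
    computed (``clamp_negative=True`` floors it at zero).
    """
    num = (
        0.408 * inputs.delta * (inputs.rn - inputs.g)
        + inputs.gamma * (900.0 / (inputs.t + 273.0)) * inputs.u2 * (inputs.es - inputs.ea)
    )
    den = inputs.delta + inputs.gamma * (1.0 + 0.34 * inputs.u2)
    eto = num / den
    if clamp_negative:
        eto = max(0.0, eto)
    return eto


def eto_series(
    weather: Sequence[WeatherDay],
    pressure: float | None = None,
    clamp_negative: bool = False,
) -> pd.DataFrame:
    """Daily ETo for a weather record, as a ``date, eto_mm`` table."""
    rows = [
        (day.date, eto_penman_monteith(EToInputs.from_weather(day, pressure), clamp_negative))
        for day in weather
    ]
    return pd.DataFrame(rows, columns=["date", "eto_mm"])


@dataclass(frozen=True)
class IrrigationEvent:
    """One irrigation application triggered by accumulated ETo.

    ``applied_depth`` is in L m^-2, numerically equal to mm of water.
    """

    date: dt.date
    accumulated_eto: float
    applied_depth: float


def schedule_irrigation(
    dates: Sequence[dt.date],
    daily_eto: Sequence[float],
    fraction: float,
    trigger: float = DEFAULT_TRIGGER_MM,
    clamp_negative: bool = True,
) -> list[IrrigationEvent]:
    """Walk a daily ETo series and emit irrigation events.

    The accumulator starts at zero; each day's ETo is added (negative days
    contribute zero when ``clamp_negative``, the default for scheduling) and
    when the running sum first reaches or exceeds ``trigger`` an event is
    emitted with ``applied_depth = fraction * accumulated`` and the
    accumulator resets.  A trailing sub-trigger accumulation emits nothing.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if trigger <= 0:
        raise ValueError(f"trigger must be > 0, got {trigger}")
    if len(dates) != len(daily_eto):
        raise ValueError("dates and daily_eto must have equal length")
    events: list[IrrigationEvent] = []
    acc = 0.0
    for date, eto in zip(dates, daily_eto):
        contrib = max(0.0, eto) if clamp_negative else eto
        acc += contrib
        if acc >= trigger:
            events.append(
                IrrigationEvent(date=date, accumulated_eto=acc, applied_depth=fraction * acc)
            )
            acc = 0.0
    return events


def season_water_total(events: Iterable[IrrigationEvent]) -> float:
    """Total applied water over a season, L m^-2."""
    return float(sum(e.applied_depth for e in events))


def irrigation_to_frame(
    events: Sequence[IrrigationEvent], fraction: float
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "date": e.date,
                "accumulated_eto_mm": e.accumulated_eto,
                "applied_depth_lm2": e.applied_depth,
                "fraction": fraction,
            }
            for e in events
        ],
        columns=["date", "accumulated_eto_mm", "applied_depth_lm2", "fraction"],
    )
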