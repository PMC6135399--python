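"""Synthetic weather and plant-harvest data with the structure of both trials.

The generator is statistical, not mechanistic: weather is a sinusoidal
annual climate with seeded Gaussian daily anomalies, and plant observations
are draws around double-logistic truth curves whose default coefficient
sets are the published table rows for the four treatments.  Noise standard
deviations default to the published fit RMSEs (0.24-1.29 g for biomass,
36-137 cm^2 for leaf area), so a fit of the generated data should recover
the truth coefficients at the published goodness of fit.

Two trial layouts are provided:

* sowing-date trial (SD1 sown 7 Dec 2010, SD2 sown 31 Dec 2010): completely
  randomised, 5 replicates, 10 plants per harvest, harvests every 10-15 d
  from 24 DAS, season ~181 d, 50 plants m^-2, at the Antumapu site;
* irrigation trial (IT1 = 100% ETo, IT2 = 40% ETo, sown 23 Jan 2014):
  6 blocks, treatments from 54 DAS, harvests from 54 DAS, season ~151 d,
  55-65 plants m^-2 (60 used), at the Intihuasi site.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chiagrow.dlogistic import (
    BIOMASS_COEFFICIENTS,
    LEAF_AREA_COEFFICIENTS,
    DoubleLogisticCoefficients,
    double_logistic,
)
from chiagrow.indices import PLANTS_COLUMNS
from chiagrow.weather import ThermalTimeSeries, WeatherDay


@dataclass(frozen=True)
class SiteProfile:
    """Climatology of a trial site for the weather generator.

    The daily mean temperature follows
    ``mean_temp + amplitude * cos(2 pi (doy - peak_doy) / 365.25)`` with a
    Gaussian anomaly of sd ``noise_sd`` shared by tmin and tmax (southern
    hemisphere peak in mid January); ``diurnal_range`` separates tmax from
    tmin.  Radiation follows the same phase with its own amplitude.
    """

    name: str
    latitude: float
    mean_temp: float        # degC, annual mean
    amplitude: float        # degC, seasonal half-range
    noise_sd: float         # degC, daily anomaly sd
    diurnal_range: float    # degC, tmax - tmin
    mean_u2: float          # m s^-1
    mean_rh: float          # %
    rn_mean: float          # MJ m^-2 d^-1, annual mean net radiation
    rn_amplitude: float     # MJ m^-2 d^-1, seasonal half-range
    peak_doy: int = 15      # day of year of the warm peak (mid January)
    elevation: float = 0.0  # m
    u2_sd: float = 0.4
    rh_sd: float = 6.0
    rn_sd: float = 1.5

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be >= 0")


#: Antumapu (33.7 S, 420 m): warm temperate, mean annual temperature 14 degC.
#: The seasonal amplitude is calibrated so a Dec-sown season accumulates
#: thermal time at the pace of the trial's phenology (~1100 ADD by 121 DAS).
ANTUMAPU = SiteProfile(
    name="Antumapu", latitude=-33.67, mean_temp=14.0, amplitude=7.5,
    noise_sd=1.5, diurnal_range=14.0, mean_u2=1.8, mean_rh=62.0,
    rn_mean=11.0, rn_amplitude=7.0, elevation=420.0,
)

#: Intihuasi (30.0 S, 135 m): warm desert.  The climatology is calibrated to
#: the trial's thermal timeline (flowering at ~499 ADD around 70 DAS and
#: maturity at ~700 ADD over a 151-day Jan-Jun season), which requires a
#: cooler mean than the extreme-month normals alone would suggest.
INTIHUASI = SiteProfile(
    name="Intihuasi", latitude=-29.99, mean_temp=13.5, amplitude=5.0,
    noise_sd=1.2, diurnal_range=12.0, mean_u2=2.2, mean_rh=55.0,
    rn_mean=13.0, rn_amplitude=6.0, elevation=135.0,
)


def generate_weather(
    profile: SiteProfile, start_date: dt.date, n_days: int, seed: int = 0
) -> list[WeatherDay]:
    """Seeded synthetic daily weather series for a site.

    Deterministic for a fixed seed; with ``noise_sd = 0`` the mean
    temperature lies exactly on the climatological sinusoid.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    days: list[WeatherDay] = []
    for i in range(n_days):
        date = start_date + dt.timedelta(days=i)
        doy = date.timetuple().tm_yday
        phase = 2.0 * np.pi * (doy - profile.peak_doy) / 365.25
        tmean = profile.mean_temp + profile.amplitude * np.cos(phase)
        anomaly = rng.normal(0.0, profile.noise_sd) if profile.noise_sd > 0 else 0.0
        tmean += anomaly
        half = 0.5 * profile.diurnal_range
        rh = float(np.clip(rng.normal(profile.mean_rh, profile.rh_sd), 10.0, 100.0))
        u2 = float(max(0.1, rng.normal(profile.mean_u2, profile.u2_sd)))
        rn = profile.rn_mean + profile.rn_amplitude * np.cos(phase)
        rn = float(max(0.5, rn + rng.normal(0.0, profile.rn_sd)))
        days.append(
            WeatherDay(
                date=date,
                tmin=float(tmean - half),
                tmax=float(tmean + half),
                tmean=float(tmean),
                rh_mean=rh,
                u2=u2,
                rn=rn,
                g=0.0,
            )
        )
    return days


@dataclass(frozen=True)
class TreatmentTruth:
    """Ground truth for one treatment of a synthetic trial."""

    label: str
    biomass: DoubleLogisticCoefficients
    leaf_area: DoubleLogisticCoefficients
    density: float              # plants m^-2
    sowing_date: dt.date
    start_das: int = 0          # DAS at which the treatment effect starts
    biomass_sd: float = 0.5     # g, per-plant Gaussian noise
    leaf_area_sd: float = 50.0  # cm^2, per-plant Gaussian noise
    flowering_add: float = 1000.0
    stage_das: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a replicated harvest trial."""

    name: str
    site: SiteProfile
    treatments: tuple[TreatmentTruth, ...]
    n_blocks: int
    n_plants_per_harvest: int = 10
    cadence_days: int = 12
    first_harvest_das: int = 24
    season_days: int = 180

    def __post_init__(self) -> None:
        if not (10 <= self.cadence_days <= 15):
            raise ValueError("harvest cadence must lie in the 10-15 day band")

    def harvest_das(self) -> list[int]:
        return list(range(self.first_harvest_das, self.season_days + 1, self.cadence_days))


def _coef(table: pd.DataFrame, row: str, variable: str) -> DoubleLogisticCoefficients:
    return DoubleLogisticCoefficients.from_row(table.loc[row], variable=variable)


def sowing_date_design() -> TrialDesign:
    """The sowing-date trial: SD1 and SD2 at Antumapu, 5 replicates."""
    sd1_sowing = dt.date(2010, 12, 7)
    sd2_sowing = dt.date(2010, 12, 31)
    return TrialDesign(
        name="sowing_date",
        site=ANTUMAPU,
        treatments=(
            TreatmentTruth(
                label="SD1",
                biomass=_coef(BIOMASS_COEFFICIENTS, "SD1", "biomass"),
                leaf_area=_coef(LEAF_AREA_COEFFICIENTS, "SD1", "leaf_area"),
                density=50.0,
                sowing_date=sd1_sowing,
                biomass_sd=float(BIOMASS_COEFFICIENTS.loc["SD1", "rmse"]),
                leaf_area_sd=float(LEAF_AREA_COEFFICIENTS.loc["SD1", "rmse"]),
                flowering_add=1140.0,
                stage_das={"E": 7, "B": 35, "F": 121, "G": 150, "M": 178},
            ),
            TreatmentTruth(
                label="SD2",
                biomass=_coef(BIOMASS_COEFFICIENTS, "SD2", "biomass"),
                leaf_area=_coef(LEAF_AREA_COEFFICIENTS, "SD2", "leaf_area"),
                density=50.0,
                sowing_date=sd2_sowing,
                biomass_sd=float(BIOMASS_COEFFICIENTS.loc["SD2", "rmse"]),
                leaf_area_sd=float(LEAF_AREA_COEFFICIENTS.loc["SD2", "rmse"]),
                flowering_add=942.0,
                stage_das={"E": 7, "B": 35, "F": 97, "G": 130, "M": 155},
            ),
        ),
        n_blocks=5,
        first_harvest_das=24,
        season_days=180,
    )


def irrigation_design() -> TrialDesign:
    """The deficit-irrigation trial: IT1 (100% ETo) and IT2 (40% ETo)."""
    sowing = dt.date(2014, 1, 23)
    common = dict(density=60.0, sowing_date=sowing, start_das=54, flowering_add=499.0,
                  stage_das={"E": 8, "B": 45, "F": 70, "G": 100, "M": 130})
    return TrialDesign(
        name="irrigation",
        site=INTIHUASI,
        treatments=(
            TreatmentTruth(
                label="IT1",
                biomass=_coef(BIOMASS_COEFFICIENTS, "IT1", "biomass"),
                leaf_area=_coef(LEAF_AREA_COEFFICIENTS, "IT1", "leaf_area"),
                biomass_sd=float(BIOMASS_COEFFICIENTS.loc["IT1", "rmse"]),
                leaf_area_sd=float(LEAF_AREA_COEFFICIENTS.loc["IT1", "rmse"]),
                **common,
            ),
            TreatmentTruth(
                label="IT2",
                biomass=_coef(BIOMASS_COEFFICIENTS, "IT2", "biomass"),
                leaf_area=_coef(LEAF_AREA_COEFFICIENTS, "IT2", "leaf_area"),
                biomass_sd=float(BIOMASS_COEFFICIENTS.loc["IT2", "rmse"]),
                leaf_area_sd=float(LEAF_AREA_COEFFICIENTS.loc["IT2", "rmse"]),
                **common,
            ),
        ),
        n_blocks=6,
        first_harvest_das=54,
        season_days=150,
    )


def apply_deficit_effect(
    biomass: DoubleLogisticCoefficients,
    leaf_area: DoubleLogisticCoefficients,
    dm_reduction: float,
    la_reduction: float,
) -> tuple[DoubleLogisticCoefficients, DoubleLogisticCoefficients]:
    """Scale truth curves for a water-deficit treatment.

    The (y_max - y_min) range of the biomass curve shrinks by
    ``dm_reduction`` and of the leaf-area curve by ``la_reduction``
    (the observed deficit effect was a 54% biomass and 43% leaf-area
    decrease); y_min and the shape parameters are preserved.
    """
    for r in (dm_reduction, la_reduction):
        if not (0.0 <= r < 1.0):
            raise ValueError(f"reduction must be in [0, 1), got {r}")
    b = replace(biomass, y_max=biomass.y_min + (1.0 - dm_reduction) * (biomass.y_max - biomass.y_min))
    l = replace(leaf_area, y_max=leaf_area.y_min + (1.0 - la_reduction) * (leaf_area.y_max - leaf_area.y_min))
    return b, l


def _allocation(add: float, flowering_add: float, end_add: float) -> np.ndarray:
    """Organ mass fractions (leaf, stem, root, inflorescence), summing to 1.

    A phenology-indexed schedule: before flowering the plant is leafy with
    no inflorescence; after flowering the leaf fraction declines and the
    inflorescence fraction rises linearly with thermal time.
    """
    if end_add <= flowering_add:
        p = 0.0
    else:
        p = float(np.clip((add - flowering_add) / (end_add - flowering_add), 0.0, 1.0))
    f_leaf = 0.45 - 0.33 * p
    f_inflo = 0.35 * p
    rest = 1.0 - f_leaf - f_inflo
    return np.array([f_leaf, 0.75 * rest, 0.25 * rest, f_inflo])


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float, floor: float) -> float:
    """Gaussian draw re-drawn (not clamped) while at or below the floor."""
    if sd == 0:
        return max(mu, floor)
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if v > floor:
            return float(v)
    return floor  # pathological mu far below floor


def generate_plant_data(
    design: TrialDesign,
    thermal: Mapping[str, ThermalTimeSeries],
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated destructive-harvest observations for a whole trial.

    For every treatment, harvest date, block and plant, total dry mass and
    leaf area are drawn around the treatment's double-logistic truth curves
    evaluated at the harvest's thermal time, with per-plant Gaussian noise
    truncated above a small positive floor; organ masses follow the
    phenology-indexed allocation schedule and sum exactly to the drawn
    total.  Fully deterministic for a fixed seed.

    ``thermal`` maps treatment labels to their thermal-time series from
    sowing.  Returns the plants-CSV dialect plus ``das`` and ``add``.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(design.treatments))
    for trt, stream in zip(design.treatments, streams):
        rng = np.random.default_rng(stream)
        series = thermal[trt.label]
        harvests = design.harvest_das()
        if harvests[-1] > series.das[-1]:
            raise ValueError(
                f"thermal series for {trt.label} covers only {series.das[-1]} DAS, "
                f"season needs {harvests[-1]}"
            )
        end_add = float(series.das_to_add(float(harvests[-1])))
        truth_w = double_logistic(
            np.array([series.das_to_add(float(d)) for d in harvests]), trt.biomass
        )
        if np.mean(truth_w <= 0) > 0.5:
            raise ValueError(
                f"biomass truth curve for {trt.label} is non-positive over most of the season"
            )
        for das in harvests:
            add = float(series.das_to_add(float(das)))
            mu_w = float(double_logistic(add, trt.biomass))
            mu_a = float(double_logistic(add, trt.leaf_area))
            frac = _allocation(add, trt.flowering_add, end_add)
            for b in range(design.n_blocks):
                for p in range(design.n_plants_per_harvest):
                    w = _truncated_normal(rng, mu_w, trt.biomass_sd, 0.01)
                    la = _truncated_normal(rng, mu_a, trt.leaf_area_sd, 1.0)
                    organs = frac * w
                    rows.append(
                        {
                            "treatment": trt.label,
                            "block": f"B{b + 1}",
                            "plant_id": f"P{p + 1}",
                            "das": das,
                            "add": add,
                            "leaf_area_cm2": la,
                            "dm_leaf_g": organs[0],
                            "dm_stem_g": organs[1],
                            "dm_root_g": organs[2],
                            "dm_inflo_g": organs[3],
                        }
                    )
    return pd.DataFrame(rows, columns=PLANTS_COLUMNS[:4] + ["add"] + PLANTS_COLUMNS[4:])
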