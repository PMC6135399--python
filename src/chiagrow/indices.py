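"""Classical (Hunt interval) and functional (fitted-curve) growth indices.

Interval indices follow Hunt's formulas between successive destructive
harvests; functional indices are evaluated analytically on fitted
double-logistic curves for biomass W(t) and leaf area A(t):

    RGR = W'/W   (g g^-1 d^-1)      NAR = W'/A   (g cm^-2 d^-1)
    LAR = A/W    (cm^2 g^-1)        LWR = 1000 * LAR (cm^2 kg^-1)
    CGR = density * W'  (g m^-2 d^-1)
    SLW = leaf dry mass / leaf area (g cm^-2)
    LAI = leaf area * density / 10^4 (dimensionless)

Note on naming: the trial literature uses "LWR" for leaf area per unit
total dry biomass, which is conventionally LAR; both names are exposed
(LWR = LAR expressed per kg) and preserved in outputs.

Rates are per calendar day; the reporting axis is thermal time (ADD), with
interval values placed at interval midpoints on both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from chiagrow.dlogistic import FitResult, double_logistic, double_logistic_derivative
from chiagrow.weather import ThermalTimeSeries

ORGANS = ("dm_leaf", "dm_stem", "dm_root", "dm_inflo")

PLANTS_COLUMNS = [
    "treatment", "block", "plant_id", "das", "leaf_area_cm2",
    "dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g",
]


@dataclass(frozen=True)
class PlantObservation:
    """One destructive harvest record for a single plant.

    Masses in g plant^-1, leaf area in cm^2 plant^-1.  ``dm_total`` is the
    sum of the four organ masses.
    """

    treatment: str
    block: str
    plant_id: str
    das: int
    leaf_area: float
    dm_leaf: float
    dm_stem: float
    dm_root: float
    dm_inflo: float
    add: float | None = None

    def __post_init__(self) -> None:
        for name in ("leaf_area", "dm_leaf", "dm_stem", "dm_root", "dm_inflo"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    @property
    def dm_total(self) -> float:
        return self.dm_leaf + self.dm_stem + self.dm_root + self.dm_inflo


def classical_rgr(w1: float, w2: float, t1: float, t2: float) -> float:
    """Interval relative growth rate (ln w2 - ln w1)/(t2 - t1), g g^-1 d^-1."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError(f"masses must be > 0, got w1={w1}, w2={w2}")
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    return (math.log(w2) - math.log(w1)) / (t2 - t1)


def classical_nar(
    w1: float, w2: float, a1: float, a2: float, t1: float, t2: float
) -> float:
    """Interval net assimilation rate, g cm^-2 d^-1 (Hunt).

    NAR = [(w2 - w1)/(t2 - t1)] * [(ln a2 - ln a1)/(a2 - a1)]; the
    equal-area limit (w2 - w1)/((t2 - t1) a1) is used when a2 ~ a1.
    """
    if w1 <= 0 or w2 <= 0 or a1 <= 0 or a2 <= 0:
        raise ValueError("masses and areas must be > 0")
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    dw_dt = (w2 - w1) / (t2 - t1)
    if abs(a2 - a1) < 1e-9:
        return dw_dt / a1
    return dw_dt * (math.log(a2) - math.log(a1)) / (a2 - a1)


def ratio_indices(obs: PlantObservation) -> tuple[float, float, float]:
    """(LWR cm^2 kg^-1, LAR cm^2 g^-1, SLW g cm^-2) for one observation."""
    w = obs.dm_total
    if w <= 0:
        raise ValueError("dm_total must be > 0")
    if obs.leaf_area <= 0:
        raise ValueError("leaf_area must be > 0")
    lar = obs.leaf_area / w
    lwr = 1000.0 * lar
    slw = obs.dm_leaf / obs.leaf_area
    return lwr, lar, slw


def cgr(w1: float, w2: float, t1: float, t2: float, density: float) -> float:
    """Interval crop growth rate density*(w2 - w1)/(t2 - t1), g m^-2 d^-1.

    Negative during senescence/defoliation by construction.
    """
    if t2 <= t1:
        raise ValueError(f"need t2 > t1, got t1={t1}, t2={t2}")
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    return density * (w2 - w1) / (t2 - t1)


def lai(leaf_area: float, density: float) -> float:
    """Leaf area index: leaf_area (cm^2 plant^-1) x density (plants m^-2) / 10^4."""
    return leaf_area * density / 1.0e4


def functional_indices(
    fit_biomass: FitResult,
    fit_la: FitResult,
    density: float,
    t_grid: Sequence[float],
    leaf_fraction: float | Callable[[np.ndarray], np.ndarray] | None = None,
    add_per_day: float | None = None,
) -> pd.DataFrame:
    """Instantaneous growth indices on a thermal-time grid.

    Derivatives of the fitted curves are per unit ADD; they are converted
    to per-day rates with ``add_per_day`` (degC d per calendar day; 1.0 if
    not given, i.e. rates stay on the thermal axis).  SLW requires a leaf
    mass fraction model (scalar or callable of the grid); without one the
    column is NaN.

    The identity RGR = NAR x LAR holds exactly at every grid point.

    Raises ``ValueError`` if either fit did not converge or the biomass
    curve is non-positive anywhere on the grid (the offending thermal
    times are listed).
    """
    if not (fit_biomass.converged and fit_la.converged):
        raise ValueError("functional indices require converged fits")
    tt = np.asarray(t_grid, dtype=float)
    k = add_per_day if add_per_day is not None else 1.0
    w = double_logistic(tt, fit_biomass.coefficients)
    la_ = double_logistic(tt, fit_la.coefficients)
    if (w <= 0).any():
        bad = tt[w <= 0]
        raise ValueError(f"biomass curve non-positive at t = {bad[:5].tolist()}...")
    # dW/dday = dW/dADD * (ADD per day)
    wprime = double_logistic_derivative(tt, fit_biomass.coefficients) * k
    rgr = wprime / w
    nar = wprime / la_
    lar = la_ / w
    lwr = 1000.0 * lar
    cgr_ = density * wprime
    lai_ = la_ * density / 1.0e4
    if leaf_fraction is None:
        slw = np.full_like(tt, np.nan)
    else:
        frac = leaf_fraction(tt) if callable(leaf_fraction) else np.full_like(tt, float(leaf_fraction))
        slw = frac * w / la_
    return pd.DataFrame(
        {"t": tt, "w": w, "la": la_, "rgr": rgr, "nar": nar, "lar": lar,
         "lwr": lwr, "cgr": cgr_, "slw": slw, "lai": lai_}
    )


def interval_indices(
    plants: pd.DataFrame,
    density: float,
    thermal: ThermalTimeSeries | None = None,
) -> pd.DataFrame:
    """Hunt interval indices on treatment-mean harvest trajectories.

    ``plants`` uses the plants-CSV dialect (one row per plant per harvest);
    per-harvest means of total mass and leaf area are formed per treatment,
    then each successive harvest pair yields one row of interval indices at
    the midpoint DAS (and midpoint ADD when a thermal series is supplied).
    Ratio indices (LWR/LAR/SLW) are evaluated from the harvest means at the
    interval midpoint (mean of the two endpoint ratios).
    """
    df = plants.copy()
    df["dm_total_g"] = df[["dm_leaf_g", "dm_stem_g", "dm_root_g", "dm_inflo_g"]].sum(axis=1)
    out_rows = []
    for trt, grp in df.groupby("treatment", sort=False):
        means = (
            grp.groupby("das")[["dm_total_g", "leaf_area_cm2", "dm_leaf_g"]]
            .mean()
            .sort_index()
        )
        das = means.index.to_numpy(dtype=float)
        w = means["dm_total_g"].to_numpy()
        a = means["leaf_area_cm2"].to_numpy()
        wl = means["dm_leaf_g"].to_numpy()
        for i in range(len(das) - 1):
            t1, t2 = das[i], das[i + 1]
            mid = 0.5 * (t1 + t2)
            row = {
                "treatment": trt,
                "das_mid": mid,
                "add_mid": float(thermal.das_to_add(mid)) if thermal is not None else np.nan,
                "rgr": classical_rgr(w[i], w[i + 1], t1, t2),
                "nar": classical_nar(w[i], w[i + 1], a[i], a[i + 1], t1, t2),
                "cgr": cgr(w[i], w[i + 1], t1, t2, density),
            }
            lar1, lar2 = a[i] / w[i], a[i + 1] / w[i + 1]
            row["lar"] = 0.5 * (lar1 + lar2)
            row["lwr"] = 1000.0 * row["lar"]
            row["slw"] = 0.5 * (wl[i] / a[i] + wl[i + 1] / a[i + 1])
            row["lai"] = lai(0.5 * (a[i] + a[i + 1]), density)
            out_rows.append(row)
    return pd.DataFrame(out_rows)
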