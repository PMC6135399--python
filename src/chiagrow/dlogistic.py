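"""Double-logistic growth/senescence model and Levenberg-Marquardt fitting.

The whole crop cycle (emergence, growth, plateau, senescence) of either dry
biomass or leaf area is described on the thermal-time axis t (ADD) by six
parameters:

    y(t) = y_min + (y_max - y_min) * [ 1/(1 + exp(-m_S (t - S)))
                                     + 1/(1 + exp( m_A (t - A))) ]

S and A are the inflection thermal times of the growth and senescence
sigmoids and m_S, m_A their rates.  The printed sign convention is kept
exactly (no reparameterisation and no "-1" offset), so fitted coefficient
tables are directly comparable with published ones: fitted m_S can be
negative and y_min is an empirical asymptote, not a physical minimum
biomass.

Fitting minimises the residual sum of squares with a damped least-squares
(Levenberg-Marquardt) iteration started from a data-driven heuristic guess
plus seeded random restarts to guard against local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import expit

COEF_NAMES = ("y_min", "y_max", "m_s", "s", "m_a", "a")
TABLE_COLUMNS = ["y_min", "y_max", "m_s", "s", "m_a", "a", "rmse", "error", "r2", "p"]

#: Published biomass coefficient rows (g plant^-1; S, A in ADD) for the two
#: sowing dates (SD1, SD2) and the two irrigation treatments (IT1 = 100% ETo,
#: IT2 = 40% ETo), with their fit statistics.  Used as synthetic-trial truth
#: sets and as the reference for table arithmetic.
BIOMASS_COEFFICIENTS = pd.DataFrame(
    [
        [-67.742, 66.620, -0.0041, 1086.756, 0.0088, 1338.448, 0.4906, 0.542, 0.997, 0.000],
        [-103.846, 102.889, -0.0039, 1267.273, 0.0085, 1414.806, 1.2865, 1.412, 0.986, 0.000],
        [-35.275, 36.823, -0.0213, 558.557, 0.0289, 704.103, 0.485, 0.573, 0.997, 0.000],
        [-29.563, 30.584, -0.0209, 530.571, 0.0121, 665.970, 0.243, 0.287, 0.998, 0.000],
    ],
    index=["SD1", "SD2", "IT1", "IT2"],
    columns=TABLE_COLUMNS,
)

#: Published leaf-area coefficient rows (cm^2 plant^-1; S, A in ADD).
LEAF_AREA_COEFFICIENTS = pd.DataFrame(
    [
        [-2109.352, 2009.767, -0.0051, 721.877, 0.0101, 1142.224, 45.783, 50.774, 0.986, 0.000],
        [-1573.041, 1373.831, -0.0059, 511.217, 0.1472, 1214.244, 60.966, 67.375, 0.977, 0.000],
        [-979.047, 1185.154, -0.0303, 569.297, 0.4217, 668.279, 136.955, 147.663, 0.871, 0.000],
        [-604.942, 674.837, -0.0232, 513.865, 0.9289, 669.912, 35.809, 40.872, 0.977, 0.000],
    ],
    index=["SD1", "SD2", "IT1", "IT2"],
    columns=TABLE_COLUMNS,
)


@dataclass(frozen=True)
class DoubleLogisticCoefficients:
    """The six parameters of the double-logistic curve.

    Units of ``y_min``/``y_max`` follow ``variable`` (g plant^-1 for
    biomass, cm^2 plant^-1 for leaf area); ``s`` and ``a`` are thermal
    times (ADD) and ``m_s``, ``m_a`` their rates in (ADD)^-1.  No sign or
    ordering constraint is imposed: published fits show negative y_min and
    negative m_s.
    """

    y_min: float
    y_max: float
    m_s: float
    s: float
    m_a: float
    a: float
    variable: str = "biomass"

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"coefficients must be finite, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.y_min, self.y_max, self.m_s, self.s, self.m_a, self.a])

    @classmethod
    def from_array(
        cls, values: Sequence[float], variable: str = "biomass"
    ) -> "DoubleLogisticCoefficients":
        v = np.asarray(values, dtype=float)
        if v.shape != (6,):
            raise ValueError(f"expected 6 coefficients, got shape {v.shape}")
        return cls(*v, variable=variable)

    @classmethod
    def from_row(cls, row: pd.Series, variable: str = "biomass") -> "DoubleLogisticCoefficients":
        return cls(
            y_min=float(row["y_min"]),
            y_max=float(row["y_max"]),
            m_s=float(row["m_s"]),
            s=float(row["s"]),
            m_a=float(row["m_a"]),
            a=float(row["a"]),
            variable=variable,
        )


def double_logistic(
    t: float | np.ndarray, coef: DoubleLogisticCoefficients
) -> float | np.ndarray:
    """Evaluate the double-logistic curve at thermal time(s) t.

    Uses the logistic sigmoid in its numerically saturating form, so
    arbitrarily large |exponent| is safe.
    """
    tt = np.asarray(t, dtype=float)
    rng = coef.y_max - coef.y_min
    out = coef.y_min + rng * (
        expit(coef.m_s * (tt - coef.s)) + expit(-coef.m_a * (tt - coef.a))
    )
    return float(out) if np.isscalar(t) else out


def double_logistic_derivative(
    t: float | np.ndarray, coef: DoubleLogisticCoefficients
) -> float | np.ndarray:
    """Analytic slope dy/dt of the double-logistic curve (units per ADD)."""
    tt = np.asarray(t, dtype=float)
    rng = coef.y_max - coef.y_min
    p1 = expit(coef.m_s * (tt - coef.s))
    p2 = expit(-coef.m_a * (tt - coef.a))
    out = rng * (coef.m_s * p1 * (1.0 - p1) - coef.m_a * p2 * (1.0 - p2))
    return float(out) if np.isscalar(t) else out


def initial_guess(
    t: Sequence[float], y: Sequence[float], variable: str = "biomass"
) -> DoubleLogisticCoefficients:
    """Data-driven starting coefficients for the curve fit.

    Asymptote guesses pad the observed range by 10%; the inflection guesses
    S and A are the first and last half-range crossings of the series and
    the rate magnitudes are 4 / (crossing width), the slope of a unit
    logistic across its transition.  Rate signs follow the local direction
    of the data at each crossing so both rise-and-fall and table-style
    declining series start in the right basin.

    A series with no downward crossing (still growing at the last harvest)
    gets A defaulted to max(t) with a warning; a constant series is an
    error.
    """
    tt = np.asarray(t, dtype=float)
    yy = np.asarray(y, dtype=float)
    order = np.argsort(tt)
    tt, yy = tt[order], yy[order]
    rng = yy.max() - yy.min()
    if rng <= 0:
        raise ValueError("cannot form an initial guess from a constant series")
    y_min = yy.min() - 0.1 * rng
    y_max = yy.max() + 0.1 * rng
    mid = yy.min() + 0.5 * rng
    above = yy >= mid
    idx = np.flatnonzero(above)
    first, last = idx[0], idx[-1]
    span = tt[-1] - tt[0]
    width = max(span / 4.0, 1e-6)
    # first crossing: rising into the upper half -> m_s > 0 under the
    # printed convention; starting already above -> declining first sigmoid
    if first > 0:
        s_guess = 0.5 * (tt[first - 1] + tt[first])
        m_s = 4.0 / width
    else:
        s_guess = tt[min(last + 1, len(tt) - 1)] if last < len(tt) - 1 else tt[len(tt) // 2]
        m_s = -4.0 / width
    if last < len(tt) - 1:
        a_guess = 0.5 * (tt[last] + tt[last + 1])
    else:
        a_guess = tt[-1]
        warnings.warn(
            "series is still above half range at the last observation; "
            "senescence inflection A defaulted to max(t)",
            stacklevel=2,
        )
    m_a = 4.0 / width
    return DoubleLogisticCoefficients(
        y_min=y_min, y_max=y_max, m_s=m_s, s=s_guess, m_a=m_a, a=a_guess, variable=variable
    )


@dataclass
class FitResult:
    """A fitted double-logistic curve with its goodness-of-fit diagnostics.

    ``rmse`` is the n-denominator residual scale sqrt(SSE/n); ``error`` the
    residual standard error sqrt(SSE/(n-6)); ``p_value`` comes from the
    regression F test on (5, n-6) degrees of freedom.
    """

    coefficients: DoubleLogisticCoefficients
    rmse: float
    error: float
    r2: float
    p_value: float
    sse: float
    n_obs: int
    converged: bool
    n_iter: int
    covariance: np.ndarray | None = None
    rank_deficient: bool = False

    def predict(self, t: float | np.ndarray) -> float | np.ndarray:
        return double_logistic(t, self.coefficients)

    def to_row(self) -> pd.Series:
        c = self.coefficients
        return pd.Series(
            [c.y_min, c.y_max, c.m_s, c.s, c.m_a, c.a, self.rmse, self.error, self.r2, self.p_value],
            index=TABLE_COLUMNS,
        )


def goodness_of_fit(
    y: Sequence[float], yhat: Sequence[float], n_params: int = 6
) -> tuple[float, float, float, float]:
    """Goodness-of-fit statistics (rmse, error, r2, p) for a fitted curve.

    rmse = sqrt(SSE/n); error = sqrt(SSE/(n - n_params));
    r2 = 1 - SSE/SST; p from F = [(SST - SSE)/(n_params - 1)] /
    [SSE/(n - n_params)] on (n_params - 1, n - n_params) df.
    """
    yy = np.asarray(y, dtype=float)
    hh = np.asarray(yhat, dtype=float)
    n = len(yy)
    if n <= n_params:
        raise ValueError(f"need n > {n_params} observations, got {n}")
    sse = float(np.sum((yy - hh) ** 2))
    sst = float(np.sum((yy - yy.mean()) ** 2))
    rmse = np.sqrt(sse / n)
    error = np.sqrt(sse / (n - n_params))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    df1, df2 = n_params - 1, n - n_params
    if sse == 0:
        p = 0.0
    else:
        f = ((sst - sse) / df1) / (sse / df2)
        p = float(stats.f.sf(f, df1, df2)) if f > 0 else 1.0
    return float(rmse), float(error), float(r2), p


def _residuals(params: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    y_min, y_max, m_s, s, m_a, a = params
    rng = y_max - y_min
    return y_min + rng * (expit(m_s * (t - s)) + expit(-m_a * (t - a))) - y


def _start_points(
    t: np.ndarray, y: np.ndarray, init: DoubleLogisticCoefficients | None,
    restarts: int, rng: np.random.Generator, variable: str,
) -> list[np.ndarray]:
    starts: list[np.ndarray] = []
    if init is not None:
        starts.append(init.as_array())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            g = initial_guess(t, y, variable).as_array()
        except ValueError:
            g = None
    if g is not None and (init is None or not np.allclose(g, starts[0])):
        starts.append(g)
    # a declining-series alternative: both sigmoids past their inflection
    span = t.max() - t.min()
    r = y.max() - y.min()
    starts.append(
        np.array([y.min() - 0.5 * r, y.max() + 0.5 * r, -4.0 / max(span, 1e-6),
                  t.min() + 0.6 * span, 4.0 / max(span, 1e-6), t.min() + 0.9 * span])
    )
    base = list(starts)
    for _ in range(restarts):
        p = base[rng.integers(len(base))].copy()
        p[[0, 1]] += rng.normal(0.0, 0.2 * max(r, 1e-6), 2)
        p[[2, 4]] *= rng.uniform(0.5, 2.0, 2)
        p[[3, 5]] += rng.normal(0.0, 0.15 * max(span, 1e-6), 2)
        starts.append(p)
    return starts


def fit_double_logistic(
    t: Sequence[float],
    y: Sequence[float],
    init: DoubleLogisticCoefficients | None = None,
    max_iter: int = 5000,
    tol: float = 1e-10,
    restarts: int = 5,
    seed: int = 0,
    bounds: tuple[Sequence[float], Sequence[float]] | None = None,
    variable: str = "biomass",
) -> FitResult:
    """Fit the double-logistic curve by damped (Levenberg-Marquardt) least squares.

    Parameters
    ----------
    t, y
        Thermal times and observations; at least 7 distinct t are required.
    init
        Optional explicit starting coefficients; otherwise a heuristic
        guess is formed from the data.
    max_iter
        Cap on function evaluations per start.
    tol
        Relative cost-reduction convergence tolerance (step-norm tolerance
        is fixed at 1e-12).
    restarts
        Number of seeded random perturbations of the heuristic start; the
        lowest-SSE solution wins, ties broken by first found.
    bounds
        Optional (lower, upper) box bounds of length 6; when given the
        bounded trust-region reflective variant is used instead of plain LM.
    """
    tt = np.asarray(t, dtype=float)
    yy = np.asarray(y, dtype=float)
    if tt.shape != yy.shape or tt.ndim != 1:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if len(np.unique(tt)) < 7:
        raise ValueError("need at least 7 distinct t values to fit 6 parameters")
    rng = np.random.default_rng(seed)
    starts = _start_points(tt, yy, init, restarts, rng, variable)
    best = None
    for p0 in starts:
        try:
            if bounds is None:
                res = least_squares(
                    _residuals, p0, args=(tt, yy), method="lm",
                    max_nfev=max_iter, ftol=tol, xtol=1e-12, gtol=1e-12,
                )
            else:
                res = least_squares(
                    _residuals, np.clip(p0, bounds[0], bounds[1]), args=(tt, yy),
                    method="trf", bounds=bounds, max_nfev=max_iter, ftol=tol, xtol=1e-12,
                )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError("all optimiser starts failed")
    params = best.x
    J = best.jac
    # the curve is invariant under swapping (m_s, s) <-> (-m_a, a); fold the
    # mirrored branch back to the published convention s <= a
    if params[3] > params[5]:
        perm = [0, 1, 4, 5, 2, 3]
        signs = np.array([1.0, 1.0, -1.0, 1.0, -1.0, 1.0])
        params = signs * params[perm]
        J = J[:, perm] * signs
    coef = DoubleLogisticCoefficients.from_array(params, variable=variable)
    yhat = double_logistic(tt, coef)
    rmse, error, r2, p = goodness_of_fit(yy, yhat)
    sse = float(np.sum((yy - yhat) ** 2))
    # coefficient covariance from the Jacobian at the optimum
    JtJ = J.T @ J
    rank = np.linalg.matrix_rank(JtJ)
    rank_deficient = rank < 6
    s2 = sse / max(len(yy) - 6, 1)
    cov = s2 * np.linalg.pinv(JtJ)
    return FitResult(
        coefficients=coef,
        rmse=rmse,
        error=error,
        r2=r2,
        p_value=p,
        sse=sse,
        n_obs=len(yy),
        converged=bool(best.status > 0),
        n_iter=int(best.nfev),
        covariance=cov,
        rank_deficient=rank_deficient,
    )


def average_coefficients(
    rows: pd.DataFrame | Sequence[FitResult] | Sequence[pd.Series],
) -> pd.Series:
    """Element-wise arithmetic mean of coefficient rows and fit statistics.

    Mirrors the published "Average SD" / "Average IT" summary rows: each
    coefficient and each goodness-of-fit column is averaged independently.
    """
    if isinstance(rows, pd.DataFrame):
        if rows.empty:
            raise ValueError("cannot average an empty coefficient table")
        return rows[[c for c in TABLE_COLUMNS if c in rows.columns]].mean(axis=0)
    rows = list(rows)
    if not rows:
        raise ValueError("cannot average an empty list of fits")
    series = [r.to_row() if isinstance(r, FitResult) else pd.Series(r) for r in rows]
    return pd.concat(series, axis=1).mean(axis=1)


def compare_fits(fit_a: FitResult, fit_b: FitResult) -> float:
    """Two-sided p of a paired t test across the six coefficient values.

    Both fits must have converged.  Identical coefficient vectors (zero
    differences everywhere) give p = 1 by convention.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("compare_fits requires two converged fits")
    a = fit_a.coefficients.as_array()
    b = fit_b.coefficients.as_array()
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if np.std(d, ddof=1) == 0:
        return 0.0  # constant nonzero shift: t is infinite
    return float(stats.ttest_rel(a, b).pvalue)
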