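"""Incidence-trend models: linear and exponential fits, plateau summary,
and assembly of per-scenario incidence series with backward extrapolation.

The registry observes diagnoses only from its first year onward, but a
diagnosis that existed earlier still contributes to today's prevalence.  Four
scenarios reconstruct the unobserved history of the annual incidence rate
``I(t)``:

``raw``
    No diagnoses before the first observed year.
``model1_linear``
    ``I = a + b t`` fitted on the rising era; zero before the first observed
    year (the line is not extrapolated backwards below its origin).
``model2_exp1987``
    ``I = A exp(k t)`` fitted on the rising era and evaluated backwards
    (negative exponent) to 1987, the year the ADHD label entered DSM-III-R.
``model3_exp1980``
    As model 2, extended to 1980, when attention-deficit disorder entered
    DSM-III.

``t`` counts years since the fit origin (the first observed year), so the
intercept of either fit is the modelled rate in that year.  After the rising
era the observed rates fluctuate around a plateau; all four scenarios use the
observed rates there, and the plateau mean with its t-based 95% CI summarises
that era for CI propagation and forward projection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .registry import RegistryTable, incidence_rate

__all__ = [
    "MODEL_IDS",
    "TrendFit",
    "IncidenceSeries",
    "PlateauStats",
    "InsufficientDataError",
    "fit_linear",
    "fit_exponential",
    "plateau_stats",
    "build_incidence_series",
    "fold_change",
    "DEFAULT_FIT_WINDOW",
    "DEFAULT_PLATEAU_WINDOW",
]

#: Scenario identifiers, in reporting order.
MODEL_IDS = ("raw", "model1_linear", "model2_exp1987", "model3_exp1980")

#: Start year of nonzero incidence per scenario.
MODEL_START_YEARS = {
    "raw": None,  # first observed year of the table
    "model1_linear": None,
    "model2_exp1987": 1987,
    "model3_exp1980": 1980,
}

DEFAULT_FIT_WINDOW = (1997, 2003)
DEFAULT_PLATEAU_WINDOW = (2004, 2012)


class InsufficientDataError(ValueError):
    """Too few usable years in the requested window."""


@dataclass(frozen=True, slots=True)
class TrendFit:
    """Fitted parameters of a linear or exponential incidence trend.

    ``family`` is ``"linear"`` (rate = intercept + slope*t) or
    ``"exponential"`` (rate = intercept * exp(slope*t)); ``t`` is years since
    ``t_origin``.  For the exponential family the fit is log-linear OLS and
    ``r_squared`` is the log-scale coefficient of determination.
    """

    family: str
    intercept: float
    slope: float
    r_squared: float
    window: tuple[int, int]
    t_origin: int

    def predict(self, year: int | float) -> float:
        """Modelled incidence rate (per 100 000) at a calendar year."""
        t = year - self.t_origin
        if self.family == "linear":
            return self.intercept + self.slope * t
        return self.intercept * math.exp(self.slope * t)


@dataclass(frozen=True, slots=True)
class PlateauStats:
    """Mean, SD and t-based 95% CI of the incidence rate over the plateau era."""

    mean: float
    sd: float
    n: int
    ci95: tuple[float, float]
    window: tuple[int, int]


@dataclass(frozen=True)
class IncidenceSeries:
    """Per-year incidence rate (per 100 000) under one scenario.

    ``rates`` maps every year from ``start_year`` to the series end; by
    convention the rate is zero for any year before ``start_year``
    (:meth:`rate` implements this).
    """

    model_id: str
    start_year: int
    rates: dict[int, float]

    def __post_init__(self) -> None:
        years = sorted(self.rates)
        if years != list(range(years[0], years[-1] + 1)):
            raise ValueError(f"{self.model_id}: series years are not contiguous")
        if years[0] != self.start_year:
            raise ValueError(
                f"{self.model_id}: series must begin at start_year {self.start_year}"
            )
        if any(v < 0 for v in self.rates.values()):
            raise ValueError(f"{self.model_id}: negative incidence rate")

    @property
    def end_year(self) -> int:
        return max(self.rates)

    def rate(self, year: int) -> float:
        """Rate at ``year``; zero before the start year, KeyError after the end."""
        if year < self.start_year:
            return 0.0
        return self.rates[year]


def _window_rates(
    table: RegistryTable, window: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(years, rates) for the years in ``window`` that carry case counts."""
    lo, hi = window
    years = [
        y for y in range(lo, hi + 1) if y in table and table[y].new_cases is not None
    ]
    rates = np.array([incidence_rate(table[y]) for y in years])
    return np.array(years), rates


def fit_linear(
    table: RegistryTable,
    window: tuple[int, int] = DEFAULT_FIT_WINDOW,
    t_origin: int | None = None,
) -> TrendFit:
    """OLS of the annual incidence rate on years since ``t_origin``.

    ``t_origin`` defaults to the first year of the window, so the intercept is
    the fitted rate in that year.
    """
    years, rates = _window_rates(table, window)
    if len(years) < 3:
        raise InsufficientDataError(
            f"linear fit needs >=3 usable years in {window}, got {len(years)}"
        )
    origin = window[0] if t_origin is None else t_origin
    res = stats.linregress(years - origin, rates)
    return TrendFit(
        family="linear",
        intercept=float(res.intercept),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        window=window,
        t_origin=origin,
    )


def fit_exponential(
    table: RegistryTable,
    window: tuple[int, int] = DEFAULT_FIT_WINDOW,
    t_origin: int | None = None,
) -> TrendFit:
    """Log-linear least squares: OLS of ln(rate) on years since ``t_origin``.

    The intercept parameter ``A = exp(OLS intercept)`` is the fitted rate at
    the origin and ``k`` (the slope) is the exponential rate constant per
    year.  ``r_squared`` is reported on the log scale.  Any non-positive rate
    in the window is a domain error.
    """
    years, rates = _window_rates(table, window)
    if len(years) < 3:
        raise InsufficientDataError(
            f"exponential fit needs >=3 usable years in {window}, got {len(years)}"
        )
    if np.any(rates <= 0):
        bad = int(years[np.argmax(rates <= 0)])
        raise ValueError(
            f"exponential fit requires strictly positive rates; year {bad} is not"
        )
    origin = window[0] if t_origin is None else t_origin
    res = stats.linregress(years - origin, np.log(rates))
    return TrendFit(
        family="exponential",
        intercept=float(np.exp(res.intercept)),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        window=window,
        t_origin=origin,
    )


def plateau_stats(
    table: RegistryTable, window: tuple[int, int] = DEFAULT_PLATEAU_WINDOW
) -> PlateauStats:
    """Sample mean, SD and t-based 95% CI of the rates over ``window``.

    The CI is ``mean +/- t(n-1, 0.975) * sd / sqrt(n)``; with zero variance it
    degenerates to the mean.
    """
    _, rates = _window_rates(table, window)
    n = len(rates)
    if n < 2:
        raise InsufficientDataError(
            f"plateau statistics need >=2 usable years in {window}, got {n}"
        )
    mean = float(rates.mean())
    sd = float(rates.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))
    return PlateauStats(mean=mean, sd=sd, n=n, ci95=(mean - half, mean + half), window=window)


def build_incidence_series(
    table: RegistryTable,
    model_id: str,
    linear_fit: TrendFit | None = None,
    exponential_fit: TrendFit | None = None,
    fit_window: tuple[int, int] = DEFAULT_FIT_WINDOW,
) -> IncidenceSeries:
    """Assemble the full per-year incidence series for one scenario.

    The rising era (the fit window) takes fitted values for the model
    scenarios and observed rates for ``raw``; every later observed year takes
    the observed rate; years between the scenario start year and the fit
    window take backward-extrapolated fitted values (exponential scenarios
    only).  Fits are computed on demand if not supplied.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")
    first_obs = table.span[0]
    case_years = table.case_years()
    last_case_year = max(case_years)
    rates: dict[int, float] = {}

    if model_id == "raw":
        start = first_obs
        for y in range(first_obs, last_case_year + 1):
            rates[y] = incidence_rate(table[y])
    elif model_id == "model1_linear":
        start = first_obs
        fit = linear_fit or fit_linear(table, fit_window)
        for y in range(first_obs, fit_window[1] + 1):
            rates[y] = max(fit.predict(y), 0.0)
        for y in range(fit_window[1] + 1, last_case_year + 1):
            rates[y] = incidence_rate(table[y])
    else:
        start = MODEL_START_YEARS[model_id]
        fit = exponential_fit or fit_exponential(table, fit_window)
        for y in range(start, fit_window[1] + 1):
            rates[y] = fit.predict(y)
        for y in range(fit_window[1] + 1, last_case_year + 1):
            rates[y] = incidence_rate(table[y])
    return IncidenceSeries(model_id=model_id, start_year=start, rates=rates)


def fold_change(rates: dict[int, float], year_from: int, year_to: int) -> float:
    """Ratio rate(year_to) / rate(year_from); base-year rate must be nonzero."""
    base = rates[year_from]
    if base == 0:
        raise ValueError(f"fold change undefined: zero rate in base year {year_from}")
    return rates[year_to] / base
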