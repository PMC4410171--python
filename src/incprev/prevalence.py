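"""Recursive aging-out prevalence model with CI propagation.

Diagnosis is treated as permanent while a patient remains in the modelled
population (ages 0-19); the only outflow is reaching age 19.  With ``I(n)``
the annual incidence rate, ``G(n)`` the aging-out proportion, and ``P(n)``
the prevalence rate (all per 100 000 children and adolescents, proportions
dimensionless), the recursion is

    P(start) = I(start)
    P(n)     = P(n-1) * (1 - G(n)) + I(n)      for n > start,

i.e. last year's prevalent pool, less the share that turned 19, plus this
year's newly diagnosed.  Equivalently (the cohort view used as a test
oracle):  P(n) = sum over m <= n of I(m) * prod_{j=m+1..n} (1 - G(j)).

Working in rate space sidesteps the need for pre-registry population counts;
absolute case counts are derived only at reporting time.

Confidence bounds come from the plateau-era incidence CI: the recursion is
re-run twice with the lower (resp. upper) CI bound substituted for the
incidence rate from the plateau's first year onward, pre-plateau incidence
left at its point value.  Because the recursion is monotone in I, the two
trajectories bracket the point estimate wherever the substitution applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .registry import RegistryTable, aging_out_proportion
from .trends import IncidenceSeries, PlateauStats

__all__ = [
    "GSchedule",
    "PrevalenceSeries",
    "CrossModelSummary",
    "CaseCount",
    "build_g_schedule",
    "run_recursion",
    "propagate_ci",
    "cross_model_summary",
    "rate_to_count",
]


@dataclass(frozen=True)
class GSchedule:
    """Per-year aging-out proportion with a fill rule outside the observed span.

    Years before the first observed year return ``fill_before`` (the first
    observed value: pre-registry demography is taken as frozen at its earliest
    observation).  Years after the observed span raise unless explicitly
    extended (forward projection supplies its own constant).
    """

    values: dict[int, float]
    fill_before: float

    def __post_init__(self) -> None:
        for y, g in self.values.items():
            if not 0.0 <= g < 1.0:
                raise ValueError(f"aging-out proportion out of [0, 1) at year {y}: {g}")
        if not 0.0 <= self.fill_before < 1.0:
            raise ValueError(f"fill value out of [0, 1): {self.fill_before}")

    @property
    def span(self) -> tuple[int, int]:
        return min(self.values), max(self.values)

    def g(self, year: int) -> float:
        if year < self.span[0]:
            return self.fill_before
        try:
            return self.values[year]
        except KeyError:
            raise KeyError(
                f"aging-out proportion not available for year {year} "
                f"(observed span {self.span}); extend the schedule for projection"
            ) from None

    def extended(self, through_year: int, g_constant: float) -> "GSchedule":
        """A copy with ``g_constant`` filled in for years after the span."""
        vals = dict(self.values)
        for y in range(self.span[1] + 1, through_year + 1):
            vals[y] = g_constant
        return GSchedule(values=vals, fill_before=self.fill_before)


@dataclass(frozen=True)
class PrevalenceSeries:
    """Per-year prevalence rate per 100 000, optionally with CI trajectories."""

    model_id: str
    rates: dict[int, float]
    ci_lower: dict[int, float] | None = None
    ci_upper: dict[int, float] | None = None

    @property
    def start_year(self) -> int:
        return min(self.rates)

    @property
    def end_year(self) -> int:
        return max(self.rates)

    def to_frame(self) -> pd.DataFrame:
        years = sorted(self.rates)
        df = pd.DataFrame({"year": years, "rate": [self.rates[y] for y in years]})
        if self.ci_lower is not None and self.ci_upper is not None:
            df["ci_lower"] = [self.ci_lower.get(y) for y in years]
            df["ci_upper"] = [self.ci_upper.get(y) for y in years]
        return df


@dataclass(frozen=True)
class CrossModelSummary:
    """Cross-scenario robustness summary at one year."""

    year: int
    mean: float
    minimum: float
    maximum: float
    relative_deviation_pct: float
    ci_mean: tuple[float, float] | None = None
    per_model: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CaseCount:
    """A prevalent-case count: exact value and display value (nearest 50)."""

    exact: float
    display: int


def build_g_schedule(table: RegistryTable) -> GSchedule:
    """Aging-out proportions observed in the table, with the backward fill rule."""
    values = {r.year: aging_out_proportion(r) for r in table}
    return GSchedule(values=values, fill_before=values[table.span[0]])


def run_recursion(
    incidence: IncidenceSeries, g: GSchedule, end_year: int
) -> PrevalenceSeries:
    """Run the aging-out prevalence recursion from the series start to ``end_year``.

    Prevalence before the start year is zero, so the initial condition is
    simply the start year's incidence.
    """
    start = incidence.start_year
    if end_year > incidence.end_year:
        raise ValueError(
            f"incidence series for {incidence.model_id} ends at "
            f"{incidence.end_year}, cannot recurse to {end_year}"
        )
    p: dict[int, float] = {start: incidence.rate(start)}
    for n in range(start + 1, end_year + 1):
        p[n] = p[n - 1] * (1.0 - g.g(n)) + incidence.rate(n)
    return PrevalenceSeries(model_id=incidence.model_id, rates=p)


def _with_plateau_bound(incidence: IncidenceSeries, bound: float, from_year: int
                        ) -> IncidenceSeries:
    rates = {
        y: (bound if y >= from_year else r) for y, r in incidence.rates.items()
    }
    return IncidenceSeries(
        model_id=incidence.model_id, start_year=incidence.start_year, rates=rates
    )


def propagate_ci(
    series: PrevalenceSeries,
    incidence: IncidenceSeries,
    g: GSchedule,
    plateau: PlateauStats,
) -> PrevalenceSeries:
    """Attach CI trajectories obtained by re-running the recursion at the
    plateau CI bounds.

    The lower (upper) plateau-era incidence bound replaces the incidence rate
    for every year from the plateau's first year on; earlier years keep their
    point incidence.
    """
    lo_b, up_b = plateau.ci95
    from_year = plateau.window[0]
    end = series.end_year
    lo = run_recursion(_with_plateau_bound(incidence, lo_b, from_year), g, end)
    up = run_recursion(_with_plateau_bound(incidence, up_b, from_year), g, end)
    return PrevalenceSeries(
        model_id=series.model_id,
        rates=dict(series.rates),
        ci_lower=lo.rates,
        ci_upper=up.rates,
    )


def cross_model_summary(
    series_set: list[PrevalenceSeries], year: int
) -> CrossModelSummary:
    """Mean, range and relative deviation of the point estimates at ``year``.

    Relative deviation is (max - min) / mean * 100%.  If every series carries
    CI trajectories, the mean lower and upper bounds are reported too.
    """
    if len(series_set) < 2:
        raise ValueError("cross-model summary needs at least 2 series")
    vals: dict[str, float] = {}
    for s in series_set:
        if year not in s.rates:
            raise ValueError(f"series {s.model_id} does not cover year {year}")
        vals[s.model_id] = s.rates[year]
    points = list(vals.values())
    mean = sum(points) / len(points)
    ci_mean = None
    if all(s.ci_lower is not None and s.ci_upper is not None for s in series_set):
        ci_mean = (
            sum(s.ci_lower[year] for s in series_set) / len(series_set),
            sum(s.ci_upper[year] for s in series_set) / len(series_set),
        )
    return CrossModelSummary(
        year=year,
        mean=mean,
        minimum=min(points),
        maximum=max(points),
        relative_deviation_pct=(max(points) - min(points)) / mean * 100.0,
        ci_mean=ci_mean,
        per_model=vals,
    )


def rate_to_count(rate: float, pop_under19: int | float) -> CaseCount:
    """Convert a rate per 100 000 into a prevalent-case count.

    The display value is rounded to the nearest 50, the convention used for
    headline counts; the exact value is kept for computation.
    """
    if pop_under19 <= 0:
        raise ValueError("population must be positive")
    exact = rate * pop_under19 / 100_000.0
    return CaseCount(exact=exact, display=int(round(exact / 50.0)) * 50)
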