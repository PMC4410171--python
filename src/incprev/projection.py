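"""Forward projection of prevalence to a horizon year.

Beyond the last observed registry year the model assumes: (i) a constant
annual incidence rate, by default the plateau-era mean; (ii) a constant
aging-out proportion, by default the arithmetic mean of the last three
observed years; and (iii) geometric population growth at the geometric mean
of the last three year-over-year ratios.  The prevalence recursion is simply
continued under (i) and (ii); (iii) is used only to convert projected rates
into absolute case counts.

Under constant I and G the recursion contracts geometrically toward the
fixed point I/G, so projected trajectories approach that ceiling from below
without overshooting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .prevalence import GSchedule, PrevalenceSeries, run_recursion
from .registry import RegistryTable, aging_out_proportion
from .trends import IncidenceSeries, PlateauStats

__all__ = [
    "ProjectionConfig",
    "project_g",
    "project_population",
    "project_prevalence",
    "fold_report",
]


@dataclass(frozen=True)
class ProjectionConfig:
    """Assumptions for extending the recursion past the observed span.

    ``incidence_assumption`` is a constant rate per 100 000 (normally the
    plateau mean); ``g_assumption`` a constant aging-out proportion (normally
    the 3-year trailing mean); ``growth_window`` the number of trailing years
    used for the population growth factor.
    """

    horizon_year: int
    incidence_assumption: float
    g_assumption: float
    growth_window: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.g_assumption < 1.0:
            raise ValueError(f"g_assumption out of [0, 1): {self.g_assumption}")
        if self.incidence_assumption < 0:
            raise ValueError("incidence_assumption must be non-negative")


def project_g(table: RegistryTable, window: int = 3) -> float:
    """Arithmetic mean of the aging-out proportion over the last ``window``
    observed years."""
    last = table.span[1]
    years = range(last - window + 1, last + 1)
    for y in years:
        if y not in table:
            raise ValueError(f"year {y} not in registry span {table.span}")
    return sum(aging_out_proportion(table[y]) for y in years) / window


def project_population(
    table: RegistryTable, horizon_year: int, window: int = 3
) -> dict[int, float]:
    """Population aged <=19 per year from the last observed year to the horizon.

    The annual growth factor is the geometric mean of the year-over-year
    ratios across the trailing ``window`` years, applied multiplicatively.
    """
    last = table.span[1]
    if horizon_year <= last:
        raise ValueError(
            f"horizon year {horizon_year} must exceed the last observed year {last}"
        )
    ratios = [
        table[y].pop_under19 / table[y - 1].pop_under19
        for y in range(last - window + 2, last + 1)
    ]
    factor = math.exp(sum(math.log(r) for r in ratios) / len(ratios))
    pops: dict[int, float] = {last: float(table[last].pop_under19)}
    for y in range(last + 1, horizon_year + 1):
        pops[y] = pops[y - 1] * factor
    return pops


def project_prevalence(
    series: PrevalenceSeries,
    incidence: IncidenceSeries,
    g: GSchedule,
    config: ProjectionConfig,
    plateau: PlateauStats | None = None,
) -> PrevalenceSeries:
    """Continue one scenario's recursion to the horizon year.

    Point trajectory: I fixed at ``config.incidence_assumption`` and G at
    ``config.g_assumption`` for each projected year.  If ``plateau`` is given,
    CI trajectories are continued the same way with the plateau CI bounds as
    the constant incidence (re-deriving the observed-era bound paths from the
    plateau bounds, matching how the point series' bounds were built).
    """
    last = series.end_year
    if config.horizon_year < last:
        raise ValueError(
            f"horizon {config.horizon_year} precedes the series end {last}"
        )
    if config.horizon_year == last:
        return series

    def _extend(obs_rates: dict[int, float], inc_const: float) -> dict[int, float]:
        p = dict(obs_rates)
        for n in range(last + 1, config.horizon_year + 1):
            p[n] = p[n - 1] * (1.0 - config.g_assumption) + inc_const
        return p

    rates = _extend(series.rates, config.incidence_assumption)
    ci_lower = ci_upper = None
    if plateau is not None:
        from .prevalence import propagate_ci

        with_ci = (
            series
            if series.ci_lower is not None
            else propagate_ci(series, incidence, g, plateau)
        )
        ci_lower = _extend(with_ci.ci_lower, plateau.ci95[0])
        ci_upper = _extend(with_ci.ci_upper, plateau.ci95[1])
    return PrevalenceSeries(
        model_id=series.model_id, rates=rates, ci_lower=ci_lower, ci_upper=ci_upper
    )


def fold_report(
    series: PrevalenceSeries, year_pairs: list[tuple[int, int]]
) -> dict[tuple[int, int], float]:
    """P(year_to)/P(year_from) for each pair, on one scenario's trajectory."""
    out: dict[tuple[int, int], float] = {}
    for y_from, y_to in year_pairs:
        base = series.rates[y_from]
        if base == 0:
            raise ValueError(f"fold undefined: zero prevalence in year {y_from}")
        out[(y_from, y_to)] = series.rates[y_to] / base
    return out
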