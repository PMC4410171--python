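"""End-to-end analysis facade: fits -> series -> recursion -> projection.

Bundles the full registry analysis in one call so the command-line interface,
scripts and tests share a single code path.  All numbers are kept at full
precision; display rounding (rates to the nearest 10, counts to the nearest
50) happens only in human-readable reports.
"""

from __future__ import annotations

from dataclasses import dataclass

from .prevalence import (
    CaseCount,
    CrossModelSummary,
    PrevalenceSeries,
    build_g_schedule,
    cross_model_summary,
    propagate_ci,
    rate_to_count,
    run_recursion,
)
from .projection import (
    ProjectionConfig,
    fold_report,
    project_g,
    project_population,
    project_prevalence,
)
from .registry import RegistryTable
from .trends import (
    DEFAULT_FIT_WINDOW,
    DEFAULT_PLATEAU_WINDOW,
    MODEL_IDS,
    IncidenceSeries,
    PlateauStats,
    TrendFit,
    build_incidence_series,
    fit_exponential,
    fit_linear,
    plateau_stats,
)

__all__ = ["AnalysisResult", "run_analysis"]

#: Scenario whose trajectory is used for fold-change reporting: the deepest
#: backward extrapolation, hence the least sensitive to the start-year cutoff.
FOLD_MODEL = "model3_exp1980"


@dataclass(frozen=True)
class AnalysisResult:
    """Everything the standard registry analysis produces."""

    table: RegistryTable
    linear_fit: TrendFit
    exponential_fit: TrendFit
    plateau: PlateauStats
    incidence: dict[str, IncidenceSeries]
    prevalence: dict[str, PrevalenceSeries]          # observed era, with CI
    projected: dict[str, PrevalenceSeries]           # extended to the horizon
    target_year: int
    horizon_year: int
    summary_target: CrossModelSummary
    summary_horizon: CrossModelSummary
    count_target: CaseCount
    count_target_ci: tuple[CaseCount, CaseCount]
    count_horizon: CaseCount
    count_horizon_ci: tuple[CaseCount, CaseCount]
    projected_population: dict[int, float]
    folds: dict[tuple[int, int], float]


def run_analysis(
    table: RegistryTable,
    fit_window: tuple[int, int] = DEFAULT_FIT_WINDOW,
    plateau_window: tuple[int, int] = DEFAULT_PLATEAU_WINDOW,
    models: tuple[str, ...] = MODEL_IDS,
    target_year: int | None = None,
    horizon_year: int = 2020,
    growth_window: int = 3,
) -> AnalysisResult:
    """Run the complete analysis on a registry table.

    ``target_year`` (default: the last year with a case count) is the year of
    the headline cross-model prevalence estimate; ``horizon_year`` the
    projection endpoint.  Counts at the target year use the observed
    population; counts at the horizon use the geometric population
    projection.
    """
    lin = fit_linear(table, fit_window)
    expo = fit_exponential(table, fit_window)
    plat = plateau_stats(table, plateau_window)
    g = build_g_schedule(table)
    last_case_year = max(table.case_years())
    tgt = last_case_year if target_year is None else target_year

    cfg = ProjectionConfig(
        horizon_year=horizon_year,
        incidence_assumption=plat.mean,
        g_assumption=project_g(table, growth_window),
        growth_window=growth_window,
    )

    incidence: dict[str, IncidenceSeries] = {}
    prevalence: dict[str, PrevalenceSeries] = {}
    projected: dict[str, PrevalenceSeries] = {}
    for m in models:
        inc = build_incidence_series(
            table, m, linear_fit=lin, exponential_fit=expo, fit_window=fit_window
        )
        series = run_recursion(inc, g, last_case_year)
        series = propagate_ci(series, inc, g, plat)
        incidence[m] = inc
        prevalence[m] = series
        projected[m] = project_prevalence(series, inc, g, cfg, plateau=plat)

    sum_tgt = cross_model_summary(list(prevalence.values()), tgt)
    sum_hor = cross_model_summary(list(projected.values()), horizon_year)

    pop_tgt = table[tgt].pop_under19
    pops = project_population(table, horizon_year, growth_window)
    pop_hor = pops[horizon_year]

    fold_series = projected.get(FOLD_MODEL) or next(iter(projected.values()))
    first_year = table.span[0]
    folds = fold_report(
        fold_series,
        [(first_year, tgt), (first_year, horizon_year), (tgt, horizon_year)],
    )

    return AnalysisResult(
        table=table,
        linear_fit=lin,
        exponential_fit=expo,
        plateau=plat,
        incidence=incidence,
        prevalence=prevalence,
        projected=projected,
        target_year=tgt,
        horizon_year=horizon_year,
        summary_target=sum_tgt,
        summary_horizon=sum_hor,
        count_target=rate_to_count(sum_tgt.mean, pop_tgt),
        count_target_ci=(
            rate_to_count(sum_tgt.ci_mean[0], pop_tgt),
            rate_to_count(sum_tgt.ci_mean[1], pop_tgt),
        ),
        count_horizon=rate_to_count(sum_hor.mean, pop_hor),
        count_horizon_ci=(
            rate_to_count(sum_hor.ci_mean[0], pop_hor),
            rate_to_count(sum_hor.ci_mean[1], pop_hor),
        ),
        projected_population=pops,
        folds=folds,
    )
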