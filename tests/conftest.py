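import pytest

from incprev import builtin_table, run_analysis


@pytest.fixture(scope="session")
def table1():
    """The packaged national registry series, 1997-2013."""
    return builtin_table()


@pytest.fixture(scope="session")
def analysis(table1):
    """Full pipeline on the packaged series: 2012 reporting, 2020 horizon."""
    return run_analysis(table1, target_year=2012, horizon_year=2020)


def cohort_sum(incidence, g_of_year, start_year, n):
    """Brute-force oracle for the aging-out recursion.

    Each annual cohort I(m) is carried forward with survival-in-population
    factors (1 - G(j)) for j = m+1..n, and cohorts are summed:
    P(n) = sum_m I(m) * prod_j (1 - G(j)).  Deliberately independent of the
    recursion implementation.
    """
    total = 0.0
    for m in range(start_year, n + 1):
        surv = 1.0
        for j in range(m + 1, n + 1):
            surv *= 1.0 - g_of_year(j)
        total += incidence(m) * surv
    return total
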