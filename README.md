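# incprev

Estimating how many children and adolescents live with an ADHD diagnosis
when all a country records is the number of *new* diagnoses each year.

National outpatient registries often publish annual counts of newly
diagnosed patients, but no patient-level follow-up and no prevalence
register. `incprev` implements a compact epidemiological workflow for
exactly this situation, built around the Slovenian national series of
hyperkinetic-disorder diagnoses (ICD-10 F90.x, ages ≤19, 1997–2013), which
is packaged as its reference dataset. It is aimed at epidemiologists and
health-service planners who need defensible prevalence estimates and
short-horizon projections from aggregate registry tables.

## The model

Let `I(n)` be the annual incidence rate of diagnosis per 100 000 persons
aged ≤19 in year `n`, computed as `100000 · new_cases / pop_under19`, and
let `G(n)` be the **aging-out proportion** — the share of the ≤19
population that is 19 years old, i.e. the fraction leaving the modelled
population each year. Treating the diagnosis as permanent while the patient
stays under 20, the prevalence rate `P(n)` per 100 000 obeys the recursion

```
P(start) = I(start)
P(n)     = P(n−1) · (1 − G(n)) + I(n)
```

equivalent to a cohort sum `P(n) = Σ_{m≤n} I(m) · Π_{j=m+1..n} (1 − G(j))`.

Because the registry starts in 1997 but diagnoses existed earlier, the
unobserved incidence history is reconstructed under four scenarios:

| scenario | rising era 1997–2003 | before 1997 |
|---|---|---|
| `raw` | observed rates | zero |
| `model1_linear` | linear fit `I = a + b·t` | zero |
| `model2_exp1987` | exponential fit `I = A·e^{k·t}` | back-extrapolated to 1987 |
| `model3_exp1980` | exponential fit `I = A·e^{k·t}` | back-extrapolated to 1980 |

(`t` = years since 1997; 1987 and 1980 are the years the diagnostic label
entered DSM-III-R and DSM-III.) From 2004 to 2012 the observed rates
fluctuate around a plateau; its mean and t-based 95% CI drive confidence
propagation (the recursion re-run at the CI bounds) and the forward
projection, which continues the recursion with constant plateau incidence,
a trailing 3-year mean `G`, and a geometric population projection for
converting rates into case counts.

A seeded synthetic-registry generator (`incprev.synthetic`) reproduces the
assumed data-generating process — exponential rise, plateau, Poisson annual
counts, drifting population — for end-to-end validation and parameter-
recovery experiments.

## Worked example

```
$ incprev report --builtin --out-dir out
Registry analysis (builtin), span 1997-2013
Linear trend:      a = 27.67, b = 6.910, r2 = 0.875
Exponential trend: A = 30.36, k = 0.141, r2 = 0.932
Plateau 2004-2012: mean 77 per 100 000 (95% CI 67-87, n = 9)
Prevalence 2012: 750 per 100 000 (95% CI 670-810); count 2950 (95% CI 2650-3200); cross-model deviation 6.6%
Projected 2020: 1000 per 100 000 (95% CI 880-1100); count 4050 (95% CI 3600-4500)
Fold change 1997 -> 2012: 4.8
Fold change 1997 -> 2020: 6.3
Fold change 2012 -> 2020: 1.3
```

Reading the output: the incidence rate roughly tripled over 1997–2003
(fitted exponential rate constant k = 0.141/year), then plateaued around
77 per 100 000. Accumulating those diagnoses through the aging-out
recursion gives a 2012 prevalence of about 750 per 100 000 (0.75% of the
population aged ≤19, roughly 2950 children and adolescents), with the four
incidence scenarios agreeing to within ~7%. Holding incidence at the
plateau mean, prevalence keeps rising toward its demographic ceiling
(plateau mean / G ≈ 1460) and reaches about 1% by 2020 — some 4050
prevalent diagnoses after accounting for projected population growth.
Headline numbers above are display-rounded (rates to 10, counts to 50);
the CSV/JSON files under `out/` keep full precision.

The same pipeline is available as a library:

```python
import incprev

result = incprev.run_analysis(incprev.builtin_table(),
                              target_year=2012, horizon_year=2020)
print(result.summary_target.mean)   # 745.086... per 100 000
print(result.count_horizon.display) # 4050
```

Other subcommands: `incprev fit`, `incprev prevalence`, `incprev project`,
and `incprev simulate` (writes a synthetic registry CSV plus a JSON sidecar
of the generating parameters).

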