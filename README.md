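# hemovoi

Probabilistic cost-effectiveness and value-of-information analysis for
peroperative **goal-directed hemodynamic treatment (GDHT)** versus routine
fluid therapy in aged hip-fracture patients.

## The problem

A randomized trial (ClinicalTrials.gov NCT01141894) compares GDHT with
routine fluid treatment in patients ≥ 70 years undergoing hip-fracture
surgery. Its interim analysis (first ~100 patients) found a relative risk
of post-operative complications of 0.806 with a 95% CI of roughly 0.46 to
1.40 — statistically inconclusive. The decision-analytic question this
package answers is: *is it worth paying for further data collection?* The
monetary ceiling on the value of that research is the **expected value of
perfect information (EVPI)**:

```
EVPI(λ) = E_θ[ max_s NB_s(θ) ] − max_s E_θ[ NB_s(θ) ],
NB_s(θ) = λ · QALYs_s(θ) − Cost_s(θ)
```

where θ are the uncertain model inputs, s ∈ {routine, GDHT}, and λ is the
willingness-to-pay per quality-adjusted life-year. Scaled by the
discounted number of future patients facing the decision (the *effective
population*), it bounds the budget that further trial recruitment can
justify:

```
Population EVPI = EVPI per patient × effective population
```

## The model

* **Decision tree (hospital episode):** the cohort splits over five
  mutually exclusive outcomes — uncomplicated recovery, cardiovascular
  complications, stroke, other complications, death — with Dirichlet
  (52, 26, 2, 162, 160)-distributed probabilities under routine care.
  Under GDHT the death probability is scaled by a lognormal relative risk
  of mortality (median 0.75) and the complication probabilities by the
  lognormal relative risk fitted to the interim 2×2 table (median 0.806).
  Episode costs are gamma-distributed; delivery costs are €155 (routine)
  versus €781 (GDHT).
* **Markov cohort model (5 annual cycles):** states {well, post-CV,
  post-stroke, post-other, recovered-other, dead}, absorbing death,
  recovery allowed only from the other-complications state. Costs and
  QALYs accrue on start-of-cycle occupancies, discounted by 3% per year
  with the first year undiscounted.
* **PSA + EVPI:** second-order Monte Carlo over all input distributions,
  both strategies evaluated on common random numbers; quadrant summaries
  of the incremental cost-effectiveness plane; EVPI across a λ grid.

Model structure, distributions, and every assumption standing in for an
unpublished input are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

```sh
$ hemovoi interim
{
  "rr": 0.8055853920515574,
  "ci_low": 0.46454884465103136,
  "ci_high": 1.3969851208528257,
  "se_log_rr": 0.2808737836622154,
  "level": 0.95
}
```

The interim relative risk is 0.806: GDHT patients had ~19% fewer
complications, but the CI spans 1, so the classical analysis is
inconclusive. The value-of-information run (1,000 PSA iterations, the
default) quantifies what resolving that uncertainty is worth:

```sh
$ hemovoi evpi --iterations 1000 --seed 42 --lambda-grid 0:50000:10000 --out results/demo
effective population: 30378
 lambda  evpi_per_patient  population_evpi
    0.0        315.772277     9.592530e+06
10000.0        234.710843     7.130046e+06
20000.0        233.119516     7.081705e+06
30000.0        248.026309     7.534543e+06
40000.0        269.666606     8.191932e+06
50000.0        294.166493     8.936190e+06
```

Read: 30,378 future patients face this treatment choice over the
technology's 5-year lifetime (6,440 operations/year discounted at 3%). At
a willingness-to-pay of €20,000/QALY, perfect information would be worth
about €233 per patient in this run, i.e. about €7 million for the
population — the ceiling against which further trial funding should be
compared. The accompanying `results/demo/quadrants.json` reports that GDHT
was less costly *and* more effective in ~64% of iterations, and dominated
(more costly, less effective) in ~5%.

The same pipeline is scriptable from Python:

```python
from hemovoi import (build_default_table, run_psa, net_benefit,
                     evpi_per_patient, effective_population)

table = build_default_table()              # the published input table
sample = run_psa(table, n_iterations=20_000, seed=1)
evpi = evpi_per_patient(net_benefit(sample, lam=20_000))
print(evpi * effective_population(6_440, 5, 0.03) / 1e6)  # million EUR
```

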