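# Methods

This note records the model, its inputs, the numerical conventions, and
every place where the package's authors had to make a structural choice.

## Decision problem

Two strategies for peroperative fluid management in hip-fracture surgery
for patients ≥ 70 years: routine fluid therapy and goal-directed
hemodynamic treatment (GDHT, oxygen-delivery-targeted fluids plus
dobutamine). Outcomes are aggregated direct health-care costs (EUR) and
quality-adjusted life-years over five post-operative years. Decision
uncertainty is summarized as the expected value of perfect information
(EVPI), per patient and for the discounted future patient population.

## Short-term model (decision tree)

The hospital episode ends in exactly one of five outcomes:

| outcome | routine probability | distribution |
|---|---|---|
| in-hospital death | 0.129 | Dirichlet(52, 26, 2, 162, 160), jointly |
| cardiovascular complications | 0.065 | " |
| stroke | 0.005 | " |
| other complications | 0.403 | " |
| uncomplicated recovery | 0.398 | " |

The Dirichlet concentration corresponds to the observed outcome counts of
a 402-patient routine-care cohort, so the joint draw respects the simplex
constraint. Under GDHT the death probability is multiplied by the
mortality relative risk (lognormal, μ = −0.28, σ = 0.09; median 0.75,
from a meta-analysis of high-risk surgical patients) and each complication
probability by the complications relative risk, whose lognormal is fitted
from the interim trial table (15/49 vs 19/50): μ = log 0.8056 = −0.2162,
σ = se(log RR) = 0.2809. Uncomplicated recovery absorbs the remaining
mass. If a draw pushes the scaled mass above 1 the scaled components are
renormalized and uncomplicated set to 0; this happens in roughly 0.1–0.2%
of draws at the default inputs and is counted per run.

Each outcome carries a gamma-distributed episode cost. The tree has one
branch per outcome group, but the cost table prices subtypes, so the
grouped costs are mixtures: cardiovascular = unweighted mean of the
myocardial-infarction and heart-failure draws; other = unweighted mean of
the seven "other" component draws (pneumonia, renal failure, wound
infection, deep-vein thrombosis, pulmonary embolism, gastrointestinal
bleeding, confusion). The mixing weights are configurable
(`ModelConfig.cv_episode_weights` / `other_episode_weights`); subtype
frequencies within groups were not published, so equal weights are the
neutral default. Delivery costs (device + pre-operative + intra-anesthesia
staff) are deterministic: €11 + €27 + €117 = €155 for routine, €221 +
€159 + €401 = €781 for GDHT. No QALYs accrue in the tree.

## Long-term model (Markov cohort)

Six states: well, post-cardiovascular, post-stroke, post-other,
recovered-other, dead. The tree outcome mix seeds the model (uncomplicated
→ well, death → dead, complications → their post states). Annual cycles,
default horizon 5. Recovery is possible only from post-other;
cardiovascular and stroke sequelae are lifelong; dead is absorbing.

Transition probabilities per cycle:

* post-CV → dead: 0.107 / 0.058 / 0.056 in cycles 1/2/3; the cycle-3
  value is carried forward (only three years were published; carrying the
  last value forward is monotone and conservative).
* post-stroke → dead: 0.15 in cycle 1 (3-month stroke mortality), then
  the cardiovascular schedule. The original registry values for later
  years were not published; `ModelConfig.stroke_annual_mortality`
  overrides this follow-on schedule.
* post-other → dead with a Beta(31, 140) draw (mean 0.18), → recovered
  with Beta(70, 101) (mean 0.41), remainder stays.
* recovered-other → dead with Beta(17, 95) (mean 0.15).
* well → dead with `standard_annual_mortality`, default **0.10** — an
  implementer assumption standing in for the unpublished age-adjusted
  standard mortality of the ≈ 85-year-old source population (Swedish
  life-table mortality at that age is roughly 0.08–0.13). This is a
  configuration default, not a published value.

Utilities: well = Beta(322, 113) draw (mean 0.74); post-CV / post-stroke /
post-other = well minus a gamma-distributed decrement (printed magnitudes
0.19 / 0.35 / 0.15); recovered-other = Beta(227, 117) (mean 0.66); dead
= 0. Decrements are sampled as positive magnitudes, applied subtractively,
and resulting utilities floored at 0.

Costs: cycle 1 uses the first-year post-hospital schedule (well 147,
post-CV 7,673, post-stroke 7,512, post-other 7,314, recovered 396) plus a
one-off €4,837 charged to the fraction that died in hospital (the cost
table lists it as the first-year cost of the "state after death"; the
€9,020 death *episode* cost applies separately in the tree). Cycles 2+
use the later-year schedule (post-CV 386, post-stroke 402, post-other
396); well and recovered rows are unlisted there and read as 0. Deaths in
later cycles accrue no additional cost by default;
`ModelConfig.death_cost_every_cycle` charges the €4,837 to newly dead
fractions in every cycle instead.

Accrual and discounting: cycle k accrues cost and QALYs on the
start-of-cycle occupancies, discounted by (1 + r)^−(k−1) with r = 0.03 —
first year undiscounted, no half-cycle correction. This convention makes a
zero-mortality well cohort accrue utility × 4.7171 QALYs over 5 cycles,
and makes the effective population of 6,440 annual operations over 5
years exactly 30,378 — matching the published figure, which pins down the
discounting convention. The hospital-episode cost is undiscounted
(cycle 0).

## Parameter table and its inconsistencies

Gamma rows are read as (shape, scale) with mean shape × scale; beta as
(a, b); lognormal as (μ, σ) on the natural-log scale (so exp(−0.28) ≈
0.75 matches the printed mortality RR). Under these conventions every
distribution's analytic mean reproduces its printed point estimate within
2% — except four rows where the published table is internally
inconsistent:

| row | printed estimate | hyperparameter mean | gap |
|---|---|---|---|
| other-complications decrement | 0.15 | Gamma(100, 0.0007) → 0.07 | 53% |
| renal-failure episode cost | 12,197 | Gamma(6, 1442) → 8,652 | 29% |
| cardiovascular decrement | 0.19 | Gamma(298, 0.0006) → 0.1788 | 5.9% |
| confusion episode cost | 7,961 | Gamma(866, 9) → 7,794 | 2.1% |

Neither reading is silently corrected. The default source
(`param_source="hyperparams"`) uses the hyperparameters verbatim; the
alternative (`"moments"`) re-centres every distribution on the printed
point estimate while keeping its dispersion parameter (beta total a+b,
gamma shape, Dirichlet total concentration, lognormal σ). The four rows
are flagged in `KNOWN_INCONSISTENT_ROWS` and exempted from the fidelity
check, which asserts the 2% band on all other rows.

## PSA and value of information

Each iteration draws one full parameter set (table order, documented) and
evaluates both strategies on it — common random numbers, since both arms
share the same biology and differ only in the relative-risk application
and delivery costs. Default 1,000 iterations (the conventional run size);
headline reproductions use 20,000 to push Monte Carlo error below
reporting precision (about 10 s on one CPU). Quadrant classification
assigns exact-zero increments to the more-effective / less-costly side
(measure-zero; logged if counted). EVPI is computed exactly from the
net-benefit matrix as mean-of-row-maxima minus maximum column mean, is
clamped at 0 against floating-point residue, and equals exhaustive
enumeration on any finite scenario — the toy scenarios in
`synthetic_data` (EVPI 5, 0, 0 by hand enumeration) pin this down. The
effective population rounds down.

## Synthetic data

`simulate_trial` draws independent per-arm binomial event counts (control
arm first) for a 1:1 trial; defaults mirror the interim design (50 per
arm, control risk 0.38, true RR ≈ 0.8). It emulates only the binary
composite endpoint: no per-complication subtypes, no time-to-event
structure, no enrolment logistics, and no within-patient correlation —
so tests passing on it validate the estimator and pipeline mechanics, not
the clinical realism of any particular trial. The sample-size calculator
uses the pooled-variance normal approximation; with control risk 0.61, RR
0.63, 80% power and α = 0.05 it returns 152 in total, and 468 when only
57% of the risk reduction is assumed realizable (dilution factor,
`RR' = 1 − 0.57 × (1 − RR)`) — consistent with the trial's planned
enrolment of 460.

## Reconstruction fidelity and known limitations

Deterministic quantities reproduce exactly: interim RR 0.806, CI upper
bound 1.397, effective population 30,378. Direct evaluation of the Wald
formula gives a lower bound of 0.4645 where reports of this interim
analysis print 0.464 — a final-digit rounding difference, documented and
not chased.

The stochastic results depend on inputs the original analysis did not
publish (standard annual mortality, the post-stroke follow-on schedule,
episode-cost mixing weights, the death-cost policy), for which the
defaults above stand in. With the default table and 20,000 iterations the
package reproduces the published pattern — GDHT dominant in about two
thirds of iterations, dominated in ~5%, per-patient EVPI in the low
hundreds of euros rising with λ, population EVPI in the €6–9 million
range — but the per-patient EVPI at €50,000/QALY and the dominant-quadrant
share sit, respectively, about 20% and 9 percentage points below the
published 337 and 76.2%. This is reconstruction bias from the unpublished
inputs, not Monte Carlo noise (quadrant MC standard error ≈ 0.3 pp at
N = 20,000). Under the `moments` source the €50,000 EVPI moves to ~344,
matching the published 337, which suggests the original spreadsheet
parameterized at least some inputs from printed means; the default
nonetheless remains the printed hyperparameters.

Other limitations: cohort-level (no microsimulation), no age progression
of mortality within the horizon beyond the published schedules, one
complication per patient, EVPI only (no EVPPI/EVSI), currency fixed in
euros (the SEK conversion rate used for the original cost data is
metadata, never applied at runtime).
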