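# Methods

## Model structure

`hivdes` simulates independent individual trajectories from ART initiation
to death with a discrete-event engine. The state of an individual is the
`PatientState` record: demographics (sex, age, employment, transmission
group, hepatitis-C co-infection), clinical markers (CD4⁺ count, log₁₀ viral
load, adherence), a four-class resistance score, the current therapy line
(1–3 or non-suppressive), regimen characteristics (number of protease
inhibitors, doses/day, pills/day), an absorbing AIDS flag, and a scheduled
non-HIV death age.

At every decision point the engine samples a candidate time for each
admissible event and advances to the earliest one. Event-time models are
Weibull distributions parameterised by shape `p` and *median* `m`; the
scale is recovered as λ = m/(ln 2)^{1/p}. Covariates shift the median
additively (months per unit deviation from the arm's reference profile),
and sampling is conditional on the time already survived on the event's
clock (the inverse-survival solution `t = λ((t₀/λ)^p − ln u)^{1/p}`), so
history accumulated between events is never discarded.

Clock conventions. Suppression and failure clocks run per line/regimen
(suppression restarts when a line or a third-line attempt starts; failure
runs from the suppression date; regimen switch from the current regimen
start). Recurring events — hospitalization, AIDS-defining events,
resistance class steps — are renewal processes conditioned on the time
since their last occurrence. One-shot processes (first resistance, HIV
death) run from ART initiation. Conditioning a renewal event on the global
clock would push an increasing-hazard Weibull deep into its tail and fire
it almost continuously, which motivated this split.

Line logic. Lines 1 and 2 are left at the first confirmed virological
failure or when suppression is not reached within the 12-month deadline
(the deadline used in clinical practice in the data period; configurable —
current guidance uses 6 months). Line 3 is never left: failures there
reshuffle the regimen and restart the suppression window, until resistance
reaches class 4, which starts non-suppressive therapy. "Confirmed" failure
is modelled as a single composite event, with no explicit confirmatory-test
delay. Event-time ties are broken by a fixed priority in which death
preempts everything.

Per-line suppression attainment is scored on the line's *first* regimen
attempt (suppression achieved before any failure in that line). For lines
1–2 this coincides with attainment ever (any failure exits the line); for
line 3, which retries indefinitely, it is the only definition comparable
across lines and it reproduces the trial-derived 46% first-attempt figure.

## Evolving state

* CD4⁺ follows a line-specific logarithmic curve `a·ln(1 + b·dt)` anchored
  at the line start, calibrated so the first-year gains are 28 / 24 / 21
  cells/µL in lines 1–3 with curvature `b = 0.2`/month (only yearly
  aggregates are reported by the source; the curvature is a package
  default). Non-suppressive therapy declines linearly at 17 cells/µL/year.
  A consequence of the logarithmic form is that multi-year within-line
  gains plateau rather than staying linear.
* Viral load drops instantly to the detectability floor (log₁₀ 49 ≈ 1.69)
  at suppression and stays there; at failure it rebounds to a uniform draw
  whose per-arm bounds (3.604–4.304 and 3.627–4.327 log₁₀ copies/mL) are
  calibrated so the mean rebound-to-baseline log₁₀ ratio is 0.83. The
  unsuppressed drift coefficients default to zero (the fitted values are
  not public); hooks are in `TrajectorySpec`.
* Adherence follows a binomial/logit GLM. Tabulated percentage-point
  marginal effects are converted to logit slopes at the reference adherence
  p̄ = 0.88 via β = Δp/(p̄(1−p̄)); each individual is anchored at their own
  sampled baseline adherence and moves with covariate changes.
* Resistance moves one class at a time (classes R<1, 1≤R<5, 5≤R<10,
  10<R≤25) with a uniform level within the new class; within class 4 the
  level is max(current, triangular(10, 12, 25) draw).
* AIDS classification is permanent once an AIDS event fires or CD4 < 200.

## Baseline cohort and life table

Continuous baseline characteristics are drawn from a piecewise-linear
quantile function through the published quartile anchors (tails extrapolate
the adjacent segment slope, truncated at support bounds); categorical ones
from Bernoulli/table distributions; all fields independently (only
marginals are published; correlation hooks would go in the profile). The
age IQR (33–47) around the published median 39 is a package default. The
non-HIV life table shipped is a **synthetic** Gompertz–Makeham table
(`make_gompertz_makeham_life_table`), a documented stand-in for the
national table the study used; any table can be supplied as CSV-like rows
(age, q_male, q_female). Non-HIV death ages are drawn by sequential annual
mortality probabilities, capped at 105.

## Costs and outcomes

Monthly ART and non-ART outpatient costs come from Gamma/log-link GLMs
whose intercepts are calibrated so the simulated first-line medians equal
the published 613/1057 € (ART) and 63/98 € (non-ART) figures. Unit costs:
line switch 582 €, regimen switch without failure 495 € plus an
intolerance-episode cost of 1126 € (2005 prices, inflated by a
configurable 1.10 factor) for the 54% of switches attributed to toxicity,
AIDS event 4765 €, hospitalization 4742 €. Non-suppressive ART is a
per-individual lognormal daily cost drawn on entry. QALYs weight life
years by a CD4-stratum × suppression utility table; the shipped weights
are package defaults in the range of published HIV utility sets, **not**
taken from the study's cited source. Costs and effects are discounted at
5%/year with discrete annual compounding; continuously accruing quantities
discount at the midpoint of each inter-event interval, one-off costs at
the event time. Ledgers keep discounted and undiscounted tracks, and an
event/interval trace can be replayed through the economics module to audit
the accounting.

## Calibration targets and defaults

Published inputs used directly: the Weibull shapes (1.030 suppression,
1.447/1.873 failure, 1.499 switch, 1.501 first resistance, 1.524 class
switch, 0.733 hospitalization), the covariate marginal-effect table, the
baseline characteristic tables, unit costs and the discount rate.
Anchored medians: regimen switch 80.4 / 32.4 months (the 6.7 y / 2.7 y
Kaplan–Meier medians per arm), first resistance 336 months (28 y), class
switch 84 months (7 y). The mortality-column covariate effects are on an
undocumented scale and ship disabled.

Quantities the source does not print were calibrated once against its
summary outputs, and then frozen:

| default | value | anchor |
|---|---|---|
| suppression median, lines 1–2 | 8.5 mo | 68% line-1 attainment by 12 mo |
| line-2 suppression shift | +4.0 mo | 55% line-2 attainment |
| suppression median, line 3 (unshifted) | 13.5 mo | 46% first-attempt attainment |
| failure median, lines 1–2 | 100 mo | ~9 years mean time in first line |
| failure median, line 3 | 30 mo | package default |
| hospitalization median | 78 mo | ~4.5 lifetime hospitalizations |
| HIV-death medians (shape 1.3) | 800 / 435 mo by AIDS stratum | undiscounted life expectancy ≈ 24.3 y |
| AIDS-event Weibulls by CD4 stratum | 36/90/200 mo, shape 1.2 | placeholder for the cited staging model |

The line-2 suppression shift deserves a note: the published at-mean
marginal (+0.485 months) cannot reproduce the published line-2 attainment
under the additive-median reading, because patients entering line 2 after a
rebound carry *lower* viral loads and the viral-load effect then makes them
suppress faster than line-1 patients. The package follows the outcome
anchor.

Because additive marginal effects are only locally valid, the shifted
median is floored at `max(3 months, 0.25 × baseline median)` (both parts
configurable). Without the relative part, late-stage covariate
combinations (high resistance plus the line-3 shift) pin hospitalization
and class-switch medians at the absolute floor and produce quarterly event
storms that dominate cost and runtime.

The regimen-switch model is arm-specific for the whole lifetime (its
intercept per arm is the printed per-arm Kaplan–Meier anchor). The source
fitted a single line-independent model whose intercept is not public, so
the arms here keep their switch-pace difference in later lines too; the
simulated lifetime cost gap between arms is therefore larger than the
published one, and simulated incremental results should be read as
direction-and-dominance, not as a reproduction of the published totals.

## Probabilistic sensitivity analysis

`run_psa` draws complete parameter sets from `PriorSet` priors (defaults:
lognormal multipliers with 10% log-sd on event-time medians and unit
costs, normal on the GLM intercepts, Beta(54, 46) on the toxicity
probability — the study states only that distributions were derived from
estimated standard errors), simulates both arms with common random numbers
(identical per-individual substreams derived from (seed, index)) and
records one (ΔCost, ΔQALY) pair per set. `proportion_dominant` and `ceac`
summarise the cloud; the CEAC reports P(λ·ΔQALY − ΔCost > 0) on a
willingness-to-pay grid.

## Numerical and reproducibility choices

Every stochastic routine takes a `numpy.random.Generator`; cohorts derive
one substream per individual from (seed, index), making results
order-independent, parallelisable by contract and bit-reproducible for a
given seed. Uniform draws for inverse-CDF sampling are kept strictly
inside (0, 1). Kaplan–Meier estimation uses lifelines. A guard caps the
per-individual event count and the non-HIV death age (105 y) guarantees
termination.

Default problem sizes in the shipped tests are chosen for a single CPU:
10⁵ draws for distributional checks, 10⁵ simulated individuals (50,000 per
arm) plus a 20-set × 2,500-individuals-per-arm PSA for the full-scale run
— a scaled-down analogue of the 10⁶-individual and 133 × 50,000 analyses
the method targets at production scale.

## Known limitations

* Baseline characteristics are sampled independently; real cohorts
  correlate CD4, viral load and adherence.
* A single aggregate resistance score (no drug- or class-specific
  resistance), as in the source model.
* Hospitalization events are cost-only (no marker impact); the AIDS-event
  model standing in for the cited staging model is a placeholder.
* Utility weights and the life table are documented stand-ins; analyses
  aimed at absolute QALY levels should supply their own tables.
* The logarithmic CD4 curve reproduces first-year gains, not multi-year
  linear accrual; long within-line CD4 trajectories plateau.
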