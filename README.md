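# hivdes

Discrete-event microsimulation of lifetime costs and health outcomes for
HIV-1 treatment-naive adults starting antiretroviral therapy (ART) with one
of two strategies: two nucleoside reverse-transcriptase inhibitors plus a
non-nucleoside (2NRTI+NNRTI) or plus a boosted protease inhibitor
(2NRTI+PI/r). The package is written for health economists and modellers who
need patient-level cost-effectiveness estimates — incremental costs, life
years, quality-adjusted life years (QALYs), ICERs, dominance — together
with probabilistic sensitivity analysis and acceptability curves.

## The model

Each simulated individual starts first-line ART with characteristics drawn
from marginal distributions observed in Portuguese cohort data (sex, age,
CD4⁺ count, log₁₀ viral load, pharmacy-refill adherence, hepatitis-C
co-infection, transmission group, AIDS status, baseline drug resistance,
regimen composition). Four forces drive progression: CD4⁺ count, viral
load, resistance (an inverted genotypic sensitivity score in four classes)
and adherence.

Time to each clinical event — viral suppression, virological failure,
regimen switch without failure, resistance development, hospitalization,
AIDS-defining event, HIV death — follows a Weibull distribution

  S(t) = exp(−(t/λ)^p),

parameterised by its shape p and its *median*; tabulated covariate effects
shift the median additively (months per covariate unit). At every decision
point the time of each admissible event is drawn from its **conditional**
distribution given the time already survived,

  t = λ·((t₀/λ)^p − ln u)^{1/p},  u ~ U(0,1),

and the earliest candidate fires. Lines switch after confirmed failure or
when suppression is not reached within 12 months; after the third line, an
individual whose resistance reaches the highest class moves to
non-suppressive therapy until death. Non-HIV mortality is a competing risk
scheduled from a life table. Costs (2009 €, payer perspective) accrue from
ART and outpatient generalized linear models plus unit costs per event;
life years are weighted by CD4×suppression utilities and everything is
discounted at 5%/year.

## Worked example

```python
import hivdes

params = hivdes.default_two_arm_parameters()
nn  = hivdes.simulate_cohort(params["NNRTI"], 2000, seed=7)
pir = hivdes.simulate_cohort(params["PIr"],   2000, seed=7)
inc = hivdes.compare_strategies(nn, pir)
for s in (nn, pir):
    m = s.means
    print(f"{s.arm:6s} cost {m['total_cost']:9.0f} EUR  LY {m['life_years']:.2f}  "
          f"QALY {m['qalys']:.2f}  switches {m['regimen_switches']:.2f}")
print(f"delta cost {inc.delta_cost:+.0f} EUR, delta QALY {inc.delta_qalys:+.3f} "
      f"-> {inc.classification}")
```

prints

```
NNRTI  cost    145182 EUR  LY 12.96  QALY 12.13  switches 1.96
PIr    cost    234112 EUR  LY 12.93  QALY 12.07  switches 5.33
delta cost -88930 EUR, delta QALY +0.066 -> dominant
```

Costs and life years are discounted at 5%; `means` also carries the
undiscounted ledgers, event counts and months per therapy line, with
standard errors in `ses`. The NNRTI strategy costs less over a lifetime —
driven by its lower first-line drug price and its longer time to regimen
switch — at essentially equal effectiveness, hence `dominant`. (With the
shipped default calibration the cost gap is larger than in the source
cohort because later-line ART prices stay arm-specific; see
`docs/methods.md`.)

The same run is available from the shell:

```bash
hivdes simulate --n 2000 --seed 7 --out results/
hivdes psa --n-sets 20 --n-ind 2500 --seed 7 --out results/
hivdes ceac --psa results/psa_pairs.csv --lambda-max 100000 --step 1000 --out results/ceac.csv
hivdes write-config --out my_parameters.yaml   # edit and pass via --config
hivdes km --times event_times.csv              # Kaplan-Meier median check
```

## Layout

- `src/hivdes/params.py` — parameter objects, validation, Weibull median
  calibration, YAML round-trip
- `src/hivdes/cohort.py` — baseline cohort generator (quantile-matched
  draws) and the competing non-HIV death age
- `src/hivdes/survival.py` — conditional Weibull sampling, next-event
  selection, Kaplan–Meier median
- `src/hivdes/progression.py` — marker trajectories, suppression/rebound,
  adherence GLM, resistance ladder, line rules
- `src/hivdes/economics.py` — cost GLMs, unit costs, discounting, QALYs
- `src/hivdes/simulate.py` — the discrete-event loop and cohort summaries
- `src/hivdes/psa.py` — priors, probabilistic sensitivity analysis, CEAC,
  table rendering
- `docs/methods.md` — model description, calibration targets, defaults and
  limitations
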