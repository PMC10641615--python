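# sheia

Diet-quality scoring, dietary greenhouse-gas accounting and all-cause
mortality analysis for FFQ-based cohorts — plus a synthetic-cohort simulator
so the entire analysis chain is testable without access to any restricted
register data.

The package is aimed at nutritional epidemiologists who want to evaluate a
food-based dietary-guideline index — specifically the **Swedish Healthy
Eating Index for Adults 2015 (SHEIA15)** — against two outcomes at once:
mortality hazard and the climate footprint of the reported diet.

## The score

SHEIA15 measures adherence to the 2015 Swedish food-based dietary guidelines
with nine components: six adequacy components (vegetables + fruit, seafood,
whole grains, dietary fibre, MUFA, PUFA) and three moderation components
(SFA, red and processed meat, added sugar).  Each component *c* with
sex-specific recommended intake *r_c* contributes

* adequacy:&nbsp;&nbsp; `s_c = min(1, max(0, x_c / r_c))`
* moderation: `s_c = min(1, max(0, 2 − x_c / r_c))`

and the total `S = Σ s_c ∈ [0, 9]`.  Moderation components earn full credit
at or below the cut-off, nothing at twice the cut-off, linear in between.
Scores are computed on the **energy-adjusted** profile — every gram-based
intake is rescaled so total energy equals 2000 kcal/day (women) or
2500 kcal/day (men) — so the index reflects diet quality, not quantity, and
is invariant to uniform under-reporting of intake.

Dietary greenhouse-gas emissions (GHGE) are the intake-weighted sum of
per-food emission factors (kg CO₂e per kg edible food, farm to industry
gate), energy-adjusted with the same scale factor.

## The analysis chain

`simulate/load → exclusion filters → energy-adjusted metrics → SHEIA15 →
quintiles (within sex × age group) → Cox mortality models → rank tests on
GHGE → leave-one-component-out sensitivity`

* **Filters** — six exclusion criteria (incomplete FFQ, implausible
  height/weight/BMI, age outside 35–65, food intake level outside the
  1st–99th percentiles) with a full audit log, plus one observation per
  subject (earliest visit).
* **Survival** — a self-contained Newton–Raphson Cox partial-likelihood
  maximiser (Breslow ties by default, Efron available), purposeful
  (Bursac-style) covariate selection with the 20 % change-in-estimate
  confounding rule, and a Grambsch–Therneau proportional-hazards diagnostic.
* **Rank tests** — tie-corrected Kruskal–Wallis, Dunn post hoc with
  Bonferroni, Jonckheere–Terpstra trend and Mann–Whitney U, each with a
  permutation null as an internal oracle.
* **Simulator** — log-normal food-group intakes with a Gaussian copula,
  energy derived through a composition table, ~45 % energy under-reporters
  (food intake level < 1.2), and exponential/Weibull event times whose
  log-hazard is linear in the true diet-quality score, administratively
  censored at the end of 2016.

## Worked example

```python
from sheia import SimulationConfig
from sheia.pipeline import RunConfig, run_pipeline

cfg = RunConfig(out_dir="run1", seed=1,
                simulation=SimulationConfig(n_subjects=10_000, beta_score=-0.10))
out = run_pipeline(cfg)   # writes delimited-text tables + manifest.json
```

`table_quintile_hr.csv` then holds, for each sex, the hazard ratio of each
score quintile against quintile 1 (basic and fully adjusted models).  The
simulation above generates a protective diet effect of −0.10 log-hazard per
score unit; the women's adjusted model reads:

```
   sex    model  quintile    hr  ci_low  ci_high     p   n  events
female adjusted         1 1.000     NaN      NaN   NaN 989      77
female adjusted         2 0.747   0.532    1.049 0.093 988      59
female adjusted         3 0.664   0.470    0.938 0.020 987      56
female adjusted         4 0.701   0.495    0.994 0.046 986      54
female adjusted         5 0.734   0.519    1.038 0.080 986      55
```

i.e. every higher quintile has a lower mortality hazard than quintile 1,
with CI widths reflecting the ~270 events in this draw.
`table_ghge_medians.csv` shows the monotone climate gradient across the same
quintiles (medians 5.22 → 3.37 kg CO₂e per 2000 kcal and day for women),
which the Kruskal–Wallis and Jonckheere–Terpstra tests in
`table_ghge_tests.csv` confirm (p ≈ 0 at this sample size).  The
leave-one-out tables show the GHGE contrast collapsing toward zero when the
red/processed-meat component is excluded — the emissions signal is carried
almost entirely by that component.

A command-line interface mirrors the stages (`sheia simulate`, `filter`,
`metrics`, `score`, `survival`, `tests`, `run`); see `sheia --help`.

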