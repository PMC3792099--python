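# msmtx

Multi-state survival analysis for comparing a transplant strategy with a
non-transplant strategy when the two arms come from **separate
registries** — and a simulation engine that demonstrates why naive
comparisons of such data are biased.

## The problem

Whether (and when) patients with advanced myelodysplastic syndromes should
receive an allogeneic stem-cell transplant is usually asked of
observational data: a transplant registry that enrols patients *at
transplant*, and a registry of patients managed with best supportive care.
Three structural problems make a naive Kaplan-Meier or Cox comparison
wrong:

1. **Left truncation** — transplant-registry patients were guaranteed to
   be alive until transplant; counting the waiting time as observed
   survival is immortal-time bias.
2. **Right truncation** — a transplant is recorded only if it happened
   before the registry window closed, over-representing short waits.
3. **Invisible deaths while waiting** — transplant candidates who die
   first appear in *neither* registry.

`msmtx` implements the multi-state answer.  The disease course is an
irreversible illness-death model (Diagnosis → Transplant → Death, plus
Diagnosis → Death) on the time-since-diagnosis scale.  Three estimable
ingredients — the right-truncated waiting-time distribution
F̂(t | T ≤ τ) = ∏_{u>t} (1 − d(u)/Y(u)), the Diagnosis→Death hazard from
the non-transplant registry, and the Transplant→Death hazard with delayed
entry — are combined by the Aalen-Johansen product integral
P(s, t] = ∏ (I + dÂ(u)) into the from-diagnosis survival curve of the
transplant strategy, 1 − P̂₁₃(0, t).  The key *equal-mortality (Markov)
assumption* — transplant-intent patients die pre-transplant at the
non-transplant registry's rate — is untestable, and the package treats it
as a first-class object: the simulator can enforce it or break it, and the
bias study quantifies what happens in either case.

On top of this sit a counting-process Cox model (Breslow ties, delayed
entry) for the pooled "average hazard ratio", piecewise and
kernel-smoothed time-varying treatment effects, and a scaled-Schoenfeld
proportional-hazards test — because when early treatment-related mortality
makes the hazard ratio time-varying, any single average HR is misleading.

## Worked example

Simulate registries with an early post-transplant mortality spike
(treatment-related mortality during the first quarter year), then analyse
them:

```python
import msmtx as mx
from msmtx.cox import (fit_treatment_comparison, fit_time_varying_effect,
                       test_proportional_hazards)
from msmtx.stepfun import DAYS_PER_YEAR

params = mx.make_scenario_presets(n=2000, seed=1)["s1-trm"]
cohort = mx.simulate_cohort(params)
tx, non_tx = mx.apply_registry_sampling(cohort)

data = mx.assemble_multistate_dataset(non_tx, tx)
curves = mx.reconstruct_strategy_survival(data)
fit = fit_treatment_comparison(non_tx, tx)
ph = test_proportional_hazards(fit)
tve = fit_time_varying_effect(data.comparison_rows)
```

Printing the registry sizes, the strategy curves at 1/2/5 years, the Cox
summary, the test result and `tve.coef_table` gives:

```
registries: 671 transplant, 1010 non-transplant
median survival (years): transplant strategy 1.41, non-transplant 1.50
  S(1 y): transplant 0.596, non-transplant 0.621
  S(2 y): transplant 0.399, non-transplant 0.385
  S(5 y): transplant 0.107, non-transplant 0.086
average HR (transplant vs none): 0.99 (95% CI 0.88-1.10; p = 0.799)
PH test: chi2 = 22.2, p = 0.0000
  interval   hr  hr_lo  hr_hi
   (0, 91] 5.28   3.78   7.39
 (91, 365] 0.93   0.74   1.17
(365, inf] 0.82   0.72   0.95
```

Read bottom-up: transplant quintuples the death hazard during the first
three months (treatment-related mortality), is neutral to beneficial
afterwards, and the two strategies' survival curves cross — yet the
*average* hazard ratio is an unremarkable 0.99 (p = 0.80).  Without the
proportional-hazards test (p < 0.0001) and the interval-specific estimates,
the average would hide everything that matters clinically.

The same pipeline runs from the shell:

```bash
msmtx simulate --preset s1-trm --n 2000 --seed 1 --out-dir out/sim
msmtx sample-registries --cohort out/sim/complete_cohort.csv \
      --truth out/sim/truth.csv --scenario out/sim/scenario.yaml \
      --out-dir out/sim
msmtx fit --non-tx out/sim/non_tx_registry.csv \
      --tx out/sim/tx_registry.csv --out-dir out/fit
msmtx figures --fit-dir out/fit --plot
msmtx bias-study --preset s1-markov --preset frailty-selection \
      --n-reps 100 --seed 0 --out-dir out/bias
```

## Scenario presets

| preset | meaning |
|---|---|
| `s1-markov` | constant hazards, equal-mortality assumption holds, transplant neutral |
| `s1-trm` | early post-transplant mortality spike (first 0.25 y) |
| `frailty-selection` | shared frailty routes high-risk patients to transplant — the assumption fails |
| `tv-effect` | true transplant-vs-none HR is 5.8 in the first 3 months and 1.0 after a year |

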