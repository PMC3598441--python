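# wccox — weighted Cox models for case-control studies with exposure histories

Population-based case-control studies of occupational and environmental
exposures usually collect a subject's whole exposure history, then throw the
dynamics away: standard logistic regression freezes every covariate at the
index age (diagnosis for cases, interview for controls). The **weighted Cox
(WC) model** instead analyses the case-control sample as a survey sample of
the source population, with age as the time axis, time-dependent covariates
`x(t)`, and time-dependent sampling weights. `wccox` implements the WC model,
its variance estimators, and a full simulation bench for comparing it with
conditional (CLR) and unconditional (ULR) logistic regression.

## The model

The estimate solves the weighted partial-likelihood score equation

```
U(β) = Σᵢ ωᵢ(tᵢ) δᵢ [ xᵢ(tᵢ) − S¹(tᵢ,β)/S⁰(tᵢ,β) ] = 0 ,
S⁰(t,β) = Σⱼ ωⱼ(t) Yⱼ(t) exp(xⱼ(t)'β) ,
```

with weights

```
ωᵢ(t) = 1                                          (cases)
ωᵢ(t) = (1−π(t))/π(t) · n_cases(t)/n_controls(t)   (controls)
```

where `π(t)` is the probability of developing the disease at age `t` or
later in the source population (estimated from the enumerated cohort, or
from published age-band incidence rates), and `n_cases(t)`/`n_controls(t)`
count study members with index age ≥ t. Three variance estimators:

* **naive** `I⁻¹(β̂)` (inverse observed information),
* **robust** `V₁ = D'D`, the Binder sandwich via weighted dfbetas
  (accounts for drawing the sample from the source population) — "WC1",
* **superpopulation** `V₂ = V₁ + I⁻¹` (Lin; adds the variability of the
  source population itself being a sample) — "WC2".

WC1 and WC2 share point estimates and differ only in standard errors; the
robust variance systematically understates the true variability when the
event rate in the source population is non-negligible, and the
superpopulation variance repairs the resulting under-coverage.

## Worked example

```python
import numpy as np
from wccox import (SimulationConfig, generate_population, sample_case_control,
                   CohortPiFunction, study_cox_arrays, fit_weighted_cox)
from wccox.evaluation import replication_rng

cfg = SimulationConfig(population_size=1000, scenario="A", model=1,
                       ratio=1, target_event_rate=0.10, master_seed=7)
rng = replication_rng(7, 0)
pop = generate_population(cfg, rng)                  # ~100 cases out of 1000
study = sample_case_control(pop, cfg.ratio, rng)     # 1:1 risk-set sampling
pi = CohortPiFunction(pop.exit_age, pop.event)       # π(t) from the cohort
fit = fit_weighted_cox(study_cox_arrays(study, pop, pi, cfg.model))
print(fit.summary())
```

```
weighted Cox fit: 2 covariates, 7 iterations, converged
log pseudo-likelihood -409.3579
covariate                       beta  se(naive) se(robust) se(superpop)
intensity                     1.5367     0.1275     0.1458       0.1937
duration                      0.0163     0.0148     0.0218       0.0264
```

This study drew 90 cases. The generating effects were β = 1.39 (intensity,
per fiber/ml) and β = 0.05 (duration, per year); the intensity estimate
1.54 ± 1.96·0.19 covers the truth comfortably, and the duration estimate
0.016 ± 1.96·0.026 does too — one study of ~180 units carries limited
information about a weak per-year effect. The WC2 interval uses
`se(superpop)`, the wider and better-calibrated of the two.

The same machinery is scriptable from the shell:

```
wccox simulate config.yaml --out-dir out/      # population + study CSVs
wccox pi incidence.csv -o pi.csv               # rates → π(t)
wccox weights out/study.csv --cohort out/population.csv -o out/w.csv
wccox fit out/population.csv -o fit.json
wccox experiment config.yaml --replications 250 --out-dir out/
```

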