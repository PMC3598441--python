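# Methods

## The weighted Cox model for case-control data

A population-based (or nested) case-control study is treated as a survey
sample of the source population. With age `t` as the time axis, the hazard
model is λ(t|x(t)) = λ₀(t)·exp(x(t)'β) and β is estimated from the
pseudo-maximum-likelihood score

U(β) = Σᵢ ωᵢ(tᵢ) δᵢ [xᵢ(tᵢ) − S¹(tᵢ,β)/S⁰(tᵢ,β)],
S⁰(t,β) = Σⱼ ωⱼ(t) Yⱼ(t) exp(xⱼ(t)'β),

where δᵢ flags the case whose diagnosis defines event age tᵢ and
Yⱼ(t) = 1 while a sampled unit is at risk (entry < t ≤ exit; entry defaults
to birth, and left truncation is supported by supplying entry ages).

**Weights.** All eligible cases are assumed sampled, so cases carry
ω ≡ 1 up to diagnosis. A control selected at age a carries, for t ≤ a,

ω(t) = (1 − π(t))/π(t) · n_cases(t)/n_controls(t),

where π(t) is the probability that a member of the source population
develops the disease at age t or later given at risk at t, and the counts
are the numbers of study cases/controls with index age ≥ t. Both
comparisons are **inclusive** at t: that convention makes every control's
weight well defined up to its own selection age (the control itself is
still counted) and fixes the value used when a risk set is evaluated at an
event age. Weights are right-continuous step functions with breakpoints at
every distinct index age and every π breakpoint; when an evaluation age
exceeds the last π breakpoint the last band's value is carried forward.

**π(t).** Two estimators are provided. From an enumerated cohort:
π(t) = #(events with exit ≥ t among at risk at t) / #(at risk at t),
computed exactly by suffix counts over the sorted exit ages (delayed entry
subtracts the not-yet-entered). From an age-band incidence table (rates per
100,000 person-years): π on band k is the tail sum Σ_{j≥k} rate_j/10⁵,
constant within bands and non-increasing in age. The tail-sum form is the
arithmetic that reproduces published age-conditional probability tables for
pleural mesothelioma to their printed precision, and is verified as such in
the tests. Trailing all-zero bands are dropped so π stays positive wherever
weights are evaluated; weights with π = 0 are refused.

**Fitting.** Newton–Raphson on the weighted log pseudo-likelihood with
step-halving (up to 10 halvings), convergence at max|U| < 1e-9 or relative
coefficient change < 1e-10, at most 25 iterations. Tied event ages use the
Breslow convention (simulated ages are continuous, so ties among events are
measure-zero; controls share index ages with their case, which the
inclusive risk-set rule handles). Per-age centring of the linear predictor
guards exp overflow. Monotone likelihoods are detected either by the
estimate passing a bound (‖β̂‖∞ > 50) with a non-vanishing score or by
iteration exhaustion, and raise instead of returning a silently bad fit.

## Variance estimators

* **naive**: I⁻¹(β̂), the inverse observed information of the weighted
  score.
* **robust (WC1)**: the Binder sandwich I⁻¹ [Σ_c g_c g_c'] I⁻¹ where g_c is
  the cluster sum of weighted score residuals; computed as D'D with
  dfbetas D = G·I⁻¹. Sampled units originating from the same source subject
  (controls are drawn with replacement) share a cluster. With
  time-dependent weights, the unit's own weight is applied at each
  evaluation age ωᵢ(t_k); this is the convention under which
  Σᵢ ωᵢûᵢ = U(β̂) holds exactly and D'D agrees with the standard
  weighted-dfbetas computation of survival software. A literal first-power
  reading of the sandwich middle term is available behind
  `robust_variance(..., omega_power=1)`; the dfbetas identity
  (`omega_power=2`) is the default.
* **superpopulation (WC2)**: V₂ = V₁ + I⁻¹, the Lin estimator, adding the
  naive term for the variability of the finite source population around the
  infinite superpopulation. Exact matrix sum, so V₂ − V₁ = I⁻¹ by
  construction and the WC2 interval is always at least as wide as WC1's.

A useful identity checked in the tests: multiplying all weights by a
positive constant leaves both β̂ and V₁ unchanged (the dfbetas are
scale-free), while the naive — and hence superpopulation — variance scales
by 1/c.

## Logistic comparators

CLR maximises the one-case-per-set conditional likelihood
exp(x_case'β)/Σ_set exp(x_j'β) by Newton–Raphson (own implementation,
cross-checked against an independent conditional-logit routine); sets
without covariate discordance drop out, and one-signed discordance
(separation) raises. ULR is an ordinary logistic MLE with intercept, the
exposure covariates, and index age entering linearly on the logit — the
linearity is a deliberate reproduction of common practice, including its
misspecification. Both freeze the time-dependent covariates at the index
age.

## The synthetic-data generator

The generator emulates a male population occupationally exposed to an
asbestos-like agent.

* **Exposure windows**: age at first exposure ~ lognormal(mean 21 y,
  sd 8 y); duration ~ lognormal(mean 27 y, sd 14 y); age at last exposure
  is their sum. Means follow the descriptive statistics of published
  asbestos case-control data; sds follow the declared per-SD effect units
  (8 y, 14 y).
* **Intensity trajectories**: clamped-linear in age,
  max(0, c + s·(t − t_first)), with latent classes
  constant (s = 0), highly increasing (s = +0.15 fibers/ml/y), moderately
  increasing (+0.05) and moderately decreasing (−0.05). Scenario A mixes
  them 85/6/3/6 % (the mix seen in real asbestos histories); scenario B is
  50/50 highly-increasing/moderately-decreasing. Intercepts are lognormal
  per class (constant: mean 0.4, sd 1.1; increasing: mean 0.2, sd 0.3–0.4;
  decreasing: mean 1.5, sd 0.8 so a falling profile has room above zero);
  the constant-class spread is set so the intensity covariate's scale is
  near its declared 1.0 fiber/ml unit.
* **Covariates**: the intensity covariate at age t is the cumulated
  intensity divided by duration (the mean index of exposure); duration and
  time-since-cessation accrue as usual; all integrals are closed-form on
  the clamped-linear profile (the zero crossing of a decreasing profile is
  an explicit node), so there is no quadrature error. After cessation the
  intensity covariate is frozen at its final value — both numerator and
  denominator stop changing, the behaviour implied by the cumulative/MIE
  definition.
* **Event times** come from the permutational algorithm: draw n marginal
  (age, status) pairs — event ages Weibull(shape 5, scale 72 y; median
  ≈ 67 y, concentrating events in late working life) against independent
  Uniform(0, b) censoring, keep the minimum and its status — then sweep the
  ages in ascending order, assigning each event age to a still-unassigned
  subject with probability ∝ exp(x(t)'β) (the same covariate derivation
  used at analysis time, so the analysis model is correctly specified) and
  each censoring age uniformly. The assigned-age multiset equals the drawn
  one exactly, and at β = 0 assignment is an exchangeable permutation.
* **Censoring calibration**: under this construction the expected event
  fraction is P(T ≤ C), independent of β and the trajectories, with closed
  form via the lower incomplete gamma function; the bound b solves it for
  the target rate (10% for populations of 1000, 2% for 5000) by Brent
  root-finding. The fraction is increasing in b: a larger bound censors
  later and lets more events through.
* **Sampling**: every event becomes a case; m ∈ {1,2,4} controls per case
  are drawn with replacement from subjects at risk at the case's age
  (excluding the case), giving 1:m individual matching on age. If the
  oldest event has no subject left at risk the replication raises a
  sampling error; the experiment runner records and skips such
  replications (1–3% at the default settings) rather than failing.
* **Reproducibility**: every replication's generator is seeded by
  SeedSequence((master_seed, replication_index)), so any single replication
  can be regenerated in isolation.

What the generator does **not** emulate: frequency matching (birth-year
strata), case under-ascertainment, covariate measurement error, competing
risks, and real job-exposure-matrix structure. Passing tests therefore
speak to the estimators' behaviour under a clean incidence-density design
with correctly specified exposure models, not to robustness against those
complications.

## The replication bench

Per replication: generate a population; fit the full-cohort time-dependent
Cox model (the efficiency oracle; a streaming implementation that never
materialises the events × subjects covariate array, so cohorts of 20,000
fit comfortably); sample the study; estimate π from that replication's own
source population; build weights; fit WC, CLR and ULR. Criteria per method
and covariate: relative bias vs the true β and vs the full-cohort Cox
estimate, empirical relative efficiency var(β̂_Cox)/var(β̂), RMSE
√(bias² + var), ASE/SDE, and 95% coverage using each method's own standard
error (WC1 robust, WC2 superpopulation, CLR/ULR/Cox naive). Empirical
variances use the unbiased (n−1) convention. Non-converged fits are
excluded per method and counted in `n_converged`; a zero true β switches
the relative bias to absolute with a flag.

Problem sizes: the packaged benchmark uses 600 replications for the
coverage comparison and 300 per arm for the efficiency contrast —
scaled-down but comfortably past where the Monte-Carlo error (≈1 coverage
point, ≈0.03 on an efficiency ratio) stops mattering for the qualitative
conclusions.

## Known limitations

* The exact nuisance parameters of the published benchmark (lognormal,
  Weibull, slope and intercept values) are not public; the packaged
  defaults are back-fitted to the published descriptive statistics and
  declared per-SD units. Coverage of the superpopulation interval
  (≈97.6% here vs 97.5% published) and the robust interval (≈91% vs 89.1%)
  and the efficiency orderings reproduce closely; the absolute
  relative-efficiency level of the weighted Cox estimator in the
  5000-subject, 2%-event arm is the most parameter- and seed-sensitive
  quantity (≈0.22–0.34 across seeds here vs 0.20 published) because it
  depends on the tail of the intensity distribution through the extreme
  control weights.
* Weight uncertainty is ignored (π is plugged in as known), as is any
  adjustment for case sampling fractions below 1 — the weight function is
  the natural hook for both.
* Efron tie handling, stratified baselines, and Schoenfeld-residual
  variance estimators are out of scope.
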