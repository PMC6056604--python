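# Methods

## Catchment construction

Admission rows sharing an episode key (within a person) are one episode of
care: transfers and care-type changes do not create new admissions. A merged
episode is attributed to its **first** hospital in row order — the admission
decision is made at the first facility — with `attribute="last"` available
for sensitivity analysis.

For each residence area, the flow profile is the proportional distribution
of the area's all-cause episodes over hospitals: `w(h) = episodes to h /
total episodes from the area`. Episode counts (not distinct-person counts)
are used. Areas with no admissions carry no profile; their residents are
excluded from modelling and written to an explicit exclusions report rather
than dropped silently. No minimum-admission threshold is applied: an area
with a single admission gets a degenerate profile, matching how such
structures behave in sparse rural data.

Discrete HSAs assign each area to its maximum-weight hospital. Ties are
broken by lexicographically smallest hospital id, so the partition is a pure
function of the profiles and invariant to row order. Hospitals that are
nowhere the plurality choice keep an *empty* HSA — they remain visible in the
weighted network but have market share index 0.

Weighted hospital covariates are person-level weighted averages
`Σ_j w_ij x_j`; when requested they are centred on the group mean and divided
by 10 so a one-unit change is a 10-point change (e.g. percent bed occupancy).

## Model and priors

The outcome model is a log-linear Poisson rate model with a log follow-up
offset and one or more random classifications, each entering as
`Σ_j w_ij^(c) u_j^(c)` with `u_j^(c) ~ N(0, σ²_c)` and weight rows summing
to 1. There is no person-level Gaussian residual: counts are the lowest
level, and no overdispersion term is included (a stated limitation — true
overdispersion will inflate variance estimates and narrow intervals).

Priors (configurable): `β ~ N(0, 10^6)` iid; `σ² ~ Inverse-Gamma(0.001,
0.001)`. These are the customary defaults of MCMC multilevel software for
this model class. The inverse-gamma prior is near-improper: with very weak
data it concentrates near zero, so variance estimates from tiny systems
should be read with its influence in mind.

## Sampler

Metropolis-within-Gibbs, mirroring the standard MCMC engine for Poisson
multilevel models:

- each fixed effect and each random effect is updated by scalar random-walk
  Metropolis (the Poisson likelihood is non-conjugate);
- each σ²_c is drawn exactly from its conditional
  `Inverse-Gamma(a + J_c/2, b + Σ_j u_j²/2)`;
- proposal scales adapt every 50 iterations during burn-in toward ~44%
  acceptance (multiplicative steps shrinking as batches accumulate) and are
  frozen at the end of burn-in, so the post-burn-in chain is a valid
  fixed-kernel MCMC;
- the linear predictor, its exponential and the log-likelihood are
  maintained incrementally; a unit's update touches only persons with
  nonzero weight on that unit (CSC layout), so cost scales with the weight
  matrix's nonzeros, not n × J. The stored deviance is −2× the exact Poisson
  log-likelihood at the stored state (tests recompute it from the state).
- a post-burn-in acceptance rate outside [0.1, 0.8] for any block produces a
  warning in the result's diagnostics, never a failure.

Default settings are 5,000 burn-in / 20,000 stored samples / thin 1;
desk-scale tests use 1,000 / 4,000, which suffices for the variance and
fixed-effect summaries asserted there. The kernel is numba-compiled; chains
are deterministic given the seed. Exchangeability over person order holds up
to floating-point summation order: permuting persons leaves all posterior
summaries within Monte-Carlo error but is not bitwise identical (per-person
RNG substreams were considered and rejected as needless complexity for a
sampler whose proposals are per-parameter, not per-person).

A classification may have its variance pinned (`fixed_variance=0`), which
zeroes its effects and reduces a cross-classified model to the smaller one —
used by the reduction tests.

DIC uses the plug-in at the posterior means of (β, u) — the parameter-level
convention — so `pD = D̄ − D(β̄, ū)` and `DIC = D̄ + pD`.

## MRR, PCV, rankings

`MRR = exp(√(2σ²)·Φ⁻¹(0.75))`, with Φ⁻¹(0.75) evaluated numerically
(≈ 0.6745; the combined coefficient √2·Φ⁻¹(0.75) ≈ 0.954). The point MRR is
computed from the posterior mean of σ² — this pairing reproduces the
conventional reporting of a variance estimate alongside its MRR — while the
credible interval transforms the σ² chain draw by draw (order-preserving,
as the map is monotone). PCV is `(v_before − v_after)/v_before` and may be
negative. Hospital rankings are posterior medians of `u_j` with 95% credible
intervals; a hospital is flagged when its interval excludes 0, with no
multiplicity adjustment. Ranking comparisons report Spearman correlation
over shared hospitals and list hospitals present only in the
multiple-membership fit (those with empty HSAs).

## Synthetic worlds

`generate_system` emulates the statistical structure of a large linked
admission cohort at desk scale:

- **Geometry and flows.** Areas and hospitals uniform on the unit square;
  hospital sizes lognormal(0, 1); flow probabilities
  `p_aj ∝ size_j · exp(−d_aj / φ)`. The decay φ = 0.05 was calibrated once so
  the mean top-hospital loyalty is ≈ 68% (second ≈ 18%), matching the
  60–75% loyalty spectrum of empirical postal-area flows, and then frozen.
  φ → 0 degenerates every area onto one hospital (the nested-model limit).
- **Scale.** 60 areas, 15 hospitals, ~6,000 persons (mean 100/area,
  gamma-Poisson with shape 1.2 for realistic skew) — roughly a 1/45 scale
  model of ~600 areas / 79 hospitals / 267k persons, so a full closed loop
  runs in seconds.
- **Persons.** Follow-up uniform on [2.0, 5.4] years (mean 3.7); covariates
  age (decade units, centred), sex, and a standard-normal health score with
  coefficients (0.35, −0.10, 0.50) — a small stand-in for a survey's
  predisposing/need factors, with effect sizes typical of self-rated health
  gradients in preventable admission.
- **Outcomes.** Non-preventable admissions at 0.27/person-year and
  preventable ones at `exp(β0 + x'β + Σ_j p_aj u_j)` with β0 = log 0.027/yr
  (≈ 0.1 events/person over follow-up, ~6% of persons affected) and
  `u_j ~ N(0, 0.13)`. Hospitals of admission are multinomial draws from the
  area's true flows; the admissions table is the union of both processes, so
  person-level preventable counts equal their flagged admissions. An
  optional second geography (SLA-like regions with their own variance)
  supports cross-classified models.

What the generator does **not** emulate: real geography and contiguity,
private/secondary hospital sectors, overdispersion or zero inflation beyond
the mixed-Poisson structure, survey content, and mortality/censoring beyond
the follow-up draw. A green closed-loop test therefore establishes that the
estimator recovers its own generating mechanism at the stated scale — not
that a particular empirical variance estimate is correct.

### Null-test intensity

The null closed loop (σ²_u = 0 → fitted σ² concentrates near 0) is run at
~2,000 persons with the outcome at the *all-cause* intensity
(β0 = log 0.27/yr, ~1.3 events/person). At the rare preventable intensity,
2,000 persons yield only ~13 events per hospital, giving per-hospital noise
of sd ≈ 0.28 on the log scale — σ² below 0.05 is then statistically
unidentifiable regardless of sampler quality, and measured upper bounds sit
at 0.17–0.43. With ~130 events per hospital the upper 95% bound is 0.01–0.03
across seeds. The default generator is unchanged; only the null oracle uses
the informative intensity.

## Numerical notes and limitations

- Weight-row sums are validated to 1e-6 on input and produced to 1e-9 by
  construction; flow profiles reject non-positive weights.
- The intercept chain is initialised at `log(Σy / Σt)`; other parameters at
  0; σ² at 0.1. Burn-in absorbs initialisation at the tested scales.
- With few hospitals (J ≈ 15) the σ² posterior is wide and right-skewed;
  single-replicate point estimates scatter around the truth, and recovery
  claims are made over ≥ 20 replicates.
- Deviance is −2× the exact Poisson log-likelihood (including the log Y!
  term), so DIC values are comparable across models on the same data only.
- The sampler updates parameters one scalar at a time; heavily correlated
  fixed effects would mix slowly (no blocking is implemented).
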