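# Methods

## Model

crashmix estimates an unordered three-alternative injury-severity model
(severe SI, minor MIN, no injury NI — the standard collapse of the KABCO
police scale with K+A → SI, B+C → MIN, O → NI).  Conditional on
coefficients, choice probabilities are multinomial logit: each
alternative's severity function is a linear index plus an i.i.d. extreme
value type I error, and the probability of the observed outcome is the
softmax of the three indices.  Every covariate is an indicator attached to
exactly one alternative's utility ("defined for" that severity class);
the reference alternative carries no constant unless explicitly
overridden.  The published crash models this package is shaped around
place their single constant on the no-injury baseline, which is a valid
but restrictive normalisation (it forces the SI and MIN constants to
zero); the spec object permits it behind an explicit
`allow_reference_constant` flag so the restriction is always a visible
choice.

Selected coefficients are random across crashes with heterogeneity in
both moments:

    β_n = β + δ′z_n + σ · exp(ω′w_n) · v_n

The mean shifts linearly in the z-attributes, the standard deviation
scales multiplicatively in the w-attributes (the exponential keeps it
positive for any ω), and v is a standard disturbance.  The normal mixing
density is the default; lognormal, uniform and triangular are available,
all driven through the same underlying standard-normal Halton stream via
probability transforms, so switching distributions never changes the draw
machinery.  Unconditional probabilities integrate over the mixing
density; the simulated log-likelihood replaces the integral with the
average over R draws and sums the log of the averaged chosen-alternative
probability.

## Simulated maximum likelihood

**Draws.**  Halton sequences, one prime base per random dimension in
order (2, 3, 5, …), the first 10 points discarded (the leading points of
a radical-inverse sequence cluster near 0 and map to extreme normal
quantiles), each observation receiving its own contiguous
non-overlapping block of R points per dimension.  The cube is a pure
function of (bases, discard, shape) — bitwise reproducible, nothing
hidden.  Plain (unscrambled) Halton is the default because the models
here use 1–3 random coefficients, well below the dimensionality where
Halton correlation artifacts appear; digitally scrambled draws are
available behind a flag (delegated to scipy's QMC engine) and require a
seed.  The default draw count for production fits is 1000; the validation
studies in this repository use 100–200 draws, which the QMC convergence
test (log-likelihood deltas shrinking through 125/250/500/1000 draws)
shows is already in the converged regime for these model sizes.

**Optimisation.**  L-BFGS-B on the negative simulated log-likelihood
with an analytic gradient (the score of the simulated probability,
derived per parameter through the coefficient transform); central finite
differences over the same fixed cube are retained as a cross-checked
fallback.  All parameters are boxed at ±50 — a bound that never binds
for plausible indicator-variable coefficients (it corresponds to odds
factors of e^50) but stops quasi-Newton steps running off along weakly
identified ridges where simulation noise makes the likelihood flat; an
estimate at the bound is flagged as non-converged.  The likelihood and
score are evaluated in observation blocks of 2048 to bound memory.  σ is
stored unconstrained and enters as |σ|, avoiding boundary failure when a
random term is spurious; reports show the positive scale.  Convergence
stops on relative likelihood change (ftol 1e-11) or projected-gradient
max-norm (gtol 1e-5), max 500 iterations; non-convergence is flagged on
the result, never raised.

**Starting values.**  With random terms present, the plain-MNL analogue
(every term fixed) is fitted first — its likelihood is globally concave,
so this stage is safe from any start — and the mixed model starts from
those coefficients with σ = 0.5.  Cold starts near σ = 0 sit in a flat
region of the simulated likelihood and were observed to wander; the
two-stage start is the standard remedy in mixed-logit practice.

**Inference.**  Standard errors come from the inverse of a centrally
differenced Hessian of the analytic gradient at the optimum; when that
matrix is not usable the BHHH outer product of per-observation scores is
tried; when neither inverts, standard errors are reported as NaN rather
than fabricated.  Significance is flagged at the 90% two-tailed level, as
a report column — no automatic stepwise removal.

**Null log-likelihood.**  Two conventions are implemented and the report
names which was used.  `equal_shares` (−N ln 3, all parameters zero) is
the default because the published tables this package mirrors print
exactly −N ln 3; `constants_only` (N Σ s_k ln s_k at empirical shares) is
the other common convention, with 0·ln 0 taken as 0.

## Post-estimation

Marginal effects for indicator covariates are average discrete changes:
probabilities with the indicator forced to 1 minus probabilities at 0,
averaged over the estimation sample (not evaluated at covariate means).
Random coefficients enter at their estimated means; by default the mean
includes the per-observation δ′z shift (the overall-mean-only variant is
available and logged when chosen), and the simulation noise term is
always dropped.  A covariate that also serves as a mean or variance
shifter is flipped in every role, keeping the counterfactual coherent.
Each row sums to zero across the three alternatives by construction;
reports round to 4 decimals, raw values are retained.

Sign shares of a normal random coefficient are Φ(mean/sd) positive,
Φ(−mean/sd) negative, reported in percent.

The transferability test compares one pooled model against separately
estimated group models: LR = −2[LL(pooled) − Σ LL(group)] against the χ²
quantile with df = (parameters across group models) − (pooled
parameters).  A slightly negative statistic can occur under simulation
noise and is reported as-is with a warning rather than clamped.

## Synthetic data generator

The generator produces exactly what the model assumes: independent
Bernoulli indicator covariates (optionally one-hot blocks for mutually
exclusive categories), coefficients realized per observation through the
heterogeneity structure, utilities plus independent standard Gumbel
errors via the inverse CDF −ln(−ln u) on a seeded uniform stream, outcome
by argmax.  Generation is a deterministic function of (truth, design,
seed), and every dataset carries its truth and realized coefficients for
recovery tests.

The preset scenario mirrors the scale of a statewide five-year large-truck
extract: n ≈ 7000; one normally distributed random coefficient (a rural
indicator in the severe-injury utility, mean −1.0, sd 2.2) with one mean
shifter (interstate, δ = −0.6) and one variance shifter (tree collision,
ω = 0.6); fixed indicators for rollover (SI), fatigue (MIN), rear-end
(NI); a no-injury constant of 2.0.  Prevalences (rural 0.45, interstate
0.22, tree collision 0.02, rollover 0.14, fatigue 0.02, rear-end 0.19)
are the empirical frequencies of the corresponding indicators in the
in-state descriptive table the scenario emulates.

What the generator does **not** emulate: correlations between indicators
(real contributing factors, road class and locale are strongly
associated), underreporting of minor crashes, within-category
exclusivity unless the one-hot mode is used, and any spatial or temporal
structure.  Tests passing on this generator therefore establish that the
estimator recovers the model it assumes — not that the model is correct
for any particular crash database.

## Validation studies and problem sizes

- **σ = 0 equivalence**: with the random sd at zero the simulated
  likelihood equals a closed-form MNL oracle to 1e−8 on small instances;
  the fixed-only fit is also cross-checked against an independent MNL
  implementation (statsmodels) in the full parameterisation where the two
  parameter spaces coincide.
- **Recovery study**: the preset scenario at n ∈ {1000, 2500, 5000},
  20 replications, 100 Halton draws; RMSE of the random coefficient's
  mean and sd against truth decreases in n.  The study uses a
  nested-sample (common random numbers) design: each replication
  generates one dataset at the largest n and fits the smaller sizes on
  its leading rows, so per-seed errors are positively correlated across n
  and the RMSE comparison is variance-reduced — the standard design for
  consistency studies.  Individual small-sample fits can still be
  erratic: with a binary covariate entering one rare alternative, (β, σ)
  is weakly identified and occasional maximum-likelihood estimates walk
  out a ridge of nearly constant β/σ.  That is genuine finite-sample
  behaviour of simulated ML, visible in the RMSE levels, not hidden.
- **LR size study**: 30 replications of two groups drawn from one shared
  truth, fixed-coefficient specs (the statistic consumes only the three
  converged log-likelihoods), nominal size 10%; the separate-model
  support rate stays within three Monte-Carlo standard errors of nominal.
  A companion power check shows the support rate rising toward 1 as the
  true group gap grows.
- **Coverage**: 95% Wald intervals from the plain-MNL fit cover the truth
  at roughly nominal rate over 30 replications at n = 2000.

These sizes (100–200 draws, 20–30 replications, n ≤ 5000) were chosen as
the smallest designs at which each property is clearly resolved; the
production default of 1000 draws is unchanged.

## Degenerate inputs and numerical choices

Softmax is computed with a max-utility shift; NaN utilities are rejected.
A simulated probability below 1e−300 is floored with a logged warning
before the log.  Unknown KABCO codes, missing licensing states and
out-of-vocabulary attribute levels are quarantined into a load report,
never silently dropped — severity data dictionaries vary and silent
coercion would bias descriptive tables.  Row percents in descriptive
tables round half-up to one decimal (matching how such tables are
conventionally printed) with raw fractions retained.  Ties in the argmax
outcome generator cannot occur with probability one (continuous Gumbel
draws); numpy's argmax takes the first index in the measure-zero event.

## Known limitations

No ordered-response, nested, latent-class or correlated-random-parameter
variants; no panel (repeated-crash) draw sharing; no elasticities for
continuous covariates (all model variables are indicators); plain Halton
only up to 10 dimensions.  The LR test's degrees of freedom are supplied
by the caller when group specs differ, since parameter counts of
unestimated specifications cannot be inferred from log-likelihoods alone.
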