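# Methods

This note documents the models implemented in `volatility_learner`, the
design decisions behind the estimation machinery, what the synthetic-data
generators do and do not emulate, and the problem sizes the test suite and
the reproduction script use.

## Task model

A task run is 180 trials: a 90-trial stable block (designated shape
delivers the outcome event with probability 0.75 on every trial) and a
90-trial volatile block (probability 0.80, designated shape reversing at
every 20th within-block trial, i.e. switches after trials 20/40/60/80 with
a truncated final run of 10).  Outcome magnitudes for the two shapes are
i.i.d. uniform integers on 1..99 per trial.  The magnitude and event
sequences are deterministic functions of (task version, block order,
seed), so one seed per cohort condition yokes sequences across subjects
sharing a block order, as in the modelled experiment.  Which shape starts
as the high-probability shape is a fair coin flip from the seed; the two
blocks are concatenated with no marker visible to the agent.

Outcome valence per version: the event is *good* in the gain version
(reward delivered) and *bad* in the aversive and loss versions (shock /
points subtracted); the coded outcome `O_t` is 1 iff choosing shape 1
would yield the good outcome, which the schedule determines completely.

## Model family

Thirteen observation models share three ingredients — a probability
estimate, a value rule and a softmax choice rule:

* **#1 multiplicative**: Rescorla–Wagner estimate, risk-adjusted
  probability `(p−0.5)γ+0.5` clipped to [0,1], value = difference in
  expected value `p′M1 − (1−p′)M2`.
* **#2–#8 additive**: value `λ[p−(1−p)] + (1−λ) sign(ΔM)|ΔM|^r`
  (`r` fixed at 1 up to #6; free from #7; #8 adds a lapse
  `(1−ε)·softmax + ε/2`).
* **#9/#12 two-estimate**: separate per-shape estimates, only the chosen
  shape's estimate is updated, both then decay toward 0.5 with rate δ.
* **#10/#13 Beta–Bernoulli**: four pseudo-counts (shape × valence) decay
  by factor δ each update; the count matching the chosen shape and
  received valence gains α ∈ (0,10); probability estimates are Beta
  means `(a+1)/(a+b+2)`.
* **#11–#13** add a choice kernel `k` (exponential moving average of past
  choices) entering the softmax as `ω_k[k−(1−k)]`.

The printed update equations for the Beta–Bernoulli family add α to all
four counts; the accompanying description states only the matched count is
updated.  The implementation follows the description (only the matched
count gains α), which is also the variant with a meaningful interpretation
of α as an update magnitude.

### Condition decomposition

Natural-scale parameters are resolved per trial from unconstrained
components with ±1 effect codes: block type (+1 volatile), task version
(+1 reward gain, −1 aversive or loss) and previous-outcome valence (+1
good, −1 bad, 0 on the first trial of a run or after a missed response).
Interactions multiply their main-effect codes.  Links: logistic for
parameters in (0,1) (α of the RW families, λ, η, δ, ε), exponential for
inverse temperatures (ω, ω_k), scaled logistic onto (0.1, 10) for γ and r
and onto (0, 10) for the Beta–Bernoulli α.  The valence code for *every*
valence-split parameter reflects the outcome received on the previous
trial — the natural reading for learning rates ("learning following a
good/bad outcome"), adopted for λ and ω as well for consistency.

Component censuses: models #1/#2 have 4 components (baseline, version,
block, block×version) for each of their three parameters (12 per
subject); the winning model #11 has 7 components for α, λ and ω (adding
valence and its two-way interactions), 2 for r and ω_k (baseline +
version), 1 for η — 26 per subject, hence 2,236 subject-level parameters
for an 86-subject cohort.  A variant adds the block×version×valence
interaction to α only.

### Initialization and state handling

`p = q = k = 0.5` and zero pseudo-counts at the start of each task run
(symmetric ignorance); state carries across the seamless stable/volatile
boundary and resets between task versions.  Missed responses contribute no
likelihood and freeze all state (no outcome was observed).  Magnitudes are
divided by 100 before entering the value rule so the probability term
(range [−1,1]) and the magnitude term are commensurate and λ is a
meaningful mixture weight.

## Hierarchical estimation

Each retained component receives an independent population-level prior
`Normal(μ + β_g X_g + β_d X_d + β_a X_a, σ²)` per component, with
Normal(0, 10) hyperpriors on μ and the βs and half-Cauchy(2.5) on σ (the
weakly-informative reading of a "Cauchy(2.5)" variance prior, which keeps
σ positive).  Factor scores are z-scored before entering the linear
predictor, so βs are per-SD effects.  Components whose effect code never
varies in the data, or is exactly collinear with an already-kept
component (e.g. any version contrast when only one task version is
supplied), are dropped with a warning.

### Sampler

With no autodifferentiation available to the package, the posterior is
sampled by a blocked MCMC scheme built for this geometry:

* **subject components** — adaptive Metropolis-within-Gibbs, one component
  at a time, vectorized across subjects (subjects are conditionally
  independent given the population level), plus one adaptive-covariance
  joint proposal per subject per sweep (covariance learned during tuning);
* **population coefficients (μ, β)** — exact conjugate Gibbs draws
  (Bayesian linear regression with known variance);
* **population SDs** — Metropolis on log σ, *interleaved with a
  non-centered rescaling move* that proposes σ and the subject residuals
  jointly while holding standardized residuals fixed.  Without this move
  the chain collapses into the hierarchical funnel and underestimates σ;
* **cross-level shifts** — a move that shifts a whole component column
  together with one population coefficient along the corresponding design
  direction (intercept or one covariate), leaving residuals unchanged.
  This lets μ and the βs mix at their marginal scale instead of through
  the slow subject-level random walk.

Chains start from a deterministic coordinate-ascent warm start (penalized
likelihood), with small per-chain jitter; proposal scales adapt only
during the tuning phase.  R-hat is computed with arviz and values above
1.1 trigger a warning, mirroring the usual convergence rule.  The
likelihood inside the sampler is a compiled kernel whose sequential part
(state recursion) runs in numba and whose elementwise part (value rule,
softmax, log-probabilities) is vectorized; a test asserts identity with
the readable reference implementation to 1e-10.

The sampler's correctness is checked against a conjugate Normal toy model
whose exact marginal posterior is computed by numerical integration, and
against closed-form shrinkage identities.

### Intervals

95% highest-density intervals are the narrowest contiguous interval
containing ⌈0.95·n⌉ sorted draws; an effect is "credible" iff its
interval excludes zero (an interval touching zero does not count).

## Model comparison

PSIS-LOO uses the reciprocal pointwise likelihood as importance ratios,
replaces the largest `min(0.2 S, 3√S)` ratios with quantiles of a
generalized-Pareto fit to the tail (empirical-Bayes fit of Zhang &
Stephens 2009, with the usual weak-prior regularization of the shape
toward 0.5), truncates at the raw maximum, and reports per-point Pareto k
diagnostics; points with k > 0.7 are flagged, not refit.  Points are
subject × trial observations.  Reported "PSIS-LOO" values use the
deviance convention −2·elpd so lower is better.  WAIC uses the variance
form of the effective-parameter penalty.  Comparison tables compute the
standard error of each pairwise elpd difference from the pointwise
differences.  The smoothing is cross-checked against an independent
implementation (arviz) and against brute-force exact leave-one-out on a
conjugate toy model.

## Synthetic cohorts

The choice generator is the generative counterpart of the likelihood: it
draws factor scores i.i.d. standard normal (the orthonormality
Anderson–Rubin scoring enforces on real data), draws subject components
from the population linear model, and plays the agent forward on the task
schedules with counterbalanced block orders (each block-order combination
assigned to n/4 subjects ±1).  Default population values anchor the
printed cross-group posterior means of the winning model — e.g. 0.16 for
the volatile−stable learning-rate component, 0.50 for good−bad, −0.21
for reward−aversive, and general-factor weights −0.18 / −0.21 / −0.19 on
the volatility, valence and volatility×valence learning-rate components —
with population SD 0.5 on the unconstrained scale, which produces
realistic heterogeneity around those anchors.  Baselines not printed as
components (e.g. baseline learning rate, inverse temperature) are set to
behaviorally typical values: learning rate ≈ 0.27, mixture weight ≈ 0.7
toward probability, ω ≈ 4.5, r ≈ 1, small perseveration.

The item generator plants a bifactor loading structure — every item loads
on a general factor and one of two specific factors — and produces
ordinal codes by thresholding standardized latent responses.  General
loadings are drawn with wide spread (0.6 ± 0.3) and specific loadings
bounded away from zero (0.4 + U(−0.15, 0.2)): heterogeneous general
loadings are what make the three-dimensional common space identifiable
(with loadings constant within blocks the general column is a linear
combination of the specific-block indicators and the structure is
exactly rank two), while the specific-loading floor reflects that scale
constructors select items that mark their subscale.  The category mixture
is one binary item per four polytomous (5/6-option) items, mirroring a
battery in which only the personality (yes/no) items are binary; each
item's thresholds get a random skew shift, as in real symptom inventories
where severe categories are rarely endorsed.

What passing tests on these generators do *not* show: robustness to
missing-not-at-random responses, to item batteries whose specific factors
correlate with acquiescence or method variance, to real response styles,
or to violations of the bivariate-normality assumption underlying
polychoric correlations.

## Bifactor pipeline

Categories endorsed by fewer than 2% of subjects are merged into their
inward neighbor until all categories meet the threshold; single-category
items are dropped with a warning.  Polychoric correlations use the
two-step estimator (thresholds from the marginal frequencies via the
standard-normal quantile function, then pairwise maximum likelihood under
the bivariate normal, with the rectangle probabilities evaluated by a
Gauss–Legendre quadrature of the tetrachoric series identity, checked
against scipy's multivariate normal CDF).  Non-positive-definite matrices
are smoothed by eigenvalue clipping.

Parallel analysis compares observed eigenvalues with the mean eigenvalue
sequence of 50 standard-normal datasets of matching size.  The retention
decision is made on the *Pearson* correlation matrix of the (collapsed)
items so that observed and simulated eigenvalue noise are comparable;
feeding it the polychoric matrix inflates the mid-spectrum relative to
the normal-data reference and over-retains.  This matches the default
behaviour of the standard R routine for parallel analysis.

The bifactor solution is Schmid–Leiman: principal-axis factoring with
iterated communalities, quartimin (oblimin) rotation by gradient
projection, one higher-order factor fitted to the lower-order factor
correlation.  With exactly two lower-order factors the higher-order model
is under-identified and the standard equality constraint is imposed (both
load √φ).  Items are assigned to the specific factor where their
orthogonalized loading exceeds 0.2 (configurable).

Two consequences of the two-factor Schmid–Leiman transform matter for
scoring.  First, its loading matrix is exactly rank two (the general
column is a linear combination of the specifics), so three orthogonal
scores cannot be computed from it directly; scoring therefore uses the
*purified* bifactor pattern (general loading plus the assigned specific
loading only), the same purification the item-assignment rule applies.
Second, the transform forces every item's general:specific ratio to be
constant within a lower-order factor; `refine_pattern` re-estimates the
loading magnitudes under the purified pattern by alternating least
squares on the off-diagonal correlations, recovering per-item ratios
(the exploratory counterpart of re-estimating loadings after item
assignment).  Anderson–Rubin scores whiten with the sample correlation of
the standardized responses, which makes the score columns exactly
orthonormal on the estimation sample; reduced-item scoring restricts the
weights to the supplied items and standardizes them with pooled
reference-sample statistics when provided.

## Recovery and posterior-predictive checks

Parameter recovery follows the estimation-based protocol: the model is
fit once to a synthetic cohort, the *estimated* (posterior-mean) subject
components serve as ground truth, replicate datasets are simulated from
them and re-fit, and recovery is the across-subject Pearson correlation
between ground truth and recovered posterior means, per component,
averaged over components and replicates.  Ground truth taken as estimates
rather than raw population draws matches how recovery is assessed in
practice (the recoverable quantity is what the method reports, in the
subspace the data constrain); raw draws include variance along
directions 360 trials cannot identify, and recovery measured against
them conflates identifiability with reproducibility.

The switch-count check simulates one dataset per subject from
posterior-mean parameters and correlates simulated with observed
switch counts across subjects.  Expected learning rates per condition
cell evaluate `logistic(Σ (μ_c + β_g,c · offset) χ_c)` per posterior draw
for a hypothetical subject `offset` SDs out on the general factor.

## Problem sizes

The package's own experiments are scaled to a single CPU:

* recovery (tests): 20 subjects, 2 replicates, 2 chains × (500 tune +
  500 draws); the reproduction script uses 4 chains × (1200 + 1200);
* population-effect repeats: 20 cohorts of 86 subjects × two task
  versions, 1 chain × (250 + 320) each;
* model-selection check: 40 subjects, one task version, 2 chains ×
  (300 + 400);
* bifactor: 128 items × 285 subjects.

Full-scale configurations (10 replicates, 4 chains × 2200 sweeps) are a
matter of passing larger numbers to the same functions.

## Known limitations

* The sampler is a random-walk scheme; posterior tails and interval
  calibration at very short runs are approximate, and weakly identified
  components (kernel update rate, kernel temperature) mix slowest —
  consistent with those parameters being the convergence stragglers in
  hierarchical fits of this family generally.
* Polychoric estimation is pairwise two-step; full-information ML is out
  of scope.
* Exact-refit corrections for high-Pareto-k points are not implemented
  (flagging only).
* The loss task version shares the aversive version's valence map; no
  separate loss-specific parameters are introduced.
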