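# Methods

## The model

An MPT model maps a parameter vector θ ∈ [0,1]^K to category probabilities:
for each response tree, the probability of a category is the sum over its
branches of products of factors, each factor a process probability `p`, its
complement `1−p`, or a constant.  Validity is checked numerically: branch
products must sum to one per tree at 100 quasi-random parameter points
(tolerance 1e−9 by default, 1e−12 in the test suite).  Symbolic validation
was deliberately avoided — the numeric check is cheap and catches every
practical mis-specification, including typos in EQN files.

Two constructors cover the source-monitoring family: `build_2htsm()` (the
four-parameter submodel with a single item-memory parameter for old and new
items) and `build_2htsm_bell()` (two within-subject conditions; per condition
separate item and source memory per source, shared guessing, and distractor
detection fixed deterministically to `D_New = (D_A + D_B)/2`).  Derived
parameters like `D_New` are expression nodes evaluated before branch
products, not sampled quantities; in EQN files they travel as structured
`# derived:` comments so models round-trip losslessly.

The statistical model assumes item homogeneity: responses are aggregated
over items, and each participant's per-tree counts are multinomial at
θ_i = Φ(z_i), with z_i ~ MVN(μ, Σ), Σ = diag(σ) Ω diag(σ).  Within-subject
condition parameters share one covariance matrix (P = 12 in the two-condition
variant); between-subject groups would get independent hierarchies.

## Priors

- `informative`: probit-normal group means N(0, 0.28) for guessing-type
  parameters (b, g; "0.28" is read as a standard deviation — the stricter of
  the two possible readings, and the one that mildly concentrates guessing
  near the chance level 0.5) and N(0, 1) for memory-type parameters (D, d);
  σ_p ~ Gamma(shape 2, rate 3) (mean 2/3 on the probit-SD scale; shape-rate
  is the dominant convention in this literature — both readings are
  configurable via `NormalSpec.scale_is` and `GammaSpec`); Ω ~ LKJ(1).
  The N(0, 0.28) applies to *both* guessing parameters; a user can override
  either via the config's `group_mean` block.
- `matzke_klauer`: N(0, 1) means for all parameters (uniform implied
  probability-scale prior) and the TreeBUGS-style covariance construction —
  precision ~ Wishart(identity scale, df = P+1) with parameter-expanded
  scaling factors ξ_p ~ Uniform(0, 10).  The construction is isolated behind
  `TreeBUGSDeviation` so its hyperparameters can be adjusted without touching
  callers.

Parameter types are inferred from base names (D/d memory, b/g guessing);
anything else must be tagged explicitly.  `extremeness_index` (individual
prior mass within a band of 0/1, with a draw-level Monte-Carlo SE that
respects the within-draw correlation of participants) quantifies the
pathology that motivates the informative preset: under the default priors
roughly 69% of individual-level source-guessing mass sits within 0.1 of the
extremes, versus roughly 11% under the informative preset.

Because Φ is nonlinear, Φ(μ_p) is the probability-scale group *median*;
`group_prob_summary` reports the individual-level mean in closed form per
draw as Φ(μ/√(1+σ²)) averaged over draws.

## Posterior sampling

No probabilistic-programming backend is assumed; the sampler is an adaptive
Metropolis-within-Gibbs over the unconstrained parameterization:

1. individual probit vectors z_i: per-participant random-walk MH, vectorized
   across participants, with per-participant scalar proposal scales;
2. group means μ: exact conjugate Gibbs given z and Σ (normal prior ×
   MVN likelihood);
3. non-centered *translation* moves: shift μ_p and every participant's z_p
   together (deviations fixed), one component at a time — the MVN prior
   cancels, so only the likelihood of the trees containing that parameter
   and the prior on μ_p enter;
4. deviation SDs σ: a joint random-walk on log σ against the centered target,
   plus componentwise non-centered *rescale* moves that hold the
   standardized deviations fixed — together these break the funnel between
   σ_p and the deviations of weakly identified parameters (source memory
   appears in few branches and is the slowest-mixing block);
5. correlation Ω: random-walk on the off-diagonals with a Cholesky
   positive-definiteness check and the LKJ(η) density det(Ω)^(η−1);
6. TreeBUGS construction: conjugate inverse-Wishart Gibbs for the scale
   matrix, MH on log ξ.

Proposal scales adapt by Robbins–Monro toward 0.234 (multivariate) / 0.44
(univariate) during warmup and freeze afterwards, so the post-warmup chain is
a valid time-homogeneous MCMC.  With the hierarchy collapsed (deviation fixed
at 0) the sampler reduces to random-walk MH on μ alone, which is how the
conjugate single-binomial oracle is run.  Initialization: probit means 0
(jittered per chain), σ at the prior median, identity correlation, individual
deviations 0; a non-finite starting likelihood triggers re-jittering up to a
retry cap.

Default settings mirror the full-scale protocol (50,000 retained draws,
10,000 warmup, 3 chains); `McmcSettings.smoke()` (2,000/1,000, 2 chains) is
the desk-scale profile used throughout the tests.  Split-R-hat and bulk ESS
(via arviz) are reported for every group-level quantity; max R-hat ≥ 1.05
attaches a warning rather than raising, because weakly identified
source-memory blocks legitimately need longer chains at paper scale.

## Predictive checks

`predictive_simulate` replays the generative story for retained draws
(parameter draws re-used per replicate: the standard joint draw of parameters
and data).  T1 is a Pearson-type discrepancy on mean category frequencies,
`Σ (n̄_k − ē_k)²/ē_k`; T2 the analogous discrepancy on the across-participant
covariance matrix of category frequencies, with the model-expected covariance
computed analytically per draw as the covariance of expectations plus the
mean multinomial noise, and entries standardized by √(V_kk V_ll).  p-values
are `Pr(T(rep) ≥ T(obs))` with ties counted as exceedances.  The exact
discrepancy formulas are isolated in two small functions (`_t1`, `_t2`) so
they can be aligned with other conventions without touching the machinery.
Under the true model the p-values avoid the 2.5% tails in ≥ 90% of seeded
runs (they are conservative, as posterior-predictive p-values are).

## Bayes factors

Order constraints are conjunctions of strict inequalities over derived
quantities (arithmetic expressions over model parameters, evaluated on the
probability scale by default — the scale on which the hypotheses are stated —
or on the probit scale on request; exact ties count as non-conforming).
Results can legitimately differ between scales for order constraints among
differences; the package treats the scale as part of the hypothesis.

- Prior proportions: the analytic path requires each constrained quantity to
  be a difference of two distinct parameters with identical, independent,
  zero-symmetric priors, and every ordered quantity to be sign-constrained;
  it returns `0.5^m × (#linear extensions of the order DAG)/k!`.  (The naive
  "÷2 per pairwise ordering" rule is a special case and is wrong for chains
  of three or more; the linear-extension count is exact.)  Everything else
  goes through Monte Carlo with a binomial SE.
- `encompassing_bf`: posterior conforming fraction ÷ prior proportion.
  Fewer than 10 conforming draws flags the result; zero conforming draws
  reports the upper bound `1/(n × prior proportion)` instead of 0, since a
  zero is a finite-sampling artifact.
- `savage_dickey_bf`: posterior ÷ prior density at the null, per quantity,
  multiplied across quantities — justified because the test-relevant group
  means have independent priors in this model family; a joint estimate is
  deliberately not the default.  Density estimators: an in-package log-spline
  (penalized ML on a cubic B-spline basis over the declared bounded support,
  quantile-placed knots, BIC-selected knot count, Gauss–Legendre
  normalization; it passes uniform/normal/triangular/Beta oracles to ≤ 5%)
  and a moment-matched truncated normal.  The truncated normal is more
  stable but biased for skewed posteriors — the two methods agreeing is
  itself a diagnostic.
- `compose_by_transitivity`: BF_r0 = BF_re / BF_0e, with encompassing-model
  fingerprints checked so the two inputs provably share one posterior.
- `bf_repeat` (fresh seeds, full re-sampling) and `split_draw_segments`
  (disjoint chain segments, labeled fast mode) both quantify computational
  stability; the published protocol is ambiguous between them, so both are
  provided.
- `individual_level_bf` applies the restriction to every participant
  simultaneously; the prior proportion must come from Monte Carlo (the
  hierarchy has no analytic form).  The Monte-Carlo path simulates only the
  marginal MVN of the constrained parameters (group structure drawn in full,
  so the marginal is exact), which makes 10⁶ draws × 138 participants a
  ~30 s computation.
- The direction of the disordinal inequality (which condition has the larger
  effect) is configuration, not code: the underlying studies are ambiguous
  about it, and the prior proportion is direction-invariant by symmetry.

## Synthetic data

The generator instantiates the generative model: group probit means,
MVN individual deviations, probit-inverse, per-tree multinomials.  The
default study design mirrors the two-condition face/behavior paradigm:
per condition 10 source-A and 10 source-B studied items and — the split of
the 40 new faces across conditions being unstated in the source design —
20 new items per condition (configurable), 80 trials per participant,
138 participants.  Illustrative truth values default to magnitudes typical
of such studies (item memory ≈ .5, source memory ≈ .15–.45, guessing ≈
.35/.65 across conditions, deviation SD 0.4 on the probit scale, identity
correlation); they are demo values, not estimates of any dataset.

What the generator does *not* emulate: item-level heterogeneity (it draws
aggregated counts directly, exactly as the model assumes), stimulus
properties, serial-position or fatigue effects, and non-MVN individual
differences.  Passing recovery and calibration tests therefore show the
implementation is faithful to its own assumptions — not that those
assumptions hold for any real dataset.

## Problem sizes used in the checks

The test suite runs everything at desk scale, chosen as the smallest sizes at
which the checks are statistically meaningful: parameter recovery at 100
participants with the smoke MCMC profile (tolerances 0.1 for item memory and
guessing, 0.15 for the weakly identified source memory); T1/T2 calibration
over 20 seeded runs at 25 participants; preset contrasts and estimator
oracles at 10⁵ draws; the individual-level prior probability at 10⁶ draws and
138 participants (matching the published design; the estimate is ≈ 3×10⁻⁴
under this package's prior conventions, the same order as the published
≈ 5×10⁻⁴ — the residual gap is consistent with the documented ambiguities in
the Gamma/Normal scale conventions).  The full-scale (50,000-draw) case-study
reproduction requires the original dataset, which ships with the published
reanalysis, not with this package; `examples/case_study.py --profile paper
--data <csv>` runs that protocol end to end.

## Known limitations

- The sampler is random-walk based; for P ≫ 12 or thousands of participants
  a gradient-based backend would mix faster.  The sampler contract (any
  correct MCMC over the unconstrained parameterization producing
  `ParameterDraws`) is the intended extension point.
- Posterior fitting under the TreeBUGS-default prior uses parameter
  expansion with MH on ξ; it mixes more slowly than the gamma/LKJ family and
  is primarily intended for prior-predictive contrasts.
- Savage–Dickey results assume the null quantity's prior is independent of
  nuisance parameters; testing individual-level point nulls (which violate
  this) is intentionally unsupported.
- Log-spline density estimates below ~500 in-support samples are refused
  rather than extrapolated.
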