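# Methods

This note records the models the package implements, the conventions
and defaults it commits to, and what the synthetic testbed does and
does not establish.

## Rank inference

**Data contract.**  A pant-grunt is directed from the subordinate
(giver) to the dominant (receiver); the Elo engine scores the receiver
as the winner.  Only interactions where both participants are at least
12.0 years old enter the rank record (inclusive boundary; ages are
whole-day differences divided by 365.25).  A male's hierarchy-entry
date is the later of his age-12.0 date and his first appearance in the
filtered interaction record; the operational definition matters only
for where his daily series starts, not for the likelihood.  Within-day
interaction order is input-file order and is part of the data contract:
the sequential likelihood is deterministic only under a declared
ordering.

**Likelihood.**  With logistic scale fixed at 400 rating points (the
classical convention: a 400-point gap gives 10:1 odds) the win
probability is p = 1/(1 + 10^(−Δ/400)) and each interaction contributes
−ln p(winner); winner and loser then gain/lose k(1 − p).  Free
parameters are ln k and the per-male entry scores.  The likelihood is
invariant to translating all entry scores, so the mean entry score is
anchored at 1000; cardinal and ordinal outputs are anchor-invariant
(tested).  Optimisation is quasi-Newton (L-BFGS-B) from the fixed
documented start k = 16, all entries at the anchor; non-convergence is
reported, not raised.

**Identifiability caveat.**  k is informed only by *change* in the
implied hierarchy.  On sparse records (≈1,000 events among 10 males)
the static model k → 0 can beat the truth's likelihood and the
estimate collapses; at the ≈2,000+ event densities of the recovery
benchmark the median relative error of k is below 20% and the entry
ordering is recovered with Spearman ≥ 0.9.  Users applying the fit to
thin records should check k against a profile of the likelihood.

**Daily series.**  One record per male-day from entry to death or last
observation; raw scores are constant between interaction days and step
after a day's updates.  Cardinal score: mean probability of beating
each of the other n−1 males present, i.e. division by the number of
potential opponents, which makes the measure reach [0, 1] exactly and
sum to n/2 per day (machine-precision identity, tested).  Ordinal
ranks: 1 = highest raw score, ties share the smallest applicable rank.
Days with a single male present have undefined cardinal/ordinal and
are excluded downstream.

## Trajectory components

Six per-male summaries with eligibility rules: entry cardinal and rise
slope require entry at age in [12, 13); peak cardinal and best ordinal
require rank data to at least age 26; top tenure additionally requires
best ordinal ≤ 3 and entry before 16; the decline slope requires two
years of data past the last day at the best ordinal.  Slopes are per
year (365.25 days).  The decline is measured from the last day at best
ordinal to the last available day within the following
round(2 × 365.25) = 730 days, divided by the actual elapsed time.  A
male who never rises above his entry rank has an inapplicable rise
slope (flagged with a reason, not silently dropped).  Validation
regressions are bivariate OLS of a component on a z-scored trait;
sensitivity exclusions are passed explicitly and never alter other
males' components.

## Personality

Trait scores average keyed items within rater (reversing − items as
8 − x, missing items pairwise-excluded), then across raters.  The
item→trait key is configuration; the shipped default is a synthetic
unit-weighted key over 19 of 24 items assembled from the adjectives
that define each trait, with five filler items unkeyed.  Analyses of
deposited instruments should supply the instrument's own key as YAML.

ICC(3,k) comes from the targets × raters two-way ANOVA (statsmodels
OLS, type-II sums of squares): (BMS − EMS)/BMS.  For unbalanced
designs k is the harmonic mean of raters per target.  The estimate is
invariant to shifting or positively rescaling all ratings (tested) and
agrees with pingouin's ICC(C,k) on balanced data.

## Rank GAMM engine

Gaussian additive mixed model fitted by penalized least squares:

* **Basis.**  Cubic regression splines in the value-at-knots
  parameterisation with natural boundary conditions; knots at evenly
  spaced quantiles of the unique covariate values (default 5 per
  margin).  The wiggliness penalty is the integrated squared second
  derivative.  Evaluation outside the knot range clamps to the
  boundary value by default; linear extrapolation is available but is
  dangerous for tensor products under out-of-sample prediction.
* **Identifiability.**  Main-effect smooths are centred (sum-to-zero
  over training rows), so a 5-knot smooth has 4 reference df and a
  5 × 5 tensor-product interaction 16; `ti` terms are row-wise
  Kronecker products of centred marginals with one penalty per margin.
* **Shrinkage.**  Double-penalty: each term's penalty null space (the
  linear part the wiggliness penalty cannot reach) gets a separate
  ridge with its own smoothing parameter.  A truly linear effect can
  therefore rest at edf ≈ 1 and a null effect at edf ≈ 0.  The
  single-penalty alternative (null-space eigenvalues floored at a
  fraction of the smallest positive one) cannot represent a linear
  effect parsimoniously — with it, even the reference implementation
  reports ≈3.5 edf for exactly linear data — which is why the
  double-penalty form is the default and only form here.
* **Random effects.**  Per-male intercepts and per-male slopes in age
  and each trait as identity-penalized dummy blocks; model 6 adds a
  per-date intercept.  Unseen levels predict at the population level.
* **REML.**  For smoothing parameters λ, the restricted criterion is
  computed from the penalized normal equations with σ² profiled out;
  penalty blocks are normalized to unit Frobenius norm so the log-λ
  live on a common scale, optimised by L-BFGS-B within [−12, 25].
  Per-term edf is the trace of the hat-matrix block; term χ² tests are
  Wald-type on the Bayesian covariance with df equal to the edf and
  are approximate (terms shrunk below edf 0.05 report p = 1).  Nested
  fits are compared by χ² on 2|ΔREML| with df = Δedf.
* **Validation.**  On shared fixtures the engine matches mgcv
  (REML-selected `cs` smooths) to ≈1e-4 in fitted values and ≈0.01 edf.
* **Null-smooth collapse is probabilistic.**  REML leaves a pure-noise
  smooth above 0.5 edf on roughly 15–35% of realizations — verified
  side-by-side with mgcv, which shows the same rates on identical
  data — so collapse-rate checks are run over 20 seeded replicates
  with an 80% criterion rather than asserted per-realization.

**The six-model suite.**  1: age only; 2/3: + Dominance /
Conscientiousness with its age interaction; 4: both; 5: all six
traits; 6: model 5 plus the date random effect.  Every model carries
the per-male random intercept and random slopes for age and each
included trait.

**Cross-validation.**  Stratified: each male's rows are split across
10 seeded folds.  Forward chaining: date-ordered rows in 10 sequential
blocks, training on blocks 1..m to predict block m+1 — predictions
provably use only past data (audited from fold indices).  Smoothing
parameters are estimated once on the full table and held fixed while
folds refit coefficients: re-selecting smoothness inside small early
folds, where age and male identity are nearly confounded, lets a steep
age tilt cancel against male random effects and produces unbounded
out-of-fold errors.  Full per-fold re-selection remains available as an
option.  Forward-chaining error is expected to exceed the stratified
error whenever rank is temporally autocorrelated, and its early folds
remain the least reliable because they contain the fewest males.

## Siring model

Risk sets: siring date = birth − 228 days (mean gestation for
singleton births); candidates are males ≥ 11.0 years old that day with
a cardinal score, trait scores and a recorded relatedness to the
mother; dyads missing relatedness are excluded, and an event whose
true sire fails the filters raises an integrity error rather than
silently losing its case.  Age and cardinal Elo are z-scored across
retained rows; trait scores across the candidate male sample (one
value per male reused over events).

The GLMM is Bernoulli-logit with a per-male random intercept; the
random effect is integrated out by 25-node Gauss–Hermite quadrature
(the likelihood factorizes over males), coefficients and log σ
optimised jointly, Wald 95% intervals from the numerical Hessian at
the optimum.  Fixing σ = 0 reproduces plain logistic regression
exactly, and estimates match lme4's `glmer` (nAGQ = 25) to ~1e-3 on
shared fixtures.  AICc uses n = number of candidate rows (Bernoulli
observations) and p = fixed effects + 1 for the random-intercept SD;
Δi = AICc_i − AICc_best is reported as a non-negative quantity and
Akaike weights normalize exp(−Δ/2).  The 14-model family spans the
base terms (age, Elo, relatedness), linear/quadratic Dominance and
Conscientiousness, their age and Elo products, and one all-six-trait
model.

## Synthetic data

One seed feeds named sub-streams (roster, interactions, ratings,
relatedness, siring), so bundles are byte-reproducible and stages can
be re-randomised independently.  Defaults describe a community of 30
males observed over 37 years with entries staggered from 10 years
before the window to 4 years before its end, exponential adult
lifespan of mean 14 years beyond age 12, and ~16 interactions per
male-year — the observation density of a multi-decade field study.  A
single latent quality scalar per male links entry scores (loading 0.6,
entry SD 300 rating points, spreading entry win probabilities over
roughly the 0.1–0.5 cardinal range of a real mid-sized hierarchy),
true traits (Dominance +0.775, Conscientiousness −0.775, giving a
trait-level correlation of −0.60), and siring odds.  Interactions are
generated sequentially from the true Elo process; sires are drawn by a
multinomial logit over each event's candidates with coefficients on
z-scored rank and age (scaled over all candidate rows, matching the
risk-set assembly), relatedness, Dominance and Dominance².

Rater noise has two parts: an error in the rater's perception of the
male's latent quality that propagates through the trait loadings (a
halo — the same misjudgement raises Dominance and lowers
Conscientiousness together) and an independent per-trait residual,
smaller for the behaviorally salient Dominance/Conscientiousness
items.  This split is what lets the observed trait correlation stay
near −0.6 while interrater reliabilities of mean scores sit in the
0.35–0.55 band; with independent rater noise those two targets are
mutually inconsistent, since attenuation would drag the observed
correlation toward −0.25.  Item scores are discretised and clipped to
1–7, which mildly attenuates both quantities; the delivered values are
checked by Monte Carlo, not asserted analytically.

`SimConfig.recovery_benchmark()` (10 males, 18 years, 40
interactions/male-year → a few thousand events) is the condition for
parameter-recovery studies; `simulate_risk_rows` draws risk-set rows
directly from the Bernoulli GLMM — the exact process the siring model
assumes — for coefficient-recovery and CI-coverage properties, where
the community generator's multinomial sire assignment would confound
the comparison.

**What passing tests do not show.**  The generator's males have
time-constant competitive ability between interactions (a martingale
Elo walk, no aging trend), raters share no systematic biases beyond
the halo term, relatedness is independent of the hierarchy, and
observation effort is uniform in time.  Recovery under these
conditions demonstrates correctness of the estimators, not robustness
to phenomena real field data contain — observation gaps, age-driven
ability change, rater drift, or non-random paternity sampling.

## Problem sizes

The test suite and the acceptance script run the Elo recovery at the
benchmark density (20 replicates), the GAMM suite on a 20-male /
25-year community thinned to every 10th day (~8k rows), CV on half of
that, the GLMM family at the study's event scale (55 events, ~400
candidate rows), and calibration studies at 15–25 replicates.  These
sizes are the package's defaults for its own verification; all scale
up by configuration.
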