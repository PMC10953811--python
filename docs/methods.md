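# Methods

## Judgment variables from picture ratings

All statistics are computed per participant × picture category, pooling the
two presentations of the 8 category pictures into a single 16-rating sample
(one (K, σ, H, H₊, H₋) point per category; pooling maximizes the per-point
sample size and is the only rule that keeps the six-point fits determined).
σ uses the n−1 divisor and is defined as 0 for a single rating.  Entropies
are in bits (base 2) with the 0·log 0 := 0 convention; H₊ and H₋ condition
on the sign of the rating and are 0 when no rating of that sign occurs.

The value function is fitted in logarithmic form, H = a + b·ln|K|, per limb
(approach K>0, avoidance K<0); points with K = 0 carry no ln|K| and are
dropped.  A limb with fewer than two usable points makes the participant's
feature set incomplete.  The power-law alternative (ln H on ln|K|) was
considered and not implemented: the logarithmic form is the one whose
diagnostics the surrounding analyses consume, and a second fit family would
double the QA surface without changing any downstream contract.  Adjusted
R² uses p = 1 predictor per limb; the F statistic is the usual regression F
(∞ for an exact fit).

The limit function is a single quadratic σ(K) over all six category points
(branches are not fitted separately; with three points per half-axis,
separate quadratics would be exactly determined and their R² meaningless).
Features are read off each half of the rating scale [−3, 3]:

- peak risk = max of the fitted quadratic on the half-axis (closed form via
  the vertex);
- tipping point = the root of σ(K) nearest zero on that half-axis, or the
  scale boundary 3 when no root lies in (0, 3] — features must be total
  functions for the classifiers;
- total risk = ∫ max(σ(K), 0) dK from 0 to the tipping point, evaluated
  exactly by splitting the interval at the quadratic's roots and
  integrating the antiderivative on the positive pieces.

The trade-off function is a polar summary, not a curve fit: each category
point maps to radius √(H₊²+H₋²) and angle atan2(H₋, H₊) ∈ [0°, 90°].
Zero-radius points (a participant indifferent to a category) have no angle
and are excluded from the angle aggregates but kept in the radius
aggregates.  Mean angle, angle range, mean radius and radius range are the
four trade-off features.

Loss aversion is the slope-magnitude ratio |b₋|/|b₊|.  Being a ratio it is
heavy-tailed: when the approach limb is nearly flat the feature explodes,
which is precisely what the extreme-outlier exclusion below is for.  The
15-feature vector satisfies an exact mirror symmetry — negating every
rating swaps the approach/avoidance roles (risk aversion ↔ loss resilience,
ante ↔ insurance, the peak/tipping/total features swap sides, the trade-off
angle reflects about 45°, loss aversion inverts) — which the test suite
uses as an algebraic invariant of the whole extraction path.

## Quality assurance

A participant is dropped when any of these fire: FLAT (all 96 ratings
identical), NEAR_FLAT (ratings span ≤1 point), INCOMPLETE (missing rating
records, a failed fit, or a non-finite feature), LOW_FIT (any value- or
limit-function R² below 0.8), OUTLIER (any feature with modified z =
0.6745·|x−median|/MAD above 4, medians and MADs taken over the cohort's
complete profiles), and SPEEDER (questionnaire completed in under 800 s,
applied only when a completion-time column exists).  The outlier rule is
per-feature, not multivariate — the simplest reading of "extreme outliers"
that is scale-free across features with very different units.

## The synthetic cohort

The generator is the package's stand-in for the undeposited survey data and
defines the study conditions for every test.  Three independent standard
normal latent factors drive rating behaviour: `g` sets the
negative-overweighting asymmetry κ = 0.25 + 0.2·g, `u` the dispersion
multiplier e^{0.1u}, and `t` the additive valence shift 0.2·t.  A category
with valence v is rated around mean μ = v·e^{−κ·sign(v)} + shift, with SD

    sd = noise_sd · e^{0.1u} · max(2.0 − 0.2·μ², 0.15),

rounded to the nearest level and clipped to [−3, 3].  The quadratic SD law
is what embeds the two regularities the extractor fits — σ is an inverted-U
in K, and H falls with ln|K| — and the multiplicative asymmetry makes the
mirror identity exact at the mean level: negating all valences and κ negates
every category mean.  Because the avoidance limb sits at larger |μ| where
the entropy curve is steeper, κ shifts the fitted slope ratio, making median
loss aversion strictly increasing in the asymmetry parameter (verified as a
property test).  Default category valences (−2.4 … +2.4 across the six
categories) are arbitrary in the sense that no per-category rating
distributions are published; they were chosen to give three categories per
limb spanning the scale.

Demographics use the marginal proportions of the published demographic
summary table (N=3476) as categorical/ordinal targets; age is a truncated
normal (mean 51.40, SD 14.92, range 18–70).  Mediation structure is
embedded linearly: the age z-score, income and education each load on `g`
with weight `mediation_strength` (income and education additionally load on
age with weight 0.3), so the generative a-path equals `mediation_strength`
and the b-path equals the demographic's logistic coefficient, giving a known
indirect effect a·b without any causal claim.  Uptake is Bernoulli with
logit = intercept + Xβ over standardized features, the intercept solved by
bisection so the expected uptake rate equals the configured base rate
(default 72.64%, the published share; the survey reports only the observed
rate, not a generative intercept).  The four precaution behaviours load on
the standardized uptake logit with coupling 0.8 so they carry signal without
determining the outcome.

What the generator does **not** emulate: real IAPS image semantics, the
mental-health oversampling of the original panel, response styles beyond
flat-rating, and — importantly — the very high per-participant lawfulness
of real raters.  With only 16 ratings per category point, sampling noise in
Ĥ and σ̂ leaves roughly a third of synthetic participants above the R²>0.8
QA bar, versus 86.49% retention in the survey.  Passing tests therefore
demonstrate correctness of the estimators and pipeline on data with the
study's *structure*, not that real raters behave like the generator.

## Group comparison

The Wilcoxon rank sum test reports per-group actual and expected rank sums
(n_g(N+1)/2) with a Higher/Lower direction flag, midranks for ties, and a
two-sided p from the tie-corrected normal approximation.  When both groups
have ≤8 observations the p value switches to exhaustive enumeration of all
group assignments — the approximation is unusable there, while at cohort
scale (N≈3476) enumeration is pointless.  Chi-square is the Pearson
statistic without continuity correction; zero-margin rows/columns are
dropped with a warning.  Benjamini–Hochberg q values are computed step-up
over the full family of tests by default (m = all 15 judgment variables).
A `significant_only` flag instead restricts the family to nominally
significant p values, a nonstandard correction family some survey reports
use; the two modes agree only when every test in the family is significant.

## Prediction

"Number of tree splits" is interpreted as the maximum tree depth — the only
standard per-tree parameter taking the values 10/15 in the study's
toolchain.  The balanced random forest grows each Gini-criterion tree on a
bootstrap containing n_min draws with replacement from each class (n_min =
minority count), so every tree sees a balanced sample; test folds are never
resampled.  Cross-validation is stratified (unstratified folds at a 27%
minority would occasionally yield single-class test folds, leaving recall
or specificity undefined); fold-level metrics are averaged, not pooled, and
folds where a metric is undefined are excluded from that metric's mean with
a logged count.  AUROC is the Mann–Whitney rank statistic with midrank
(half-credit) ties.  Gini importances are impurity decreases averaged over
trees and folds, normalized to sum 1, with group sums over {age, income,
education}, the 15 judgment variables, and the remainder.  Logistic
regression standardizes features with training-fold statistics and caps
optimization at 100 iterations; the standalone logistic report (statsmodels
MLE) gives Wald SEs, z, p, coefficient ± 1.96·SE intervals, and McFadden
pseudo-R² against the intercept-only model.  Nominal demographics enter as
single integer-coded variables — faithful to the one-coefficient-per-
variable shape of the published regression tables, and statistically
questionable for the same reason; dummy coding would change both the
regression and the Gini grouping.

## Mediation and moderation

The estimand is the product of coefficients a·b: a from OLS of the
standardized mediator on the standardized IV, b from the logistic model of
the binary DV on (IV, mediator).  The total effect c (IV-only logistic) and
direct effect c′ are reported but not differenced — with a binary outcome
c and c′ live on different latent scales, so c − c′ is not a clean indirect
effect while a·b is.  Inference is a nonparametric case-resampling
percentile bootstrap (default 1000 resamples; percentile rather than BCa
for speed and simplicity), p = 2·min(frac ≤ 0, frac ≥ 0); a Sobel z is
included as an analytic secondary check.  Moderation fits DV ~ IV +
moderator + IV×moderator on standardized (hence centered) inputs and
Wald-tests the product term.  The sweep runs 45 primary mediations
(judgment IV, demographic mediator), 45 secondary (roles swapped) and 45
moderations, with per-cell error capture and no multiple-testing correction
(the sweep is reported at raw α = .05).  Logistic fits inside the bootstrap
use an in-package Newton–Raphson (IRLS) solver with a 1e−8 ridge — three
orders of magnitude faster than a full model object per resample — and are
cross-checked against statsmodels in the tests.  No covariates are included
in the mediation regressions; the sweep is a screen for statistical
pathway, not a causal adjustment exercise.

## Pipeline

Stages run simulate → features → compare → predict → mediate; each stage's
seed derives deterministically from the global seed through a fixed
SeedSequence schedule so stages can be rerun in isolation.  All outputs are
plain CSV/JSON with stable column order; the run manifest records a config
hash, per-stage row counts (exclusion accounting always reconciles: input =
analyzed + Σ dropped-by-reason) and wall-clock times.  The default model
grid runs at 10 repeats of 10-fold CV; the full 100×10 protocol is a config
value (`cv_repeats: 100`) and changes only runtime, since the repeat
dimension enters the reported means symmetrically.

## Problem sizes in the tests and acceptance script

Unit tests run on cohorts of 100–400 participants.  The acceptance checks
use: 2000-participant cohorts for the prediction and mediation-recovery
properties (10×10 CV for the balance comparison, 5×10 in the script); 500
simulations each for the rank-sum, mediation and moderation null-calibration
rates (n = 1000 rows, 200 bootstrap resamples per mediation); and 100
replicates at n = 3000 for logistic CI coverage.  These sizes put Monte
Carlo error comfortably inside the asserted bands while keeping the whole
suite in a few minutes on one CPU.

## Known limitations

- The 15 feature formulas are explicit operationalizations of the published
  verbal definitions and stated function spaces; the canonical closed forms
  live in earlier literature and unshipped supplements, so numerical values
  need not match those sources even where the semantics do.
- Loss aversion is undefined (∞) for a perfectly flat approach limb; such
  profiles are flagged incomplete rather than imputed.
- The generator's raters are noisier than real ones (see above); QA
  retention on synthetic cohorts is ~30%, not ~86%.
- Integer coding of nominal demographics imposes an ordering the categories
  do not have; it is kept for fidelity to the published table shapes.
- Mediation/moderation results are associations among standardized
  variables; nothing here identifies causal direction.
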