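# Methods

This note records the models implemented in `lipidsphere`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make results reproducible.

## Phenotype classification

Subjects are classified on three axes derived from the standard lipid
panel: non-HDL cholesterol (NHDLC = TC − HDLC, mg/dL), triglycerides
(TG, mg/dL) and the inverse of HDL cholesterol (1/H, dL/mg). The
inversion makes "higher = worse" uniform across axes and makes all
pairwise correlations positive, which the later geometric treatment
relies on.

The rule has a two-level structure. A subject whose three *raw* values
(NHDLC, TG, HDLC) all lie inside their population interquartile windows
is labelled normolipidemic; the windows are closed intervals
(endpoints count as inside). Everyone else receives a three-letter
label: per axis, upper-case strictly above the population median and
lower-case at or below it (a value exactly at the median is
lower-case). The H letter is assigned on the 1/H scale, so a
user-supplied 1/H median need not equal the reciprocal of an HDLC
median, though the defaults are consistent (0.02 dL/mg ↔ 50 mg/dL).
The two levels use different statistics deliberately: membership in the
IQR box defines "normal", but once any axis leaves the box, *all three*
letters are assigned relative to medians — so a letter can be
lower-case even when that axis is individually within its IQR. We
replicate this labelling exactly rather than refining it.

Default cutoffs are US general-population reference values: windows
120–175 / 75–160 / 40–60 mg/dL and rounded medians 150 mg/dL, 110
mg/dL, 0.02 dL/mg. `calibrate_cutoffs` re-derives all six quantities
from any cohort as the empirical 25th/50th/75th percentiles (linear
interpolation). Rounding of calibrated values is **off by default**;
when requested it rounds half away from zero to caller-chosen
increments. The reference medians correspond to increments of 10 mg/dL
(146 → 150, 107 → 110) and 0.005 dL/mg, but the exact convention that
produced the published values is not documented, so we expose rounding
as an option instead of applying it silently.

## Coordinate transform

For the risk index, the transformed features (1/H, ln TG, NHDLC) are
z-scored against population means and sample standard deviations (n−1
denominator). TG is log-transformed because its population distribution
is heavily right-skewed and ln TG is approximately normal. Z-scores are
limited to ±5 and the point is shifted by +5 into the first octant;
parameters enforce `shift ≥ z_bound` so coordinates are non-negative,
which keeps both spherical angles in [0°, 90°].

Out-of-range handling differs by use: during model development,
rows with any |z| > 5 are *dropped* (`training_filter`); during
deployment every patient must receive a score, so z is *clipped* to ±5
and the result flagged (`scoring_clip`, the default). Clipping is
idempotent and affects roughly the 3-in-a-million tail under normality,
but can matter for pathological panels.

Spherical coordinates use the physics convention restricted to the
first octant: r = ‖(x,y,z)‖, polar angle θ = arccos(z/r) measured from
the NHDLC axis, azimuth φ computed as atan2(y, x) (equal to
arctan(y/x) for x > 0 and well-defined 90° at x = 0). The origin
(reachable only by a subject at z = (−5,−5,−5)) has no defined angles;
we return θ = φ = 0 with a degeneracy flag rather than erroring,
because a deployed score must not crash on an extreme panel. The
n-dimensional generalisation uses the standard hyperspherical
recursion; with the 3-vector ordered (z, x, y) it reproduces the 3-D
formulas exactly.

## Logistic lipid indices

Three chained logistic models map the coordinates to ASCVD
probabilities: L1 on (r, θ, φ); L2 on (L1, female, male); L3 on
(L1, age, female, male). Probabilities ×100 give the 0–100 "lipid
index". Two conventions are underdetermined by the published
coefficient table and were fixed as follows:

* **Angle unit: degrees.** With the bundled L1 coefficients a
  mean-valued subject scores ≈ 0.25 in degrees versus ≈ 0.66 in
  radians; only the former is plausible for a maximum-likelihood fit on
  a cohort with ~30 % outcome prevalence. The unit is stored in every
  model object and checked at scoring time, so a mismatch raises an
  error instead of silently mis-scoring.
* **L1 enters L2/L3 as a probability (0–1), not ×100.** The ~3.7
  coefficient on L1 is only sensible on the probability scale; on the
  ×100 scale its effect would be negligible.

Both sex indicators are retained exactly as published even though
{female, male, intercept} is collinear; refitting therefore applies a
small ridge penalty (default 1e−4, intercept unpenalised) so the same
parameterisation is estimable. `ridge=0` requests the exact
unpenalised MLE and raises a convergence error under complete
separation, recommending ridge. Sex is one-hot with exactly two
levels; a missing sex makes L2/L3 a scoring error while L1 remains
computable. Wald standard errors from the observed information matrix
are stored with fitted models.

Standardization parameters are stored *inside* the model file and
scoring refuses to run without them — a score produced under the wrong
population standardization is meaningless, and this is the cheapest
place to make that mistake impossible.

**Prevalence recalibration (logit shift).** A model trained at source
prevalence p_s is carried to a population with prevalence p_t by adding
logit(p_t) − logit(p_s) to the intercept. Source/target prevalences
are always caller-supplied, never guessed. The model object tracks its
unshifted base intercept and the cumulative shift, so shifting a → b →
a restores the original intercept bit-for-bit; a naive add-then-
subtract of floating-point deltas would not guarantee that. The shift
matches the target mean probability only approximately when the linear
predictor has spread (Jensen's inequality); at the spread typical of
these models (sd ≈ 0.46 on the logit scale) the residual miscalibration
is ≲ 0.005 at a 0.10 target.

**Risk enhancers.** The guideline thresholds LDLC ≥ 160 mg/dL, TG ≥
175 mg/dL, apoB ≥ 130 mg/dL are flagged together with a high-L3 flag
(default threshold 0.37, the 80th percentile of L3 in a US reference
population; population-specific percentiles should be supplied where
known). LDL cholesterol is computed by the Sampson equation, which
remains valid at high TG; a negative estimate (possible at extreme TG
with low NHDLC) is returned as-is with a warning, never clamped.

## Evaluation

* AUROC is the Mann–Whitney concordance probability with ties counted
  half (computed via scikit-learn; tests verify it against brute-force
  pairwise concordance).
* Confusion metrics call positive at score ≥ cutoff; zero-denominator
  ratios are NaN with an explicit flag.
* Cost-sensitive cutoffs: candidates are observed-score midpoints (plus
  the minimum score, the all-positive call). Stratified k-fold
  cross-validation (default 5 folds, shuffled by seed) selects the
  candidate minimising `fn_weight·FN + FP` on each held-out fold, ties
  going to the lower (more sensitive) cutoff, and the fold-optimal
  cutoffs are averaged. False negatives default to twice the weight of
  false positives — missing a future event is clinically worse than a
  spurious referral — and both the weight and fold count are exposed.
  If a fold cannot contain both classes the fold count is reduced with
  a warning; with fewer than two minority-class members it errors.
* Quantile bins split at the 1/q … (q−1)/q empirical quantiles with
  boundary ties assigned to the lower bin, so a tie group never
  straddles a boundary.
* Kaplan–Meier and the log-rank test are delegated to lifelines; tests
  pin them to hand-computed product-limit and observed-minus-expected
  worksheets, and a permutation test confirms the log-rank null type-I
  error. Survival times are used as given (years), with no
  delayed-entry support.

## Synthetic cohorts

The generator draws (1/H, ln TG, NHDLC) from a trivariate normal — the
same distributional idealisation the z-scoring step assumes — and
back-transforms hdlc = 1/(1/H), tg = exp(ln TG), tc = NHDLC + hdlc.
Defaults: means (1/51, ln 107, 146) and SDs (0.006, 0.55, 40) on the
transformed scale, placing back-transformed medians near US reference
values (HDLC ≈ 51, TG ≈ 107, NHDLC ≈ 146 mg/dL); correlations
(1/H↔lnTG 0.50, 1/H↔NHDLC 0.15, lnTG↔NHDLC 0.35), all positive, with
the strong first entry encoding the well-known inverse TG–HDL
relationship. These are documented approximations chosen once, not
values fitted to any dataset. Tail draws implying non-physiological
panels are resampled and counted. Ages are uniform on 40–70 y, 52 %
female, and apoB ≈ 0.62·NHDLC + N(0, 10) mg/dL.

Outcomes are simulated from a stored logistic model: event ~
Bernoulli(p_i), and event times are exponential with rate
p_i / survival_scale (default scale 8 y), so higher-risk subjects have
earlier events; non-events are administratively censored at the horizon
(default 15 y). Event times are deliberately *not* truncated at the
horizon: this keeps the marginal event rate exactly equal to the mean
of p_i and makes median event time scale exactly linearly in
survival_scale, which is what the parameter-recovery and calibration
tests rely on. A real registry would instead convert late events to
censorings; treat simulated follow-up beyond the horizon as a
convenience of the test harness, not an epidemiological claim.

What passing tests on these cohorts shows: that the pipeline's
machinery — transforms, scoring, fitting, recalibration, evaluation —
is internally correct under the model's own assumptions. What it does
not show: performance on real populations, where the transformed
features are not exactly normal, missingness is informative, outcome
ascertainment differs by cohort, and survey weighting matters. The
generator makes no attempt to emulate survey weights, fasting-subsample
logic, or covariance structure estimated from restricted data.

## Numerical conventions and problem sizes

Percentiles use linear interpolation (numpy default). Sample SDs use
the n−1 denominator. Rounding of calibrated cutoffs is half away from
zero. arccos arguments are clipped to [−1, 1] against rounding.
Near-axis points (a nonzero coordinate many orders of magnitude below
r) lose relative precision to arccos cancellation in the round-trip;
exact zeros are handled exactly.

The test-suite and acceptance-script problem sizes — 10,000-point
round-trips, an exhaustive 5.3-million-point phenotype grid, 50,000
subjects for coefficient recovery, 100,000 for calibration checks —
were chosen so each statistical check has comfortable power while the
full run completes in well under a minute each. One caveat found
empirically: at n = 50,000 the *intercept* of the spherical-features
model has a sampling SE of ≈ 0.145, an order larger than the slope
coefficients' (≤ 0.009), because the first-octant features sit far from
the origin and are nearly collinear with the constant term. Recovery
checks therefore hold slope coefficients to a fixed ±0.05 band but
judge the intercept against its own Wald standard error.

## Known limitations

* mg/dL only; no mmol/L conversion (a units flag errors on anything
  else rather than converting silently).
* No survey weights, no imputation, no delayed entry or competing
  risks, no confidence intervals on AUROC.
* The bundled coefficients are point estimates; no uncertainty is
  propagated through the L1 → L2/L3 chain.
* The phenotype letters are median-relative by design; within the
  eight dyslipidemic groups an individual axis may still be within its
  IQR (see above), so letters should not be read as per-axis
  abnormality calls.
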