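# Methods

This note documents the statistical machinery in `crtcascade`: the models,
the tuning protocol, the synthetic cohorts the tests run on, and the design
choices made where more than one reading was defensible.

## Preprocessing

Features are centred and scaled per column (sample standard deviation,
n−1 denominator) using training rows only, then each row is divided by its
Euclidean norm over the transformed features ("spatial sign").  The sphere
projection bounds the leverage of outlying patients: after projection no
single row can dominate a penalized fit.  Two consequences worth knowing:

- the transform is not idempotent, so `FeatureTable` carries a
  `preprocessed` flag and re-application raises;
- a *single*-feature model degenerates under spatial sign (each value
  becomes ±1), which is why recursive feature elimination — evaluated under
  the same preprocessing as the final model — tends to keep more features
  than it would under plain standardization.  That interaction is real, not
  a bug, and the RFE utility exposes `spatial_sign=False` for diagnosing it.

Spatial sign is applied to all model features, including binary indicators
after one-hot expansion (all levels retained).  Zero-variance features are
dropped with a warning; rows of zero norm are left at zero and logged.
Missing values are an error by default, with an opt-in drop-rows mode
mirroring cohort-exclusion practice.

## Base learner and ensembles

The base learner is elastic-net logistic regression minimizing

    Σᵢ log(1 + exp(−yᵢ(xᵢ·w + b))) + λ(α‖w‖₁ + (1−α)/2 ‖w‖₂²),

intercept unpenalized; α ∈ [0,1] mixes lasso and ridge, λ ≥ 0 is the total
penalty.  Fits go through scikit-learn (lbfgs when α = 0 or λ = 0, saga
otherwise; λ = 1/C) and the unpenalized intercept is re-solved exactly by a
one-dimensional Newton step afterwards, because saga resolves the intercept
slowly under strong penalties.  Non-convergence is surfaced as a warning
and a flag on the fitted model.

An ensemble draws B index subsets of size round(φ·n) **without** replacement
("pseudo-bootstrap": the tunable fraction φ < 1, not resampling with
replacement, creates the member diversity).  Subsets are sorted so row
order cannot perturb the solver.  Preprocessing is fitted once on the full
training partition and shared by all members — members then fit on their
subsets of the transformed rows; fitting the sphere projection per member
would give each member its own incompatible geometry.  Predictive mean uses
the arithmetic member average; predictive uncertainty is the (B−1)-
denominator standard deviation of the member probabilities (B = 1 reports 0
with a warning).  A subset that collapses to one class is redrawn with a
shifted seed, at most 10 times.

Defaults B = 25, φ = 0.70 sit inside the ranges that the tuning protocol
itself selects on cohorts of a few hundred patients (B 25–49, φ 0.70–0.95).

## Feature selection and hyperparameter tuning

RFE ranks features by |coefficient| of one elastic-net fit on the
standardized training partition and drops the lower half per step (halving
schedule down to one feature); the candidate subset with the best
stratified-CV AUC wins, ties to the smaller subset.

Ensemble hyperparameters (B, φ, α, λ) are tuned by mean inner-CV AUC of the
aggregated probability.  By default the **one-standard-error rule** is
applied, as in penalized-regression practice: among grid points within one
SE of the best mean AUC, the most-regularized one is selected (then fewer
members, then larger φ).  This matters for the cascade: when AUC is flat in
λ, stronger shrinkage gives the stage-1 model conservative mid-range
probabilities on patients it cannot separate — precisely the signal the
midway clause of the gate consumes.  The default λ grid is
{0.3, 1, 3, 10}; α defaults to 0.5.

## The gate and its tuning

Escalation rule (strict inequalities, OR of two clauses):

    needs_stage2  ⇔  σ̂ > τ_σ  or  |p̄ − 0.5| < τ_m.

The OR is the only reading under which each threshold independently bounds
a tolerable level of uncertainty; "midway" is interpreted as distance of
the mean probability from the 0.5 decision midpoint.  Escalated patients
take Ensemble 2's probability unchanged (pure replacement, no blending).

Threshold grids default to τ_σ ∈ {0.01,…,0.20} and τ_m ∈ {0.02,…,0.10}
(step 0.01), the value sets the protocol visits in practice; both are
configurable.  For each scaling parameter s ∈ {0.5, 1, …, 9} the pair
(τ_σ, τ_m) maximizing AUC·f^(1/s) on validation slice 1 is kept (f = the
fraction resolved at stage 1; ties to larger f, then larger τ_σ); the
weight w(f; s) = f^(1/s) satisfies w(0) = 0, w(1) = 1 and is monotone in
both arguments, so escalating everyone zeroes the objective and larger s
weakens the penalty.  Validation slice 2 then picks the candidate with the
highest plain AUC (ties to larger f).  Classification metrics use a fixed
0.5 cutoff on the final probability.

## Nested cross-validation

Stratified 10-fold outer CV; from each outer training partition two
stratified validation slices are cut (20 + 20 at n = 218, leaving 156
training rows from a 196-row partition — the slices scale proportionally at
other n).  Per fold and per stage: RFE, inner-CV tuning, ensemble fit on
the remaining training rows; gate tuning as above; evaluation of cascade,
both ensembles, and the guideline comparator on the untouched outer test
fold.  Validation slices are drawn once per fold so every scaling parameter
is tuned on identical data.  A programmatic leakage audit asserts pairwise
disjointness of train/validation1/validation2/test on every fold.  All
seeds derive from the plan seed via `SeedSequence`, making whole-protocol
replays byte-identical.

Aggregates are unweighted means and sample SDs across folds; the stage-1
retention fraction is reported with mean and quartiles.

The sample-size simulation resamples the remaining training rows **with**
replacement (deliberately a different sampler than the ensembles' subsample)
at fractions 0.1–1.0, three repeats each, retrains and retunes, and
evaluates on the unchanged outer test folds.

## Model comparison and importance

- AUC: Mann–Whitney concordance (ties half-credit), delegated to
  scikit-learn and oracle-checked against all-pairs enumeration in tests.
- DeLong: placement-covariance estimator, two-sided normal p for the AUC
  difference, 95% CIs; degenerate variance reported as p = 1 with a flag.
- McNemar: exact binomial on discordant pairs when b + c < 25 (switch
  configurable), chi-square with continuity correction otherwise; applied
  to sensitivity (positives) and specificity (negatives) separately.  The
  AUC comparison against the binary guideline rule is reported as not
  applicable.
- Baseline tables: counts (%) + chi-square for categoricals, mean ± SD +
  Welch t-test for continuous variables (Welch chosen as the safer reading
  of "two-sample t-test").
- Permutation importance: per-member metric drop after shuffling a raw
  feature column, averaged within the ensemble; fold-level aggregation
  takes absolute values.

## Guideline comparator

The 2012-style recommendation classes ship as an editable ordered rule
table (first match wins, unconditional default row): Class I = LVEF ≤ 35 ∧
LBBB ∧ QRSd ≥ 150 ∧ NYHA II–IV; Class IIa = the same with QRSd 120–149, or
non-LBBB with QRSd ≥ 150 and NYHA III/IV.  Predicted responder ⇔ class ∈
{I, IIa}.  Sinus-rhythm and medical-therapy criteria are omitted — they are
not among the recorded variables.

## Synthetic cohorts

The generator emulates the structure of a two-stage CRT cohort: n = 218
patients by default, outcome prevalence 0.555, 14 stage-1 features
(8 continuous, 6 binary) and 30 stage-2 features (24 continuous, 6 binary),
with a configurable equicorrelation among the continuous features.

Outcome model: y ~ Bernoulli(sigmoid(β₀ + x₁·β₁ + w₂·(x₂·β₂))).  A fraction
ρ (default 0.4) of patients form the **ambiguous subgroup**: their
informative stage-1 values are multiplied by an attenuation factor
(default 0 — the stage-1 linear predictor collapses, i.e. their cheap
variables are unremarkable), and by default the stage-2 signal is confined
to them (w₂ = 1 inside, 0 outside; a `global` scope is available).  This
is the construction the gate is built for: the expensive modality is
incrementally informative exactly where the cheap data is insufficient.
Ambiguity by attenuation (rather than added noise) makes the subgroup
visible to the fitted model — its predictions hover near the midpoint with
elevated member disagreement — which is a property the tests assert.

Effect sizes: β₁ = (1.0, 0.9, 0.8, 0.7) on the leading stage-1 continuous
features gives a moderate clinical signal (stage-1 test AUC ≈ 0.85 outside
the subgroup).  β₂ = (5.5, 5.0, 4.5, 4.0, 3.5, 3.0): a mixture fit dilutes
subgroup-only coefficients by roughly ρ, so β₂ is scaled by ~2/ρ relative
to β₁ to make the *learnable* within-subgroup stage-2 discrimination
decisive (within-subgroup AUC ≈ 0.95) — the staged-acquisition premise is
that imaging resolves the ambiguous patients, not that it ties with the
clinical data.  The intercept β₀ is calibrated by bisection against the
cohort's mean sigmoid to hit the target prevalence within 0.01;
calibration failure (infeasible prevalence under the given coefficients)
raises.

What the generator does **not** emulate: realistic covariance between
clinical variables, measurement error, site effects, non-linear risk, or
informative missingness.  Tests passing on these cohorts show that the
machinery recovers structure it was designed for; they are not evidence
about real CRT cohorts.

## Problem sizes used in the checks

The shipped end-to-end checks run the full protocol at n = 1000 with 10
outer folds and 100-patient validation slices (fold-averaged comparison of
the cascade against both ensembles), and the sample-size simulation at
n = 400 with 3 outer folds, 10 fractions × 3 repeats.  Fold-averaging is
the protocol's own stabilizer: single-split gate tuning at validation sizes
of one or two hundred patients is dominated by selection noise (the tuned
policies vary widely fold to fold, as the per-fold threshold tables show),
while the across-fold aggregate is reproducible.

## Known limitations

- Cascade probabilities mix two differently calibrated models; ranking
  across the escalated/retained boundary inherits that scale mismatch.
  Recalibrating the two ensembles to a common scale before mixing is a
  natural extension.
- The gate thresholds are absolute, so their effective meaning depends on
  the regularization-induced spread of the stage-1 probabilities; quantile
  versions would be scale-free but are not what the protocol specifies.
- Two stages only; no per-patient acquisition costs beyond the escalation
  fraction; no alternative base learners in this version.
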