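# Methods

## The rLR decomposition

`usmile` evaluates a *new* probabilistic binary classifier against a
*reference* classifier on the same observations.  The only model contract
is an event probability per observation; everything downstream is a
function of the triple `(y, p_ref, p_new)`.

Writing `ℓᵢ(p) = yᵢ ln pᵢ + (1−yᵢ) ln(1−pᵢ)` for the Bernoulli
log-likelihood and `dᵢ = 2(ℓᵢ(new) − ℓᵢ(ref))`, the likelihood-ratio
statistic `LR = Σ dᵢ` is split

* by class: `LR₀ = Σ_{y=0} dᵢ`, `LR₁ = Σ_{y=1} dᵢ`;
* by sign within class: `LR_c⁺ = Σ dᵢ⁺`, `LR_c⁻ = −Σ dᵢ⁻`.  Observations
  with `dᵢ = 0` (exact ties, e.g. identical probabilities) belong to
  neither subclass: they contribute nothing to either sum, and are
  likewise excluded from both I-coefficient counts.

The normalizers are the statistics a perfect classifier would attain
against the same reference, `maxLR₁ = −2 Σ_{y=1} ln p_ref,ᵢ` and
`maxLR₀ = −2 Σ_{y=0} ln(1−p_ref,ᵢ)`.  All seven ratios
(`rLR`, `rLR₀`, `rLR₁`, and the four subclass coefficients) follow by
division; the identities `LR = LR₀ + LR₁`, `rLR_c = rLR_c⁺ − rLR_c⁻` and
`rLR = rLR₀·maxLR₀/maxLR + rLR₁·maxLR₁/maxLR` hold exactly in exact
arithmetic and to ≈1e-15 relative error in floating point (asserted at
1e-8 in the acceptance suite).  With the null (prevalence) model as
reference, `rLR` equals McFadden's pseudo-R² identically.

The factor 2 keeps every LR quantity on the likelihood-ratio-test scale so
the χ² machinery applies without rescaling; the rLR coefficients are
invariant to it.

Assumptions worth stating: outcomes are binary and both classes present;
probabilities are taken at face value, so poorly calibrated models (deep
trees, boosted ensembles) should be calibrated or smoothed before the
likelihood sums are meaningful; the I coefficients use the *class* size as
denominator, because point sizes are compared between classes in the plot
and only within-class proportions make that comparison meaningful.

## Numerical choices

* **Probability clipping.** All probabilities are clipped into
  `[eps, 1−eps]` with `eps = 1e-12` (configurable) before any logarithm.
  Ordinary probabilities pass through bit-identical; exact 0/1 predictions
  stay finite.  Halving `eps` changes `rLR` by < 1e-6 when probabilities
  live in [0.001, 0.999].
* **Degenerate references.** If a class ceiling `maxLR_c` sits at the
  clipping floor (the reference is already perfect for that class), the
  corresponding rLR is undefined; the package raises
  `DegenerateReferenceError` naming the class rather than propagating NaN.
* **Forest probabilities.** The bagged-trees family grows probability
  estimators: leaves hold at least `min_samples_leaf = 10` observations so
  vote proportions do not saturate, and aggregated votes are clipped away
  from 0/1 by `1/(2·n_estimators)` (Laplace-style floor).  Without both,
  a single confidently wrong out-of-fold vote contributes a log-penalty
  that can dominate a class's entire LR sum and push single-variable
  forest models to negative rLR, stalling effect-size selection at step
  one.
* **Logistic fits** use unpenalized maximum likelihood (L-BFGS, `tol =
  1e-8`, 100 iterations).  Non-convergence and (quasi-)separation set
  `converged_` / `separation_` flags instead of raising: on the strongly
  separated high-power scenario saturated probabilities are the correct
  limiting behavior under clipping.

## Significance testing

For maximum-likelihood models, `LR` is tested one-sided against χ²ₖ, `k`
being the number of added variables (the intercept is never counted).
Non-positive statistics return p = 1: the framework tests *improvement*,
and a negative LR under cross-validation signals overfitting, not
significance.  The class components are modelled under H0 as the linear
shares `LR_c ~ w_c·χ²ₖ` with `w_c = maxLR_c/maxLR`, i.e. gamma with shape
`k/2` and scale `2·w_c` — the unique linear transformation of LR
consistent with the weighted recombination identity.  `w_c = 1` recovers
the overall test exactly.  This gamma construction is a documented
modelling assumption of the package.  Non-parametric models get no
p-values at all (absent, not false), and the plot renders their class
lines as absent rather than dashed.

## Cross-validation and selection

All reported metrics are computed on **pooled out-of-fold predictions**
under a single stratified 10-fold plan shared by every model in a
comparison.  Pooling (rather than averaging per-fold metrics) is the
package's choice: per-fold AUC-PR with ~10 events per fold is too unstable
to average.  The null reference inside CV is each training fold's
prevalence — a genuinely fitted model, no leakage.  Fold assignment
depends only on (labels, fold count, seed).

The stepwise selector ranks candidates by one of four criteria and gates
entry/removal by one of two schemes:

* **p-value scheme** (parametric models): entry requires p < 0.05 in the
  test matched to the criterion — the overall χ² test for the `auc` and
  `rlr_overall` criteria's likelihood statistic, the class gamma test for
  `rlr_event` / `rlr_nonevent`, and the one-sided DeLong test for the
  difference of correlated out-of-fold AUCs for the `auc` criterion, which
  is the classical test for "traditional AUC maximization".  The test
  statistic is formed from the pooled out-of-fold predictions of the
  candidate vs. the current model, which makes the gate conservative for
  noise variables (their out-of-fold LR is negative in expectation).
  Entered variables must also strictly improve the criterion.  Removal
  repeatedly drops the variable with the largest drop-one p ≥ 0.10.
* **effect-size scheme** (any model, no removal): the best candidate
  enters while its relative gain `(crit_new − crit_old)/max(|crit_old|,
  0.01)` is at least `min_gain = 0.03` (3 %), criteria evaluated in
  absolute (vs-null) terms.  The 0.01 floor guards the division when
  selection starts from the empty model at rLR = 0.

Ties in the criterion are broken lexicographically by variable name;
re-entry of removed variables is permitted, with an oscillation guard
stopping the run when a variable set repeats.  Per step the trace records
the full coefficient sets in both contexts — against the null model
(absolute) and against the immediate predecessor (incremental) — which is
exactly the data behind per-step U-smile panels.

## The synthetic scenarios

The generator emulates a tabular risk-modelling setting: 1000 samples, 10
features, class-conditionally Gaussian informative features (non-event
N(0,1), event N(δⱼ,1)), redundant features that are random unit-norm
linear combinations of the informative block plus N(0, 0.1²) jitter, and
independent N(0,1) noise features.  Five named scenarios span a power
gradient (2/5/8 informative features with 10 %/5 %/0 % label noise), a
90/10 imbalanced variant, and an asymmetric variant whose V1 is replaced
by non-event N(1, 4) / event N(0, 1) — informative mainly through its
variance, and deliberately replaced *after* the redundant columns are
formed so its signal is carried by V1 alone.

Design choices, fixed once:

* **Label noise** re-draws the labels of the selected fraction from
  Bernoulli(event prior) after feature generation.  This injects
  irreducible error at the stated rate while preserving the class prior —
  important at 90/10, where flipping labels uniformly would contaminate
  the minority class with ~30 % feature-contradicting observations and cap
  the achievable AUC near 0.68, far below what the scenario is meant to
  represent.
* **Effect sizes** decline linearly across the informative features,
  1.4 → 1.0 by default, calibrated once so that the imbalanced scenario's
  selected logistic models land near out-of-fold AUC-PR ≈ 0.80 and a
  V1-only model near rLR₁ ≈ 0.26; the high-power scenario uses its own
  ladder (4.5 → 2.5), sized so every headline metric is ≈ 1.0, which is
  what defines that scenario.  Labels are drawn i.i.d. with the event
  prior, so realized imbalance varies slightly per seed.

What the generator does **not** emulate: feature correlation beyond the
redundant constructions, non-Gaussian or heavy-tailed predictors,
miscalibration of the data-generating probabilities, and covariate shift.
Passing tests therefore demonstrate the machinery's correctness and the
method's comparative behavior under clean Gaussian signal, not performance
claims about real clinical data.

## Problem sizes used by the test and acceptance runs

Structural identities are checked on 1000 random prediction sets; type-I
calibration on 1000 replicates at n = 500; scenario reproductions average
10–20 generator seeds at n = 1000 with 10-fold CV; the asymmetric-scenario
majority property uses 50 seeds; forest selection runs use 100 trees in
the acceptance script (the model default is 500) with
`min_samples_leaf = 10` throughout.

## Known limitations

* At 90/10 imbalance the generator produces `rLR₀ < rLR₁` for logistic
  models (≈ 0.46 vs ≈ 0.62 on the imbalanced scenario): the null already
  predicts non-events well (per-observation ceiling `−2 ln 0.9 ≈ 0.21`),
  and typical non-event improvements realize a smaller share of that
  ceiling than event improvements do of theirs.  This asymmetry is
  structural (it persists at zero label noise), so near-equal class
  coefficients under severe imbalance should not be expected from this
  data-generating process.
* The DeLong-gated AUC variant stops entering variables once out-of-fold
  AUC saturates, even though likelihood continues to improve; on the
  near-perfect high-power scenario its final rLR plateaus around 0.95
  while the rLR-gated variants reach ≈ 1.  This is inherent to gating on
  a rank statistic.
* The χ²/gamma reference laws are asymptotic in-sample laws applied to
  out-of-fold statistics during selection; this direction of error is
  conservative (overfit penalties shrink the statistic), which is the safe
  side for variable entry but means entry p-values should not be reported
  as calibrated test results.
* Only binary outcomes are supported; there is no multi-class extension,
  no between-class test on the plot's central line, and no probability
  recalibration step.
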