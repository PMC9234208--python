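# Methods

## The normal cloud model

A qualitative concept over a continuous universe (here, a mental-health
index scale roughly spanning 18–36 points) is represented by three digital
features: the expectation **Ex** (universe units), the entropy **En ≥ 0**
(same units; the concept's spread) and the hyper-entropy **He ≥ 0** (the
spread of the spread — second-order uncertainty that makes the cloud's
membership itself random). A *cloud drop* (x, u) is one stochastic
realisation: a universe value and its certainty degree in (0, 1].

### Forward generator (1D)

Per drop: x ~ N(Ex, En); En′ ~ N(En, He); u = exp(−(x − Ex)²/(2 En′²)).
Conventions and edge cases:

* **En enters as a standard deviation** (not a variance) in every draw;
  this is the reading consistent with the Gaussian membership kernel, where
  En′ plays the role of a standard deviation.
* The position draw uses En, not the per-drop En′; consequently the
  theoretical variance of x is En², which lies within half a percent of
  En² + He² at the default parameters. Moment-recovery checks use the
  10 % tolerance that covers both conventions.
* En′ may be drawn **negative** when He > 0; the kernel squares it, so u
  depends only on |En′| and the draw is used as-is. A draw of exactly zero
  is redrawn (64 retries; unreachable in practice for a continuous draw).
* The degenerate concept En = He = 0 is defined as the deterministic drop
  (Ex, 1), the kernel's limit. En = 0 with He > 0 is rejected: the En′
  draw would straddle zero with indeterminate sign.

### Forward generator (2D)

Six features (Ex, Enx, Hx, Ey, Eny, Hy). The axes are independent
(no correlation parameter exists in the model, so the bivariate draw has
diagonal covariance); per-axis spreads Enxi ~ N(Enx, Hx), Enyi ~ N(Eny, Hy)
are drawn independently, and
Ui = exp(−½[(Xi−Ex)²/Enxi² + (Yi−Ey)²/Enyi²]). Clouds beyond two
dimensions are out of scope.

### Backward (reverse) generator

Given drops (xᵢ, uᵢ), i = 1..n (n ≥ 5):

1. **Ex̂** — nonlinear least squares of u against the two-parameter
   expectation curve y = exp(−(x − Ex)²/(2 En²)), initialised at the
   u-weighted mean of x and the sample standard deviation of x. Only Ex̂
   is kept; the curve-fit En is discarded so that the per-drop backout
   below stays the authoritative entropy estimator.
2. Drops with u > 0.999 are removed (they sit on the flat top of the
   curve, where −2 ln u ≈ 0 makes the backout numerically indeterminate),
   leaving m ≥ 5 drops; the filter is idempotent.
3. En′ᵢ = |xᵢ − Ex̂| / √(−2 ln uᵢ). The absolute value is required for a
   real result; u ≤ 0.999 guarantees ln u < 0 strictly.
4. Ên = mean(En′ᵢ); Ĥe = sample standard deviation of the En′ᵢ (m − 1
   divisor, no further bias correction).

Reported uncertainties: se(Ex̂) from the curve-fit covariance,
se(Ên) = Ĥe/√m. For drops produced by the forward generator,
En′ᵢ = |En′| of the generating draw, so the round trip recovers
(Ex, En, He) with errors shrinking as 1/√n; with He = 0 and noiseless
curve points the recovery is exact to numerical precision. Alternative
backward estimators from the wider cloud-model literature (pure
moment-based, multi-step) are deliberately not implemented.

### Conditional-cloud reasoning

A rule couples an antecedent cloud C_A (index state) with a consequent
cloud C_B (problem trend, typically over [0, 1]):

* **Activation** (X-conditional): En′A ~ N(EnA, HeA);
  u = exp(−(x − ExA)²/(2 En′A²)).
* **Emission** (Y-conditional): En′B ~ N(EnB, HeB);
  b = ExB − En′B·√(−2 ln u) on the *rising* edge (x < ExA),
  b = ExB + En′B·√(−2 ln u) on the *falling* edge. The tie x = ExA gives
  u = 1 and b = ExB on either branch; it is classified as falling for
  determinism. The emission reuses the activation's u unchanged — the
  uncertainty-transmission contract — and the En′B draw is used with its
  sign (a negative draw would mirror the edge, but at the default
  parameters its probability is ~Φ(−10)).

With all hyper-entropies zero the chain is deterministic and factors in
closed form: √(−2 ln u) = |x − ExA|/EnA, so b = ExB ± EnB·|x − ExA|/EnA.
This closed form is the oracle for every stochastic test.

**Prediction pipeline.** `predict_mental_health` estimates C_A from
historical index drops and C_B from trend drops via the reverse generator
(or accepts a rule directly), then draws `n_drops` single-rule inferences
per current index and reports their arithmetic mean and standard
deviation. The mean is the aggregator because no other choice is
motivated; the full drop set is retained in the report for any other
summary. A prediction is emitted once the mean level is positive;
otherwise the batch is redrawn up to `max_iterations` times (default 10)
and then reported as non-converged — the emit-until-positive loop is
bounded by design, never infinite.

**Multi-rule reasoning** (`multi_rule_infer`) activates all rules and
emits through the one with maximal certainty. This maximum-activation
choice is an extension provided for convenience and documented as such;
only single-rule reasoning is part of the core model.

## Questionnaire scoring

Nine-item depression and seven-item anxiety screeners, items scored 0–3,
totals ≤ 27 and ≤ 21. A respondent screens positive when the total is
**strictly greater than 5**; severity bands take the cutoffs as minima —
depression: none [0,5), mild [5,10), moderate [10,15), severe [15,20),
extreme severe [20,27]; anxiety: none [0,5), mild [5,10), moderate
[10,15), severe [15,21]. The two rules come from different sentences of
the screening convention and are deliberately not reconciled: a total of
exactly 5 is "mild" but unflagged. Extreme severe is unreachable on the
anxiety scale.

Ratio memberships grade a value against a positive reference X (the
worst-affected group's mean, configurable): u = min(value/X, 1) — in
[0, 1], non-decreasing, saturating at the reference. Mapping questionnaire
totals onto the continuous index universe is left to a configurable affine
map (`index_from_total`, identity by default); the synthetic module
generates indices directly, so nothing downstream depends on this map.

## Risk utility

Severity S(w) = κ·(e^{γw} − 1) with κ = 0.576 and γ = 1 by default;
S′ > 0 and S″ > 0, so severity grows convexly with the disorder level w.
κ has no independent calibration and is kept as named configuration —
never hard-coded at call sites — and all rank orders are invariant to it
(and to γ when levels are equal). Risk is R = P·S(w), probability times
severity, and `rank_problems` sorts descending with ties broken
alphabetically. The symbol P here is a probability in [0, 1]; it is a
different quantity from the maximal mental-health level used as a
membership reference, and the two are kept in distinct types. The bundled
eight-row problem table (probability and mean index per problem domain)
ships as CSV package data.

## Synthetic cohorts

The generator emulates the study conditions: by default 600 respondents,
indices drawn from the cloud C(22.4, 5.043, 0.325), a 0.4
screening-positive fraction, and a demographic mix typical of a community
epidemic-prevention workforce (six fields: gender, age band, marriage,
education, occupation, working hours).

* **Indices** come straight from the forward generator, so ground truth is
  known exactly and the backward round trip is testable.
* **Items**: each respondent carries a latent severity s ∈ [0, 1]; every
  item is Binomial(3, s), making the item mean linear in s and the total
  Binomial(3·n_items, s). A Bernoulli draw with the target probability
  decides the screening-positive type; s comes from Beta(6, 6) (positive)
  or Beta(2, 28) (negative), and a bounded redraw (1000 attempts) keeps
  the realised total on the matching side of the cutoff, so the expected
  flagged fraction equals the target exactly. A zero target yields totals
  ≤ 5 with certainty.

This emulates marginal structure only. Real survey items are correlated
beyond a single latent factor, severities are not Beta-distributed, and
indices and responses are generated independently by default (an optional
affine coupling via `index_from_total` is available). Passing tests
therefore demonstrate the estimators' correctness under the model's own
assumptions, not psychometric validity on real cohorts.

## Numerical choices and problem sizes

* One seeded `numpy.random.Generator` is threaded explicitly through every
  stochastic operation; no global RNG state, so identical seed + call
  sequence gives bit-identical output.
* Default problem sizes: 600 drops per cloud and per prediction (enough to
  pin the mean output to a few per-mille), 10⁴ drops for moment checks,
  5000 for round-trip checks, 20 replicates for the headline-accuracy
  experiment; all chosen as the smallest sizes at which Monte-Carlo error
  is comfortably below the tolerances being checked.
* Fixed-seed stochastic tests assert 3–4σ sampling bounds at frozen seeds;
  deterministic reductions (He = 0) are asserted at machine precision.

## Known limitations

* The reasoning layer's headline experiment measures internal consistency
  (generate → estimate → predict against known ground truth); no claim is
  made about diagnostic accuracy on real workers, and clinical validation
  of the screeners is out of scope.
* Under the default concepts the chain at index 25.6 yields u ≈ 0.82 and
  b ≈ 0.53, and these closed forms are the only oracles used; reported
  field observations of substantially higher problem probabilities at
  that index (≈ 0.93) are not derivable from the generators and are
  treated as observational, not as calibration targets.
* Logistic-regression analysis of demographic correlates is routine
  statistics and intentionally omitted; `cohort_summary` provides the
  descriptive cross-tabulation only.
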