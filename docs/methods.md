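# Methods

This note documents the statistical model behind `lepmem`, the synthetic
generator it is tested against, and the numerical and design choices made
where more than one reasonable convention exists.

## The experimental design being modelled

A pool of participants completes two blocks on the same set of target images
(29 aposematic, AP, and 29 non-aposematic, nonAP, Lepidoptera specimens):

1. **Metamemory block.** Each target is viewed once and rated on a 10-point
   scale for how memorable it looks. Ratings are normalized to
   [0, 1] by `(r − 1)/9`, so the scale's verbal anchors land exactly on the
   endpoints.
2. **Recognition block.** Targets are mixed with never-seen lures (AP-only,
   an asymmetry of the available stimulus set, which is why false-alarm
   correction is out of scope) and with repeats of a task-irrelevant
   vigilance image. Each image receives an old/new judgement. A target
   judged "old" is a *hit*; the per-image hit rate is `HR_i = H_i / N_i`.

Participants who call the vigilance image "new" one or more times are
excluded with all their trials (inattention screen). In the reference design,
57 are recruited, 7 fail, and the 50 retained participants × 57 analysed
targets (one AP target is dropped) give 2,850 analysable trials per block.

## Mixed-effects models

Trial-level analyses use mixed models with by-participant random intercepts
and slopes for image class (treatment-coded, nonAP reference, so the class
coefficient is the AP − nonAP difference):

* `rating ~ class + (class | participant)` — Gaussian LMM, fitted by REML
  through statsmodels `MixedLM` (BFGS, with a Powell retry on
  non-convergence; the retry agrees with the primary optimizer to ~1e-4).
* `recognition ~ class + (class | participant)` — binomial-logit GLMM,
  fitted by Laplace-approximated maximum likelihood in `lepmem.glmm`.
  No installed Python package fits frequentist GLMMs with correlated random
  slopes, so this fitter is part of the package; it reproduces
  `lme4::glmer`'s Laplace fit to three–four decimals on fixed effects,
  standard errors, variance components and log-likelihood (frozen-oracle
  test in `tests/test_glmm.py`).

The GLMM parameterizes the random-effect covariance through its Cholesky
factor with the diagonal bounded at zero, so zero-variance (singular) fits
are well-defined boundary solutions rather than failures. Both fitters
report singular fits with an explanatory note and fall back automatically
(drop the intercept–slope correlation, then the slope) only when a structure
yields no usable estimates. Standard errors are conditional on the estimated
variance parameters, the usual mixed-model convention.

Model comparison uses AIC computed from maximum-likelihood (not REML) fits,
counting fixed effects, variance parameters and (for the LMM) the residual
variance. Variance explained follows the Nakagawa decomposition:
`R²_marginal = σ²_f / (σ²_f + σ²_r + σ²_e)` and
`R²_conditional = (σ²_f + σ²_r) / (σ²_f + σ²_r + σ²_e)`, with `σ²_f` the
variance of the fixed-effect predictions over the design, `σ²_r` the mean of
`z_i' Σ z_i` over rows, and `σ²_e` the residual variance — π²/3 on the latent
scale for the logit family.

## Metamemory–recognition comparison

Per-image mean normalized rating and hit rate are compared by Spearman rank
correlation (average ranks for ties), overall and per class. The discrepancy
analysis ranks images by `mean_rating − hit_rate`: the largest positive and
negative differences are the two "unexpected" categories; among the
best-matching images, those with both measures above their own 60th
percentile are "memorable-expected", both below the 40th
"forgettable-expected". Two conventions are ours where the procedure leaves
them open: percentiles use linear interpolation, and the "best-matching"
pool is the lowest quintile of |difference|. Ranking ties break by image id
for reproducibility. Quadrant labels are invariant under any common affine
rescaling of both measures (property-tested).

## Consistency analysis

The participant pool is split into random disjoint halves *j* and *k*
(1000 splits by default; odd pools put the extra participant in *k*).

* **Split-half reliability**: Spearman correlation of the two half-pool
  per-image hit-rate vectors, corrected with Spearman-Brown `2r/(1+r)`,
  averaged over splits, with percentile-bootstrap 95% CIs over splits.
  Per-class values reuse the same splits as the overall value. Splits where
  a scope's vector is constant are recorded as missing and excluded with a
  logged count.
* **Δρ permutation test**: the AP − nonAP reliability difference is compared
  with a null built by permuting class labels across images (class sizes
  preserved, splits held fixed), 1000 permutations. The p-value is the
  proportion of shuffled Δρ ≥ observed (one-sided, matching the directional
  question; a two-sided flag exists) and is floored at `1/n_permutations`,
  so "p = 0.001" is the smallest reportable value at 1000 permutations.
  Under label exchangeability these p-values are uniform (calibration test).
* **Cumulative hit-rate curves**: per split and scope, images are sorted by
  group-j hit rate (descending, ties by image id); the curve at rank n is
  the mean hit rate of the top-n images — for group j, for group k under
  j's ordering, and for a shuffled baseline in which the image ↔ hit-rate
  association within group k is randomly permuted. Ranks run from top-2 to
  top-M; at rank M all three curves equal the scope mean, so the last-rank
  difference is exactly zero and its p-value 1.
* **Per-rank inference**: mean per-split differences (j−k, k−shuffled, and
  the between-class k−shuffled excess, with the surplus nonAP rank dropped
  so the rank grids align) are tested with sign-flip permutation tests
  (1000 flips, one flip matrix shared across the ranks of a family) and
  Bonferroni-corrected within each rank family; bootstrap CIs accompany the
  means.

**A calibration caveat worth knowing.** The sign-flip test is exact when the
per-split difference series is sign-symmetric, and the familywise error is
controlled under that null (verified by simulation). It is *not* calibrated
against dataset-level sampling noise: the 1000 splits are resamples of one
finite dataset, so their differences share a data-conditional component
(chance image effects appear in both halves), and with many splits the test
will flag that component reliably. Simulations with i.i.d. coin-flip
matrices show near-certain rejections at some rank. The per-rank p-values
should therefore be read as describing the observed dataset's internal
consistency structure, not as inference about a population of datasets. The
Δρ permutation test does not share this issue — its null (label
exchangeability across images) is the relevant one and is well calibrated.

The same conditional effect means a single null dataset's split-half
reliability is not tightly centred on zero (across-dataset SD ≈ 0.25 at
40 × 30); only its expectation over datasets vanishes. The reliability tests
average over fresh matrices accordingly.

## Synthetic generator

The generator produces trial tables with the covariance structure the
analysis assumes, so parameter recovery is the package's acceptance surface.

* Image *i* of class *c* has true recognition log-odds
  `logit(p_i) ~ N(class_mean_logit_c, class_image_sd_c)`. The class SDs
  default to (1.2, 0.3) for (AP, nonAP): the larger AP between-image spread
  is what produces higher AP split-half reliability downstream. The
  logit-normal family is our modelling choice — it matches the GLMM the
  pipeline fits; no distributional family is implied by the design itself.
* Image *i* also carries a latent apparent-memorability `m_i` on the rating
  scale, correlated with `logit(p_i)` at `rating_memory_coupling`
  (default 0.1 — near-dissociation) and shifted by `rating_class_shift`
  (default 0.16) for AP images.
* Participants have Gaussian intercept/slope offsets on the log-odds scale
  (defaults 0.6 / 0.3) and on the rating scale (defaults 0.16 / 0.12,
  matching the magnitude of individual differences the models report).
* Ratings are built as `m_i` + participant offsets + trial noise
  (SD 0.145), discretized onto the integer 1–10 scale and normalized
  downstream, mirroring the real data path. Because clipping to a bounded
  scale compresses means, the latent class means are calibrated (closed-form
  expectation of the discretized scale, inverted by root finding) so the
  *observed-scale* class means equal `rating_base` and `rating_base +
  rating_class_shift` exactly; without this the configured 0.16 shift would
  be attenuated to ≈ 0.151.
* The recognition block includes AP-only lures (false alarms generated but
  not analysed) and 5 vigilance repeats; flagged participants answer "new"
  to at least one repeat. By default exactly 7 of 57 participants are
  flagged (the reference design); a Bernoulli failure probability is
  available instead.
* One global seed drives everything; sub-streams are spawned in the fixed
  order images → participants → trials, so runs are bit-reproducible.

What the generator does **not** emulate: response bias and confidence
dynamics, reaction times, serial-position or fatigue effects, image-level
covariate structure (size/pattern statistics are carried as optional columns
but not generated with effects), and any dependence between a participant's
rating and recognition noise beyond the shared class structure. Passing
recovery tests therefore show that the estimators are correct for data of
the assumed structure — not that real data satisfy that structure.

## Problem sizes used in the test suite

Type-I calibration runs 200 simulated datasets per model at 30 participants
× 58 images; parameter recovery runs 200 datasets at the full 50 × 58 design
(tolerances ±0.01 on the 0.16 rating shift, ±0.1 on a 1.0 log-odds shift);
the consistency recovery check uses 50 datasets with 100 splits and 199
permutations each. Resampling-calibration checks (KS uniformity,
sign-flip familywise error) use reduced split/permutation counts chosen so
the p-value resolution is finer than the thresholds being checked.

## Known limitations

* Hit rates are not false-alarm-corrected (lures exist for one class only).
* The per-rank sign-flip p-values are conditional on the dataset (above).
* The GLMM uses the Laplace approximation; with very small clusters or rare
  outcomes adaptive quadrature would be more accurate. Cluster sizes here
  (≈ 58 trials per participant) are comfortable for Laplace.
* The bounded rating scale makes trial-level Gaussian residuals an
  approximation; the LMM is nevertheless the estimator under study, and the
  generator reproduces its assumptions on the latent scale.
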