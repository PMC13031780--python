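# lepmem

Metamemory, recognition and cross-observer memorability analysis for
two-class image-memory experiments — built around studies asking whether
aposematic (AP, warning-signal) Lepidoptera species are *judged* more
memorable, *are* better recognised, and are more *consistently* remembered
across observers than non-aposematic (nonAP) species.

The package is for behavioural researchers who have (or want to simulate)
long-format trial tables from a two-block design — a metamemory rating block
(1–10 "how memorable does this look?") followed by an old/new recognition
block with targets, lures and vigilance checks — and who want the full
analysis pipeline as tested, reusable code rather than a one-off script.

## What it computes

**Quality control.** Participants answering "new" to any repeat of the
vigilance image are excluded with all their trials; ratings are normalized
to [0, 1] by (r − 1)/9; per-image scores are aggregated as hit rates
HR⁽ⁱ⁾ = H⁽ⁱ⁾/N⁽ⁱ⁾ and mean ratings.

**Mixed-effects models.** Trial-level models with by-participant random
intercepts and slopes, class treatment-coded so β is the AP − nonAP
difference:

    rating      ~ class + (class | participant)     (Gaussian LMM, REML)
    recognition ~ class + (class | participant)     (logistic GLMM, Laplace ML)

with AIC model comparison and Nakagawa marginal/conditional R²
(R²m = σ²f / (σ²f + σ²r + σ²e); the logit family uses σ²e = π²/3). The
Laplace GLMM is implemented in-package and agrees with `lme4::glmer` to 3–4
decimals (frozen-oracle test).

**Metamemory–recognition comparison.** Spearman correlations between mean
rating and hit rate (overall and per class) and the
"think memorable / is memorable" quadrant analysis: images ranked by
rating − hit-rate difference, extremes labelled as mismatches, best-matching
images classified against 60th/40th percentile thresholds.

**Memorability consistency.** Split-half reliability over 1000 random
participant splits (Spearman correlation of half-pool hit-rate vectors,
Spearman-Brown corrected: ρ* = 2r/(1+r)), with bootstrap CIs; a
permutation test for the AP − nonAP reliability difference Δρ; cumulative
hit-rate curves (group j ordering vs group k vs a shuffled baseline) with
per-rank sign-flip tests, Bonferroni-corrected.

**Synthetic data.** A generator reproducing the design's statistical
structure — logit-normal per-image recognition probabilities with
class-specific spread, weakly coupled latent memorability ratings,
participant random effects, AP-only lures, vigilance failures — so every
stage is testable without any data download, and parameter recovery can be
verified end to end. See `docs/methods.md` for the model and its
limitations.

## Worked example

```python
import numpy as np
from lepmem import (SimulationConfig, simulate_dataset, apply_vigilance_exclusion,
                    normalize_ratings, compute_image_scores, fit_rating_lmm,
                    fit_recognition_glmm, correlate_rating_hit, make_matrix,
                    split_half_reliability, permutation_test_delta_rho)

ds = simulate_dataset(SimulationConfig(), seed=1)      # 57 participants, 58 targets
trials, report = apply_vigilance_exclusion(ds.trials)
trials = normalize_ratings(trials)
trials = trials[trials.image_id != "AP_01"]            # drop one AP target

print(fit_rating_lmm(trials, ds.images).summary())
print(fit_recognition_glmm(trials, ds.images).summary())

matrix, pids, iids = make_matrix(trials)
classes = ds.images.set_index("image_id").reindex(iids)["lepidoptera_class"].to_numpy()
rng = np.random.default_rng(1)
its, rel = split_half_reliability(matrix, classes, iids, pids, rng=rng)
delta, p = permutation_test_delta_rho(matrix, classes, rng=rng, iterations=its)
```

prints (values from this exact seed):

```
rating ~ class + (class | participant)
  family: gaussian   n_obs: 2850   groups: 50
  class effect (AP - nonAP): beta = 0.1586, SE = 0.0176, t = 9.00, p = 2.324e-19
  random effects: intercept SD = 0.1140, slope SD = 0.1160, corr = 0.261
  AIC = -1679.6   R2_marginal = 0.1069   R2_conditional = 0.4983
recognition ~ class + (class | participant)
  family: binomial-logit   n_obs: 2850   groups: 50
  class effect (AP - nonAP): beta = -0.0963, SE = 0.0791, z = -1.22, p = 0.2239
  random effects: intercept SD = 0.4340, slope SD = 0.1082, corr = -1.000
  AIC = 3814.5   R2_marginal = 0.0007   R2_conditional = 0.0437
```

with split-half reliabilities ρ = 0.84 (all), 0.93 (AP), 0.49 (nonAP) and
Δρ = 0.44, permutation p = 0.001. Read: simulated observers *rate* AP
species ≈ 0.16 units more memorable (a large, reliable effect explaining
~11% of rating variance) yet *recognise* them no better than nonAP species —
while AP hit rates are far more consistent across observers, the signature
of image-intrinsic memorability.

## Command line

```bash
lepmem simulate --config run.yaml --out data/
lepmem analyse  --trials data/trials.csv --images data/images.csv \
                --config run.yaml --out results/
lepmem report   --in results/ --out report.md
```

`simulate` writes `trials.csv`, `images.csv` and the latent ground truth;
`analyse` writes a bundle of JSON/CSV results (every file embeds the seed
and config hash; reruns are byte-identical); `report` renders a markdown
summary. CLI flags override config-file values. Exit codes: 0 ok, 1 usage
error, 2 data error.

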