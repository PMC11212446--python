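# Methods

## Problem setting

`noisytab` targets binary classification of tabular clinical data — lab
tests and vital signs for emergency presentations — when the *training
labels* are unreliable in a class-conditional way. The motivating regime is
diagnostic-test error: a reference test with imperfect sensitivity produces
many false-negative labels among true cases, while near-perfect specificity
keeps false positives rare. Deep networks trained with plain cross-entropy
can memorize such wrong labels and lose discrimination on clean test data.
The package implements three regularizers, originally developed for noisy
image labels, adapted to tabular data:

* **Label smoothing** — targets become `1 − ε` on the assigned class and
  `ε/(C−1)` elsewhere, discouraging saturated (memorized) predictions.
* **Mix-up** — training on convex combinations
  `x_mix = λx₁ + (1−λ)x₂`, `y_mix = λy₁ + (1−λ)y₂` with
  `λ ~ Beta(α, α)` drawn once per batch, applied with a per-batch
  probability `p_apply`.
* **Neighbour Consistency Regularization (NCR)** — for each sample *i* in a
  mini-batch of size *m*, with post-ReLU latent representation `v_i` and
  logit `z_i`, the penalty

      L_NCR = (1/m) Σ_i D( σ(z_i) ‖ Σ_{j ∈ NN_k(v_i)} w_ij σ(z_j) ),
      w_ij = s_ij / Σ_{l ∈ NN_k(v_i)} s_il,   s_ij = cos(v_i, v_j)

  where `NN_k` are the k most cosine-similar batch members (self-similarity
  zeroed), and `D` is a divergence between two-class distributions
  `(1−p, p)`. Samples that look alike are pushed to be classified alike,
  regardless of their possibly-wrong labels. The total objective is
  `L_total = L_CE + α·L_NCR`, with the NCR term disabled during a warm-up
  period of initial epochs.

## Model and optimization

The classifier is a fully connected ReLU network with a single sigmoid
output unit, trained with Adam. Because no autodiff framework is assumed,
the package ships its own small reverse-mode tensor engine
(`noisytab.autodiff`, float64, scalar-root backward); gradients of the NCR
term flow into both the logits and the latent representation (and from
there into all earlier layers), which unit tests verify against central
finite differences to 1e-4 relative error. The discrete top-k neighbour
selection is treated as piecewise constant, the standard practice for
ranking-based losses. A gradient-boosted tree baseline (XGBoost adapter)
provides a non-neural reference scorer.

## Synthetic cohort generator

Real triage cohorts of this kind are access-restricted, so experiments run
on a generator that emulates their statistical shape. Each sample draws a
standard-normal shared factor `g` and independent noise `e_j`:

    x_j = μ_j(y) + sqrt(ρ)·g + sqrt(1−ρ)·e_j

giving unit-variance features with uniform pairwise correlation `ρ` and a
positive-class mean shift of `separation` standard deviations in every
feature. Entries are masked missing completely at random. Defaults (the
study conditions used by tests and the acceptance script):

| parameter    | default | rationale |
|--------------|---------|-----------|
| n_samples    | 6,000   | desk-scale stand-in for a single-hospital cohort |
| n_features   | 20      | order of a routine labs + vitals panel |
| prevalence   | 0.05    | strong class imbalance of pandemic-era triage data |
| separation   | 1.0     | with ρ=0.3 gives a Bayes-optimal AUROC ≈ 0.89, matching the high-0.8s discrimination typical of such models |
| correlation  | 0.3     | physiological measurements are moderately co-correlated |
| missing_rate | 0.05    | routine panels are mostly, not fully, observed |

The equal-covariance Gaussian model admits a closed-form Bayes discriminant
(`w = Σ⁻¹(μ₁−μ₀)`), used in tests as an oracle ceiling (e.g. separation 0 ⇒
AUROC ≈ 0.5). What the generator does **not** emulate: heavy-tailed and
discrete lab values, informative missingness, temporal/wave structure, and
site shift between cohorts. Passing results therefore demonstrate the
mechanisms (noise injection, regularization, memorization signatures), not
clinical performance on any real population.

Label corruption flips exactly `round(rate · class_count)` labels per class
(round half to even), drawn uniformly under a tagged seed and always
computed from the clean labels, so re-application is idempotent and methods
compared at the same (noise level, seed) see identical corruption. The
default corruption grid is a case false-negative rate in
{0, 0.1, 0.2, 0.3, 0.4} with a fixed 0.5% control false-positive rate.

## Preprocessing and evaluation

Median imputation and z-scoring are fitted on the training split only
(medians over observed entries; moments after imputation) and applied
unchanged elsewhere — leakage-free by construction. Evaluation tunes the
decision threshold on the validation split to a target sensitivity of 0.85
(the highest threshold meeting the target, maximizing specificity subject
to it; candidates are midpoints of sorted unique scores plus extremes) and
reports AUROC, AUPRC, sensitivity, specificity, PPV, NPV with 95%
percentile-bootstrap CIs over 1,000 test resamples (single-class resamples
are redrawn and logged). Model comparison uses a paired bootstrap on shared
resample indices; the p-value is the fraction of resamples on which the
candidate fails to beat the comparator, with exact ties counted one half —
identical models give p = 0.5 by construction. Test splits always keep
their clean labels; only training labels are corrupted.

## Training defaults and numerical choices

* Architecture (32, 32), Adam at 1e-3, 60 epochs for the performance sweep;
  NCR uses the last hidden layer's post-ReLU output.
* **batch_size = 256**: at prevalence 0.05 a batch must contain more than
  `k` minority samples for a minority example's neighbourhood to be
  reachable within its own class; 256 × 0.05 ≈ 13 > k = 10. Smaller batches
  make the neighbour mixture majority-dominated and invert the intended
  effect on the minority class.
* NCR defaults: k = 10 neighbours, weight α = 1.0, warm-up 30 epochs,
  KL divergence in the printed direction D(prediction ‖ neighbour mixture);
  JS and mean-absolute-error variants are provided and satisfy the same
  identities. Probabilities are clamped to [1e-7, 1−1e-7] before
  logarithms; negative cosine similarities (impossible for post-ReLU
  features, possible for degenerate inputs) are clamped to 0; a row with no
  positive retained similarity contributes 0; ties in similarity break
  toward the lower batch index.
* Smoothing ε is a fixed tuned constant by default (ε = 0.1); an optional
  per-epoch resampled mode draws ε ~ U[0, ε_max], for treating the
  smoothing amount as stochastic. A per-example ε ~ U[0, 1] would invert
  labels half the time and is deliberately not offered.
* Mix-up: one λ per batch, partner chosen by a seeded permutation of the
  batch against itself, α_beta = 0.4, p_apply = 0.5. In `mixup+ncr` the NCR
  term is computed on the mixed batch.
* Three independent tagged random streams per run (weight init, epoch
  shuffling, mix-up) so corruption, initialization and batching are
  separately reproducible; all generator/corruption/split streams are
  tagged to prevent cross-module seed collisions.
* Cross-validated grid search uses stratified 5-fold splits of the training
  data (plain folds can lose all positives at 5% prevalence) and breaks
  ties toward the earlier grid entry.
* Non-finite losses abort training with the offending epoch/batch rather
  than silently producing NaN models.

## Diagnostics

Two analyses probe the memorization mechanism on the corrupted training
set, where the generator knows which labels were flipped:

* **Similarity strata** — pairwise latent cosine similarities stratified
  into same-class/clean, different-class/clean, same-label/mislabelled and
  different-label/mislabelled pairs (pairs subsampled to 100,000 by
  default). The scalar signature is the clean same-class minus
  different-class mean gap.
* **Confidence traces** — per-epoch mean predicted probability of the
  *assigned* (possibly wrong) label, split by noise flag. Rising confidence
  on mislabelled samples is the memorization signature.

Memorization is a late-training phenomenon: under the 60-epoch sweep
schedule the baseline has not yet diverged from the regularized model, so
the diagnostic runs train 150 epochs by default (the sweep keeps 60). At
40% case noise, over 3 seeds, the cross-entropy baseline ends more
confident in wrong labels than NCR, and NCR's latent class-separation gap
is wider — the two qualitative signatures the diagnostics exist to expose.

## Known limitations

* Neighbour search is batch-local; samples never see neighbours outside
  their mini-batch.
* The generator's Gaussian geometry favours cosine-similarity neighbours;
  mixed-type EHR features would need an embedding before NCR is meaningful.
* Class imbalance is handled only through threshold tuning, not loss
  reweighting.
* Sweep effect sizes at desk scale (n = 6,000) are smaller and noisier than
  what large multi-site cohorts would show; directions, not magnitudes, are
  the supported claims.
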