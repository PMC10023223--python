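# Methods

This note documents the model implemented in `mdmil`, the synthetic data
it is validated on, and the numerical and design choices made where the
design was genuinely open.

## Model

A slide is a bag `F ∈ R^{n×d}` of instance embeddings with one label
`y ∈ {0,…,N−1}`. The forward pass composes:

1. **Deep projection layer (DPL).** `F′ = W2·ReLU(LN(W1 F + b1)) + b2`,
   mapping `d → d′`. Row-wise; recalibrates transferred features so that
   similar tissue forms compact clusters before attention.
2. **Instance probabilities.** `P1 = softmax(cls1(F))` per instance, with
   `cls1` acting on the *raw* features (the upper stream), not on `F′`.
3. **Internal queries.** Per class `i`, `K1 = max(1, ⌊r1 n⌋)`,
   `K2 = max(1, ⌊r2 n⌋)`; confidence factor `cf_i = m̄_i − σ_i` over the
   top-K1 entries of column `i` of `P1`, with σ the population standard
   deviation (divisor K1). The gate `cf_max − β > cf_j ∀ j ≠ max`
   (strict, and vacuously failed when the arg-max is tied) selects at
   most one *reliable* class, which aggregates the mean of the `F′` rows
   of its top-K1 instances; every other class aggregates top-K2. Top-K
   ranks by descending probability, ties by ascending instance index —
   a deterministic rule that makes the module permutation invariant.
4. **Dual-query cross-attention (MDCA).** Pre-layernorms and four linear
   maps produce `Q1` (from IQ), `Q2` (from a trainable variational query
   VQ, initialized N(0, 0.02²)), `K` and `V` (from `F′`); per head,
   logits are scaled by `1/√(d′/m)`, softmaxed per row, and mixed as
   `m′ = α·mt1 + (1−α)·mt2` — a convex combination, so rows remain
   distributions. `m′V` is head-concatenated, projected, and
   residual-added to IQ.
5. **FFN → MHSA → FFN.** Both FFNs are two-layer blocks (expansion 4,
   GELU) with residual then *post*-layernorm; the MHSA is standard
   multi-head self-attention over the N subtype tokens with residual.
6. **Head.** The slide representation is the mean of the N subtype rows;
   a linear layer plus softmax gives `P2`.

### Objective

`L = CE(maxpool(P1), y) + CE(P2, y) + α_loss·L_CL` with `α_loss = 0.5`.
Max-pooling takes the per-class maximum of `P1` over instances and
renormalizes it to a distribution before the log (a global-max variant —
the single best instance supplies its row — is available via
`LossConfig.instance_pooling`). The contrastive term scores the
L2-normalized labeled subtype representation `f` (the row of the MDM
output indexed by the true label, taken after the second FFN and before
averaging — the only per-subtype, label-indexable feature in the
architecture) against a memory of per-class centers:
`L_CL = −log softmax(⟨f, c⟩/τ)[y]`.

### Memory bank

Centers are initialized before the first epoch as the L2-normalized
per-class means of `f` over the training set under the initial model,
and updated after each optimizer step as `c_k ← m·c_k + (1−m)·f`,
**re-normalized to unit length after every update**. Without
re-normalization the inner-product scale drifts as representations grow;
normalizing at init only is not a fixed point of the update. Defaults
`m = 0.999`, `τ = 0.07` follow momentum-contrast conventions.

## Hyperparameters

| name | default | meaning |
|---|---|---|
| `d` | 1024 | instance embedding width (64 in the synthetic regime) |
| `d_prime` | 512 | post-DPL width (64 in the synthetic regime) |
| `heads` | 8 | attention heads; must divide `d_prime` |
| `r1`, `r2` | 0.05, 0.01 | top-K ratios (0.1/0.01 for subtyping data) |
| `beta` | 0 | reliability margin in [−1, 1] |
| `alpha_attn` | 0.5 | IQ-vs-VQ attention mix |
| `alpha_loss` | 0.5 | contrastive weight |
| `tau`, `momentum` | 0.07, 0.999 | contrastive temperature, center momentum |
| lr, wd | 2e-4, 1e-5 | Adam with cosine decay, 30 epochs, one bag/step |

`β` is exposed two ways: the scalar margin applied to `cf_max` (default),
and an optional per-class bias vector subtracted from the confidence
factors before gating, which expresses an asymmetric prior for instance-
imbalanced detection data (give the rare tumor class a head start). Both
readings exist in the literature this design follows; the scalar is the
default because it is the form the gate equation states.

`alpha_attn` likewise has a `gated` mode (`alpha_hi`/`alpha_lo`, defaults
0.7/0.3) that leans on the IQ when a reliable class was found and on the
VQ otherwise; the fixed scalar 0.5 is the default as the testable,
assumption-free reading.

## Model selection

The checkpoint maximizing validation AUC *plus* accuracy is kept
(`selection_metric="auc_acc"`). Pure-AUC selection is available but was
observed to pick one-epoch-old models whose ranking is perfect while the
argmax threshold is still uncalibrated (val AUC 1.00 at accuracy 0.80),
which defeats the point of a selected checkpoint; the sum rewards
ranking and calibration jointly.

## Synthetic data

The generator emulates what makes MIL on slides hard, not histology
itself. Each dataset draws one set of cluster means: background clusters
plus `phenotypes_per_class` clusters per class (tumor heterogeneity).
Means sit on random orthonormal directions scaled so every pair is
exactly `cluster_separation` noise standard deviations apart (Gaussian
placement is the fallback when clusters exceed `d`; exact placement
keeps the nominal separation honest — with Gaussian means some pairs
land at ~2/3 of the nominal distance). Instances are the cluster mean
plus isotropic N(0, noise_std²) noise. A class-k bag of length
`n ~ U{min,max}` contains exactly `⌈prevalence_k·n⌉` critical instances,
phenotype chosen uniformly per instance; `prevalence 0` denotes a
pure-background (normal) class.

Presets (d = 64, bag length 80–120, separation 6, noise 1, 330 bags,
stratified 200/50/80 split):

- `camelyon_like` — detection regime: N = 2, negatives pure background,
  positives 5% critical, 159:111-style imbalance, two phenotypes per
  class.
- `tcga_like` — subtyping regime: N = 3, 80% critical, three phenotypes
  per class, 111:489:284-style imbalance.

What passing on this data shows: the architecture can mine sparse
critical instances, aggregate heterogeneous phenotypes, and concentrate
attention on the planted evidence. What it does not show: robustness to
stain variation, spatial correlation between patches, label noise, or
realistic feature-extractor geometry — real instance embeddings are not
isotropic Gaussian mixtures.

## Numerical choices

- All arithmetic float64; gradients from the in-package reverse-mode
  autodiff, validated against central finite differences (relative error
  ≤ 1e-4 required; observed ~1e-8).
- Softmaxes subtract a detached row max (gradient-neutral) for
  stability; layernorm ε = 1e-5; L2 normalization of representations
  adds 1e-12 to the norm inside the graph, while the plain-array path
  raises on norms < 1e-9 (a degenerate center is an error, not a NaN).
- `K = max(1, ⌊r·n⌋)`: the floor keeps K deterministic, the clamp keeps
  one-instance bags valid.
- Attention-mix boundary cases are exact: α = 1 reproduces the IQ-only
  path bit-for-bit, α = 0 keeps the IQ residual but ignores its
  attention.
- Ties: top-K by ascending index (stable sort); max-pooling gradients
  split among exact ties; a tied confidence arg-max disables the
  reliable branch.
- Training batches are single bags; the run is single-threaded and
  reproducible from the seed. Problem sizes for the shipped benchmarks
  (d = 64, d′ = 64, ~100-instance bags, 30 epochs, 3 seeds) were chosen
  so a full benchmark sweep runs in minutes on one CPU core.

## Preprocessing front end

Non-overlapping square tiles (default 256 px) on the floored grid,
right/bottom remainders dropped (edge handling is unspecified upstream;
dropping keeps every tile full-size). Background filter: a tile is kept
iff its **mean** HSV saturation on the 0–255 scale is ≥ 15 (strict < 15
discards); the mean was chosen over the median for smoothness, and
saturation is computed exactly as `255·(max−min)/max` per pixel so the
boundary case is reproducible in floating point. The feature extractor
is pluggable; the shipped default is a fixed-seed random linear
projection of the downsampled tile, which is deterministic and
dependency-free; production use plugs a truncated pretrained CNN behind
the same interface. Magnification handling is the caller's
responsibility.

## Known limitations

- No spatial/positional information survives aggregation; tasks needing
  tumor-microenvironment context are out of scope.
- The memory bank assumes every class appears in training; few-shot
  classes make centers noisy.
- Multiclass AUC is macro one-vs-rest.
- The CPU implementation targets research-scale bags (10³–10⁴ instances);
  it is O(n·d′²) per bag and step but not vectorized across bags.
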