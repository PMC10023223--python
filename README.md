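# mdmil

Multiplex-detection multiple instance learning (MIL) for whole-slide-image
(WSI) classification, for computational-pathology researchers working with
bags of per-patch feature vectors.

## The problem

A digital slide is gigapixels; only slide-level labels (normal/tumor, or a
cancer subtype) are available, not patch labels. Standard practice tiles the
slide, embeds each tile as a feature vector, and treats a slide as a *bag*
`F ∈ R^{n×d}` of `n` instances with one label. The classifier must find the
*critical instances* that trigger the label — hard when lesions cover a few
percent of the tissue, and harder under **tumor heterogeneity**, where one
subtype presents several distinct phenotypes so no single instance
represents its class.

## The method

Three pieces act on a bag:

- **IQGM (internal query generation).** A classification layer on the raw
  features gives an instance probability matrix `P = softmax(cls1(F))`.
  For each class `i`, a confidence factor
  `cf_i = mean(top-K1 of P[:,i]) − std(top-K1 of P[:,i])` scores how
  confidently and consistently the bag supports that class
  (`K = max(1, ⌊r·n⌋)`, ratios `r1 ≥ r2`). If the arg-max class clears the
  margin test `cf_max − β > cf_j ∀ j ≠ max`, its *internal query* q_rb
  averages the projected features of its top-K1 instances; other classes
  (or all classes, when no class clears the gate) average top-K2. A deep
  projection layer (linear → LayerNorm → ReLU → linear) supplies the
  projected features `F′ ∈ R^{n×d′}`.
- **MDM (multiplex detection).** Dual-query cross-attention:
  `Q1 = LN(IQ)W1`, `Q2 = LN(VQ)W2`, `K = LN(F′)W3`, `V = LN(F′)W4`, where
  VQ is a trainable per-class query shared across the training set. Two
  row-stochastic attention matrices are convexly mixed,
  `m′ = α·mt1 + (1−α)·mt2`, applied to V per head, projected, and
  residual-added to IQ — reducing the instance dimension from `n` to the
  number of subtypes `N`. A post-LN FFN, multi-head self-attention over the
  `N` subtype tokens, a second FFN and a mean over rows yield the slide
  representation and prediction `P2`.
- **Memory-based contrastive loss.** One momentum-updated, L2-normalized
  center per class (`c_k ← m·c_k + (1−m)·f`, re-normalized); each step the
  labeled subtype representation `f` is pulled to its center through
  `L_CL = −log exp(⟨f,c_y⟩/τ) / Σ_j exp(⟨f,c_j⟩/τ)`. The objective is
  `L = CE(maxpool(P1), y) + CE(P2, y) + α·L_CL` with `α = 0.5`.

The network is implemented in NumPy with a small reverse-mode autodiff
engine inside the package (`mdmil.autodiff`); gradients are validated
against central finite differences in the test suite.

Because the real pathology corpora behind this line of work require
multi-hundred-GB downloads and GPU feature extraction, the package ships a
first-class synthetic generator (`mdmil.synthetic`) that plants critical
instances into Gaussian background bags with per-class phenotype clusters,
with presets mirroring the two published regimes: a low-prevalence
detection dataset (~5% critical instances, imbalanced negatives) and a
high-prevalence three-class subtyping dataset (~80%, imbalanced subtypes).

## Worked example

```python
import numpy as np
from mdmil import (MDMILModel, ModelConfig, LossConfig, TrainConfig,
                   camelyon_like, train, evaluate)

dataset, truth = camelyon_like(seed=2)          # 330 bags, 200/50/80 split
config = ModelConfig(d=64, d_prime=64, n_classes=2, heads=8, r1=0.05, r2=0.01)
model = MDMILModel(config, seed=2)
result = train(model, dataset, TrainConfig(epochs=30, seed=2), LossConfig())
report = evaluate(result.model, dataset.subset("test"), n_classes=2)
print(f"test AUC      {report.auc:.4f}")
print(f"test accuracy {report.accuracy:.4f}")

bag = next(b for b in dataset.subset("test") if b.label == 1)
attn = result.model.predict(bag).attn           # N x n mixed attention
critical = bag.instance_labels > 0
print(f"attention on planted tumor instances vs uniform: "
      f"{attn[1, critical].mean() * bag.n_instances:.1f}x")
```

Output (about half a minute on one CPU core):

```
test AUC      0.9923
test accuracy 0.9500
attention on planted tumor instances vs uniform: 4.5x
```

The AUC/accuracy say the trained model separates positive from negative
bags on held-out slides; the last line says the positive subtype's
attention concentrates on the planted critical instances at ~4× the
uniform weight `1/n` — the model finds the lesions it was never told about.

A `mdmil` console script wraps the same pipeline
(`mdmil synth | tile | train | eval | attend`); see `mdmil --help`.

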