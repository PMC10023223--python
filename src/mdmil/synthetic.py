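"""Synthetic MIL bag generator with planted critical instances.

Emulates the structure that makes weakly supervised slide classification
hard: variable bag lengths, a dominant background population, and —
per positive class — several distinct *phenotype* clusters (tumor
heterogeneity), so that no single instance is representative of its
class. Each cluster is an isotropic Gaussian; cluster means are drawn
once per dataset so that the typical distance between any two means is
``cluster_separation`` noise standard deviations.

A bag of class k contains ceil(prevalence_k * n) critical instances,
each drawn from one of class k's phenotype clusters chosen uniformly at
random, and background instances otherwise. ``prevalence`` near 0.05
mimics metastasis-detection data (tiny lesions in mostly normal
tissue); near 0.8 mimics subtyping data where tumor dominates the
slide. A class with prevalence 0 is pure background (the "normal"
class of a detection dataset).

Two presets mirror those regimes, including their class imbalance.
Everything is reproducible from (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .feature_bags import BagDataset, InstanceBag, split_dataset

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_bag",
    "generate_dataset",
    "camelyon_like",
    "tcga_like",
]


@dataclass
class SyntheticSpec:
    n_classes: int = 2
    d: int = 64
    phenotypes_per_class: int = 2
    background_clusters: int = 2
    prevalence: tuple[float, ...] = (0.0, 0.05)  # per class; 0 = background-only class
    bag_length_law: tuple[int, int] = (80, 120)  # uniform integer, inclusive
    class_proportions: tuple[float, ...] = (0.5, 0.5)
    cluster_separation: float = 6.0  # mean pairwise distance, in noise stds
    noise_std: float = 1.0
    n_bags: int = 200
    seed: int = 0

    def __post_init__(self):
        if len(self.prevalence) != self.n_classes:
            raise ValueError("prevalence needs one entry per class")
        if any(not 0.0 <= p <= 1.0 for p in self.prevalence):
            raise ValueError("prevalence entries must lie in [0, 1]")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.bag_length_law[0] < 1 or self.bag_length_law[0] > self.bag_length_law[1]:
            raise ValueError("bag_length_law must be (min >= 1, max >= min)")


@dataclass
class GroundTruth:
    """Cluster geometry and per-bag instance labels backing a dataset."""

    background_means: np.ndarray  # B x d
    phenotype_means: np.ndarray  # N x P x d
    noise_std: float
    instance_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def phenotype_id(self, class_k: int, phenotype: int) -> int:
        """Global instance-label id (0 is reserved for background)."""
        return 1 + class_k * self.phenotype_means.shape[1] + phenotype


def _draw_means(spec: SyntheticSpec, rng: np.random.Generator) -> GroundTruth:
    n_clusters = spec.background_clusters + spec.n_classes * spec.phenotypes_per_class
    if n_clusters <= spec.d:
        # random orthonormal directions scaled so every pair of means is
        # exactly `cluster_separation` noise stds apart
        q, _ = np.linalg.qr(rng.standard_normal((spec.d, n_clusters)))
        means = q.T * (spec.cluster_separation * spec.noise_std / math.sqrt(2.0))
    else:
        # fallback: isotropic Gaussian means matching the separation on average
        s = spec.cluster_separation * spec.noise_std / math.sqrt(2 * spec.d)
        means = rng.standard_normal((n_clusters, spec.d)) * s
    bg = means[: spec.background_clusters]
    ph = means[spec.background_clusters :].reshape(
        spec.n_classes, spec.phenotypes_per_class, spec.d
    )
    return GroundTruth(background_means=bg, phenotype_means=ph, noise_std=spec.noise_std)


def generate_bag(
    spec: SyntheticSpec,
    class_k: int,
    rng: np.random.Generator,
    truth: GroundTruth | None = None,
    bag_id: str = "bag",
) -> InstanceBag:
    """One bag of class `class_k` with exactly ceil(prevalence*n) critical instances."""
    if truth is None:
        truth = _draw_means(spec, np.random.default_rng(spec.seed))
    lo, hi = spec.bag_length_law
    n = int(rng.integers(lo, hi + 1))
    n_crit = math.ceil(spec.prevalence[class_k] * n)
    labels = np.zeros(n, dtype=np.int64)
    feats = np.empty((n, spec.d))
    bg_choice = rng.integers(0, truth.background_means.shape[0], size=n)
    feats[:] = truth.background_means[bg_choice]
    if n_crit > 0:
        pos = rng.choice(n, size=n_crit, replace=False)
        phenos = rng.integers(0, spec.phenotypes_per_class, size=n_crit)
        feats[pos] = truth.phenotype_means[class_k, phenos]
        labels[pos] = [truth.phenotype_id(class_k, p) for p in phenos]
    feats += rng.standard_normal((n, spec.d)) * spec.noise_std
    return InstanceBag(
        features=feats, label=class_k, bag_id=bag_id, instance_labels=labels
    )


def generate_dataset(
    spec: SyntheticSpec,
    ratios: tuple[float, float, float] = (0.6, 0.15, 0.25),
) -> tuple[BagDataset, GroundTruth]:
    """A full stratified-split dataset, reproducible from (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    truth = _draw_means(spec, rng)
    counts = _largest_remainder_counts(spec.n_bags, spec.class_proportions)
    bags = []
    order = np.repeat(np.arange(spec.n_classes), counts)
    rng.shuffle(order)
    for i, k in enumerate(order):
        bag = generate_bag(spec, int(k), rng, truth, bag_id=f"bag_{i:05d}")
        truth.instance_labels[bag.bag_id] = bag.instance_labels
        bags.append(bag)
    ds = BagDataset(bags=bags, n_classes=spec.n_classes)
    ds = split_dataset(ds, ratios, seed=spec.seed)
    return ds, truth


def _largest_remainder_counts(n: int, proportions) -> np.ndarray:
    exact = np.asarray(proportions) * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    return counts


def camelyon_like(seed: int = 0) -> tuple[BagDataset, GroundTruth]:
    """Metastasis-detection regime: two classes, negatives pure background,
    positives with ~5% critical instances, 159:111-style imbalance."""
    spec = SyntheticSpec(
        n_classes=2,
        d=64,
        phenotypes_per_class=2,
        background_clusters=2,
        prevalence=(0.0, 0.05),
        bag_length_law=(80, 120),
        class_proportions=(159 / 270, 111 / 270),
        cluster_separation=6.0,
        noise_std=1.0,
        n_bags=330,
        seed=seed,
    )
    return generate_dataset(spec, ratios=(200 / 330, 50 / 330, 80 / 330))


def tcga_like(seed: int = 0) -> tuple[BagDataset, GroundTruth]:
    """Subtyping regime: three classes, ~80% critical instances per bag,
    three phenotypes per subtype, 111:489:284-style imbalance."""
    spec = SyntheticSpec(
        n_classes=3,
        d=64,
        phenotypes_per_class=3,
        background_clusters=2,
        prevalence=(0.8, 0.8, 0.8),
        bag_length_law=(80, 120),
        class_proportions=(111 / 884, 489 / 884, 284 / 884),
        cluster_separation=6.0,
        noise_std=1.0,
        n_bags=330,
        seed=seed,
    )
    return generate_dataset(spec, ratios=(200 / 330, 50 / 330, 80 / 330))
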