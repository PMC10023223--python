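"""Instance-feature bags: the data model for weakly supervised slide classification.

A *bag* is the set of per-patch feature vectors extracted from one whole
slide image, carrying a single slide-level label. Bags are stored either
in one HDF5 container (a group per bag, so variable bag lengths need no
padding) or as a directory of per-bag CSV matrices with a ``labels.csv``
manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "InstanceBag",
    "BagDataset",
    "BagValidationError",
    "ContainerFormatError",
    "read_bag_container",
    "write_bag_container",
    "split_dataset",
]

SPLITS = ("train", "val", "test")


class BagValidationError(ValueError):
    """A bag or dataset violates its invariants."""


class ContainerFormatError(ValueError):
    """An on-disk container is structurally inconsistent."""


@dataclass
class InstanceBag:
    """One slide's n x d instance-feature matrix plus its slide-level label.

    ``instance_labels`` (0 = background, k >= 1 = phenotype id) exist only
    for synthetic data, where per-instance ground truth is known.
    """

    features: np.ndarray
    label: int
    bag_id: str
    coords: np.ndarray | None = None
    instance_labels: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise BagValidationError(
                f"bag {self.bag_id!r}: features must be a non-empty 2-D matrix"
            )
        if not np.isfinite(self.features).all():
            raise BagValidationError(f"bag {self.bag_id!r}: non-finite feature values")
        n = self.features.shape[0]
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.int64)
            if self.coords.shape != (n, 2):
                raise BagValidationError(f"bag {self.bag_id!r}: coords must be n x 2")
        if self.instance_labels is not None:
            self.instance_labels = np.asarray(self.instance_labels, dtype=np.int64)
            if self.instance_labels.shape != (n,):
                raise BagValidationError(
                    f"bag {self.bag_id!r}: instance_labels must have length n"
                )

    @property
    def n_instances(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


@dataclass
class BagDataset:
    """An ordered collection of bags with a slide-level split assignment."""

    bags: list[InstanceBag]
    n_classes: int
    split_assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_classes < 2:
            raise BagValidationError("n_classes must be >= 2")
        dims = {b.dim for b in self.bags}
        if len(dims) > 1:
            raise ContainerFormatError(f"feature dimension differs across bags: {sorted(dims)}")
        for b in self.bags:
            if not 0 <= b.label < self.n_classes:
                raise BagValidationError(
                    f"bag {b.bag_id!r}: label {b.label} outside [0, {self.n_classes})"
                )
        ids = [b.bag_id for b in self.bags]
        if len(set(ids)) != len(ids):
            raise BagValidationError("duplicate bag_id")

    def subset(self, split: str) -> list[InstanceBag]:
        return [b for b in self.bags if self.split_assignments.get(b.bag_id) == split]

    def __len__(self):
        return len(self.bags)


# ---------------------------------------------------------------------- #
# I/O


def write_bag_container(dataset: BagDataset, path) -> None:
    """Write a dataset to one HDF5 file (``.h5``) or a CSV directory."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        _write_h5(dataset, path)
    else:
        _write_csv_dir(dataset, path)


def read_bag_container(path) -> BagDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        return _read_h5(path)
    return _read_csv_dir(path)


def _write_h5(dataset: BagDataset, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["n_classes"] = dataset.n_classes
        root = f.create_group("bags")
        for bag in dataset.bags:
            g = root.create_group(bag.bag_id)
            g.create_dataset("features", data=bag.features)
            g.attrs["label"] = bag.label
            split = dataset.split_assignments.get(bag.bag_id)
            if split is not None:
                g.attrs["split"] = split
            if bag.coords is not None:
                g.create_dataset("coords", data=bag.coords)
            if bag.instance_labels is not None:
                g.create_dataset("instance_labels", data=bag.instance_labels)


def _read_h5(path: Path) -> BagDataset:
    bags, splits = [], {}
    with h5py.File(path, "r") as f:
        if "bags" not in f or "n_classes" not in f.attrs:
            raise ContainerFormatError(f"{path}: missing /bags group or n_classes attr")
        n_classes = int(f.attrs["n_classes"])
        for bag_id in f["bags"]:
            g = f["bags"][bag_id]
            bag = InstanceBag(
                features=g["features"][...],
                label=int(g.attrs["label"]),
                bag_id=bag_id,
                coords=g["coords"][...] if "coords" in g else None,
                instance_labels=g["instance_labels"][...] if "instance_labels" in g else None,
            )
            bags.append(bag)
            if "split" in g.attrs:
                splits[bag_id] = str(g.attrs["split"])
    return BagDataset(bags=bags, n_classes=n_classes, split_assignments=splits)


def _write_csv_dir(dataset: BagDataset, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bag_id", "label", "split", "n_classes"])
        for bag in dataset.bags:
            w.writerow(
                [
                    bag.bag_id,
                    bag.label,
                    dataset.split_assignments.get(bag.bag_id, ""),
                    dataset.n_classes,
                ]
            )
    for bag in dataset.bags:
        np.savetxt(path / f"{bag.bag_id}.csv", bag.features, delimiter=",")
        if bag.coords is not None:
            np.savetxt(path / f"{bag.bag_id}.coords.csv", bag.coords, delimiter=",", fmt="%d")
        if bag.instance_labels is not None:
            np.savetxt(
                path / f"{bag.bag_id}.ilabels.csv", bag.instance_labels, delimiter=",", fmt="%d"
            )


def _read_csv_dir(path: Path) -> BagDataset:
    manifest = path / "labels.csv"
    if not manifest.exists():
        raise ContainerFormatError(f"{path}: missing labels.csv manifest")
    bags, splits = [], {}
    n_classes = None
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            bag_id = row["bag_id"]
            n_classes = int(row["n_classes"])
            feats = np.loadtxt(path / f"{bag_id}.csv", delimiter=",", ndmin=2)
            cpath = path / f"{bag_id}.coords.csv"
            ipath = path / f"{bag_id}.ilabels.csv"
            bags.append(
                InstanceBag(
                    features=feats,
                    label=int(row["label"]),
                    bag_id=bag_id,
                    coords=np.loadtxt(cpath, delimiter=",", ndmin=2) if cpath.exists() else None,
                    instance_labels=(
                        np.loadtxt(ipath, delimiter=",", ndmin=1) if ipath.exists() else None
                    ),
                )
            )
            if row.get("split"):
                splits[bag_id] = row["split"]
    if n_classes is None:
        raise ContainerFormatError(f"{path}: empty manifest")
    return BagDataset(bags=bags, n_classes=n_classes, split_assignments=splits)


# ---------------------------------------------------------------------- #
# splitting


def split_dataset(
    dataset: BagDataset,
    ratios: tuple[float, float, float],
    seed: int,
) -> BagDataset:
    """Assign bags to train/val/test at the slide level, stratified by class.

    Within each class, counts follow the ratios by largest remainder, so
    each class's split counts differ from the exact proportion by less
    than one bag. Deterministic given ``seed``.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r < 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise BagValidationError(f"ratios must be non-negative and sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, str] = {}
    # running (exact - assigned) per split, so remainder seats balance
    # globally across classes, not just within each class
    deficit = np.zeros(3)
    for k in range(dataset.n_classes):
        idx = [i for i, b in enumerate(dataset.bags) if b.label == k]
        if not idx:
            raise BagValidationError(f"class {k} has no bags")
        n_active = sum(1 for r in ratios if r > 0)
        if len(idx) < n_active:
            raise BagValidationError(
                f"class {k} has {len(idx)} bags, fewer than the {n_active} non-empty splits"
            )
        rng.shuffle(idx)
        counts, deficit = _allocate_counts(len(idx), ratios, deficit)
        start = 0
        for split, c in zip(SPLITS, counts):
            for i in idx[start : start + c]:
                assignments[dataset.bags[i].bag_id] = split
            start += c
    return BagDataset(
        bags=dataset.bags, n_classes=dataset.n_classes, split_assignments=assignments
    )


def _allocate_counts(
    n: int, ratios: tuple[float, ...], deficit: np.ndarray
) -> tuple[list[int], np.ndarray]:
    """Largest-remainder allocation, biased by the cumulative deficit."""
    exact = np.array([n * r for r in ratios])
    counts = np.floor(exact).astype(int)
    # guarantee each non-empty split at least one bag
    for i, r in enumerate(ratios):
        if r > 0 and counts[i] == 0:
            counts[i] = 1
    rem = n - counts.sum()
    if rem < 0:  # the at-least-one guarantee overshot; take back from the largest
        for i in np.argsort(-counts):
            while rem < 0 and counts[i] > 1:
                counts[i] -= 1
                rem += 1
    order = np.argsort(-(deficit + exact - counts))
    for i in order[:rem]:
        counts[i] += 1
    return counts.tolist(), deficit + exact - counts
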