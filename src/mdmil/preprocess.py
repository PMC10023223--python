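"""Slide-to-bag front end: tiling, background filtering, feature extraction.

A slide raster is cut into non-overlapping square tiles (right/bottom
remainders dropped), background tiles are discarded when their mean HSV
saturation falls below a threshold on the 0-255 scale, and each kept
tile is mapped to a feature vector by a pluggable extractor.

The default extractor is a fixed-seed random linear projection of the
downsampled tile, so the pipeline runs deterministically with no
pretrained weights; production use plugs a truncated CNN behind the
same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .feature_bags import InstanceBag

__all__ = [
    "TileGrid",
    "FeatureExtractor",
    "RandomProjectionExtractor",
    "tile_image",
    "saturation_filter",
    "mean_saturation",
    "extract_bag",
    "EmptyBagError",
]

DEFAULT_TILE_SIZE = 256
DEFAULT_SAT_THRESHOLD = 15.0


class EmptyBagError(ValueError):
    """No tile survived the background filter."""


@dataclass
class TileGrid:
    tile_size: int
    coords: list[tuple[int, int]]  # (row, col) top-left pixel offsets
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.coords), dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        assert self.kept_mask.shape == (len(self.coords),)


@dataclass
class FeatureExtractor:
    """A deterministic map from an RGB tile to a d-vector."""

    name: str
    output_dim: int
    transform: Callable[[np.ndarray], np.ndarray]

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        out = np.asarray(self.transform(tile), dtype=np.float64)
        if out.shape != (self.output_dim,) or not np.isfinite(out).all():
            raise ValueError(f"extractor {self.name!r} returned an invalid vector")
        return out


class RandomProjectionExtractor(FeatureExtractor):
    """Fixed-seed random linear projection of the downsampled flattened tile.

    Deterministic by construction: the projection matrix is drawn once
    from `seed` and reused for every tile.
    """

    def __init__(self, output_dim: int = 64, downsample: int = 8, seed: int = 0):
        self.downsample = downsample
        self._proj: np.ndarray | None = None
        self._seed = seed
        super().__init__(
            name=f"randproj{output_dim}", output_dim=output_dim, transform=self._project
        )

    def _project(self, tile: np.ndarray) -> np.ndarray:
        small = tile[:: self.downsample, :: self.downsample].astype(np.float64) / 255.0
        flat = small.reshape(-1)
        if self._proj is None or self._proj.shape[1] != flat.size:
            rng = np.random.default_rng(self._seed)
            self._proj = rng.standard_normal((self.output_dim, flat.size)) / np.sqrt(flat.size)
        return self._proj @ flat


def tile_image(image: np.ndarray, tile_size: int = DEFAULT_TILE_SIZE) -> TileGrid:
    """Non-overlapping tiling; remainders at the right/bottom edges dropped."""
    h, w = image.shape[:2]
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {h}x{w} smaller than one {tile_size}px tile")
    coords = [
        (r * tile_size, c * tile_size)
        for r in range(h // tile_size)
        for c in range(w // tile_size)
    ]
    return TileGrid(tile_size=tile_size, coords=coords)


def mean_saturation(tile: np.ndarray) -> float:
    """Mean HSV saturation of an 8-bit RGB tile, on the 0-255 scale.

    S = 255 * (max - min) / max per pixel (0 where max = 0).
    """
    px = np.asarray(tile, dtype=np.float64)
    mx = px.max(axis=-1)
    mn = px.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(mx > 0, (mx - mn) * 255.0 / np.where(mx > 0, mx, 1.0), 0.0)
    return float(s.mean())


def saturation_filter(tile: np.ndarray, threshold: float = DEFAULT_SAT_THRESHOLD) -> bool:
    """Keep a tile iff its mean saturation is >= threshold (strict < discards)."""
    return mean_saturation(tile) >= threshold


def extract_bag(
    image: np.ndarray,
    tile_size: int = DEFAULT_TILE_SIZE,
    threshold: float = DEFAULT_SAT_THRESHOLD,
    extractor: FeatureExtractor | None = None,
    bag_id: str = "slide",
    label: int = 0,
) -> InstanceBag:
    """Tile a slide raster, drop background tiles, embed the survivors.

    Rows of the resulting feature matrix follow row-major grid order of
    the kept tiles; ``coords`` records each kept tile's grid (row, col).
    """
    if extractor is None:
        extractor = RandomProjectionExtractor()
    grid = tile_image(image, tile_size)
    feats, coords = [], []
    kept = np.zeros(len(grid.coords), dtype=bool)
    for i, (r, c) in enumerate(grid.coords):
        tile = image[r : r + tile_size, c : c + tile_size]
        if saturation_filter(tile, threshold):
            kept[i] = True
            feats.append(extractor(tile))
            coords.append((r // tile_size, c // tile_size))
    if not feats:
        raise EmptyBagError("no tile passed the saturation filter")
    grid.kept_mask = kept
    return InstanceBag(
        features=np.vstack(feats),
        label=label,
        bag_id=bag_id,
        coords=np.asarray(coords, dtype=np.int64),
    )
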