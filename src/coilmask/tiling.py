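"""Tile sampling, train/validation pool splitting, inference grids, stitching.

Training samples one random tile from one random photograph per step
("photo first, then tile": uniform over photographs, not over image area,
which over-represents small photographs — kept as-is, by design).  Inference
covers a photograph with a grid of overlapping tiles whose per-tile
probability maps are averaged back into a full-image map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import derive_seed

DEFAULT_TILE_SIZE = 512
DEFAULT_OVERLAP = 100


@dataclass(frozen=True)
class TileSpec:
    """Top-left corner (x0, y0) and side length of one square tile."""

    x0: int
    y0: int
    size: int

    def slices(self) -> tuple[slice, slice]:
        return slice(self.y0, self.y0 + self.size), slice(self.x0, self.x0 + self.size)


@dataclass
class TileGrid:
    image_size: tuple[int, int]  # (height, width)
    tile_size: int
    overlap: int
    tiles: list[TileSpec] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "image_size": list(self.image_size),
                "tile_size": self.tile_size,
                "overlap": self.overlap,
                "tiles": [[t.x0, t.y0] for t in self.tiles],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        doc = json.loads(text)
        return cls(
            image_size=tuple(doc["image_size"]),
            tile_size=doc["tile_size"],
            overlap=doc["overlap"],
            tiles=[TileSpec(x0, y0, doc["tile_size"]) for x0, y0 in doc["tiles"]],
        )


@dataclass(frozen=True)
class SplitConfig:
    """Photograph-pool split: train_fraction of ids to training, rest to validation."""

    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split_pool(ids: Sequence[str], cfg: SplitConfig) -> tuple[list[str], list[str]]:
    """Partition photograph ids into disjoint training and validation pools.

    Assignment is by seeded shuffle; ``|train| = floor(n * train_fraction)``
    with the remainder going to validation (151 ids at 0.9 -> 135 / 16).
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 ids (validation pool would be empty)")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_train = int(np.floor(n * cfg.train_fraction))
    train = [ids[i] for i in order[:n_train]]
    val = [ids[i] for i in order[n_train:]]
    return train, val


def sample_training_tile(
    photo: np.ndarray,
    label_mask: np.ndarray,
    tile_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, TileSpec]:
    """Cut one random tile from a photograph and its label at the same spot.

    The top-left corner is uniform over the valid range; image and mask tiles
    are cut at identical coordinates.
    """
    h, w = photo.shape[:2]
    if label_mask.shape[:2] != (h, w):
        raise ValueError("label mask shape must match the photograph")
    if h < tile_size or w < tile_size:
        raise ValueError(
            f"image ({h}x{w}) is smaller than tile_size={tile_size}; reduce tile_size"
        )
    y0 = int(rng.integers(0, h - tile_size + 1))
    x0 = int(rng.integers(0, w - tile_size + 1))
    spec = TileSpec(x0=x0, y0=y0, size=tile_size)
    sy, sx = spec.slices()
    return photo[sy, sx].copy(), label_mask[sy, sx].copy(), spec


def build_validation_set(
    val_photos_with_labels: Sequence[tuple[str, np.ndarray, np.ndarray]],
    tiles_per_photo: int = 32,
    tile_size: int = DEFAULT_TILE_SIZE,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Build the fixed validation set: tiles_per_photo random tiles per photo.

    Tiles may stochastically overlap each other.  Each photo's tiles come
    from a seed derived from (seed, photo_id), so adding photographs to the
    pool does not perturb the tiles of existing ones; the same seed always
    reproduces the identical set.
    """
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for photo_id, photo, mask in val_photos_with_labels:
        rng = np.random.default_rng(derive_seed(seed, "val", photo_id))
        for _ in range(tiles_per_photo):
            img_t, mask_t, _ = sample_training_tile(photo, mask, tile_size, rng)
            out.append((img_t, mask_t))
    return out


def _axis_starts(dim: int, tile_size: int, stride: int) -> list[int]:
    starts = list(range(0, dim - tile_size + 1, stride))
    if not starts:
        starts = [0]
    if starts[-1] + tile_size < dim:
        starts.append(dim - tile_size)
    return sorted(set(starts))


def inference_grid(
    image_size: tuple[int, int],
    tile_size: int = DEFAULT_TILE_SIZE,
    overlap: int = DEFAULT_OVERLAP,
) -> TileGrid:
    """Build the overlapping tile grid covering a full image.

    Starts at 0 with stride ``tile_size - overlap`` per axis; a final start
    clamped to ``dim - tile_size`` is appended when the regular stride would
    leave a strip uncovered.  Every pixel is covered by at least one tile.
    """
    h, w = int(image_size[0]), int(image_size[1])
    if overlap < 0 or overlap >= tile_size:
        raise ValueError("require 0 <= overlap < tile_size (positive stride)")
    if tile_size > min(h, w):
        raise ValueError(f"tile_size={tile_size} exceeds image dims {h}x{w}")
    stride = tile_size - overlap
    ys = _axis_starts(h, tile_size, stride)
    xs = _axis_starts(w, tile_size, stride)
    tiles = [TileSpec(x0=x, y0=y, size=tile_size) for y in ys for x in xs]
    return TileGrid(image_size=(h, w), tile_size=tile_size, overlap=overlap, tiles=tiles)


def stitch(
    per_tile_probs: Sequence[np.ndarray], grid: TileGrid, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Merge per-tile probability rasters into a full-image map and mask.

    Each pixel's probability is the arithmetic mean over all tiles covering
    it; the mask thresholds at ``probability >= threshold`` (ties are
    foreground).
    """
    if len(per_tile_probs) != len(grid.tiles):
        missing = len(grid.tiles) - len(per_tile_probs)
        raise ValueError(
            f"got {len(per_tile_probs)} predictions for {len(grid.tiles)} tiles "
            f"({missing} missing)"
        )
    h, w = grid.image_size
    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=float)
    lo = np.full((h, w), np.inf)
    hi = np.full((h, w), -np.inf)
    for probs, tile in zip(per_tile_probs, grid.tiles):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (tile.size, tile.size):
            raise ValueError(
                f"tile at ({tile.x0},{tile.y0}): prediction shape {probs.shape} "
                f"!= ({tile.size},{tile.size})"
            )
        sy, sx = tile.slices()
        acc[sy, sx] += probs
        cnt[sy, sx] += 1.0
        np.minimum(lo[sy, sx], probs, out=lo[sy, sx])
        np.maximum(hi[sy, sx], probs, out=hi[sy, sx])
    if np.any(cnt == 0):
        raise ValueError("grid does not cover the image (uncovered pixels)")
    prob = acc / cnt
    # exact conservation: where all covering tiles agree, bypass the division
    agree = lo == hi
    prob[agree] = lo[agree]
    return prob, prob >= threshold
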