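"""Shared helpers: seeding, PNG mask I/O, image loading."""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
from PIL import Image


def derive_seed(base_seed: int, *keys: object) -> int:
    """Derive a stable sub-seed from a base seed and arbitrary string/int keys.

    Stable across processes and runs (crc32, not Python's salted hash) so that
    e.g. per-photo validation tiles do not move when other photos are added.
    """
    h = zlib.crc32(str(int(base_seed)).encode())
    for k in keys:
        h = zlib.crc32(str(k).encode(), h)
    return int(h % (2**31 - 1))


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a single-channel PNG with values 0/255."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    Image.fromarray(arr, mode="L").save(Path(path))


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a single-channel mask PNG; any nonzero pixel is foreground."""
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return arr > 127


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    """Write a float RGB image in [0, 1] as an 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="RGB").save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read any PIL-supported image as float RGB in [0, 1]."""
    arr = np.asarray(Image.open(Path(path)).convert("RGB"), dtype=float)
    return arr / 255.0
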