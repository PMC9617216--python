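"""Backend contract, reference per-pixel backend, recall loss, training loop.

The trained quantity reported per epoch is the complement of pixel recall:
``loss = 1 - |mask AND label| / |label|``.  This metric deliberately does not
penalize background pixels misidentified as specimen — false positives are
removed later by post-processing — which also means it cannot serve as the
sole gradient signal (an empty prediction is not penalized symmetrically).
The reference backend therefore trains a standard per-pixel logistic
objective and uses the recall metric for reporting and epoch selection.
"""

from __future__ import annotations

import hashlib
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import transform as sktransform

from ._util import derive_seed


# ---------------------------------------------------------------------------
# Metrics


def recall_score(mask: np.ndarray, label: np.ndarray) -> float:
    """Fraction of labeled specimen pixels recovered by the mask.

    ``|mask AND label| / |label|``; pixels outside the label never affect the
    score.  Undefined (error) for an empty label.
    """
    mask = np.asarray(mask, dtype=bool)
    label = np.asarray(label, dtype=bool)
    if mask.shape != label.shape:
        raise ValueError(f"shape mismatch {mask.shape} vs {label.shape}")
    n_label = int(label.sum())
    if n_label == 0:
        raise ValueError("empty label: recall is undefined")
    return float(np.logical_and(mask, label).sum() / n_label)


def loss(mask: np.ndarray, label: np.ndarray) -> float:
    """Complement of recall: 0 for a perfect mask, 1 for a disjoint one."""
    return 1.0 - recall_score(mask, label)


# ---------------------------------------------------------------------------
# Backend contract


class SegmentationBackend(Protocol):
    """Contract for pluggable tile-level segmentation models.

    ``predict`` must be deterministic given the current state; ``fit_step``
    updates internal state and returns a scalar training loss in [0, 1]; it
    must never mutate its input arrays.
    """

    def predict(self, tile: np.ndarray) -> np.ndarray: ...

    def fit_step(self, tile: np.ndarray, mask: np.ndarray, learning_rate: float) -> float: ...

    def save_state(self, path: str | Path) -> None: ...

    def load_state(self, path: str | Path) -> None: ...


def lowres_mask_upsample(mask_lowres: np.ndarray, tile_size: int) -> np.ndarray:
    """Bilinearly upsample a coarse per-ROI probability raster to tile resolution.

    External instance-segmentation backends emit small fixed-resolution mask
    heads (e.g. 28x28); this is the adapter step that maps them onto a tile.
    A constant raster stays constant and the 0.5 crossing of an upsampled
    step stays within one coarse cell of the original boundary.
    """
    arr = np.asarray(mask_lowres, dtype=float)
    if arr.shape == (tile_size, tile_size):
        return arr.copy()
    return sktransform.resize(
        arr, (tile_size, tile_size), order=1, mode="edge", anti_aliasing=False
    )


# ---------------------------------------------------------------------------
# Reference backend: logistic per-pixel classifier on multi-scale features


_FEATURE_SIGMAS = (2.0, 8.0)


def _tile_features(tile: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack over local color and texture.

    Raw RGB; normalized chromaticity (per-channel fraction of the pixel sum,
    raw and smoothed) — brightness-invariant, which separates a dark body
    band from a dark mat by hue rather than intensity; Gaussian-smoothed RGB
    and local SD (texture) at two scales, the coarse scale carrying body
    color across wide bands; squares of the smoothed chromaticity; bias.
    """
    tile = np.asarray(tile, dtype=float)
    h, w, _ = tile.shape
    feats = [tile[..., c] for c in range(3)]
    chroma = tile / (tile.sum(axis=-1, keepdims=True) + 1e-3)
    chroma_sm = np.stack(
        [ndi.gaussian_filter(chroma[..., c], 4.0, mode="reflect") for c in range(3)], -1
    )
    for c in range(3):
        feats.append(chroma[..., c])
    for c in range(3):
        feats.append(chroma_sm[..., c])
    for sigma in _FEATURE_SIGMAS:
        sm = np.stack(
            [ndi.gaussian_filter(tile[..., c], sigma, mode="reflect") for c in range(3)], -1
        )
        sq = np.stack(
            [ndi.gaussian_filter(tile[..., c] ** 2, sigma, mode="reflect") for c in range(3)],
            -1,
        )
        sd = np.sqrt(np.maximum(sq - sm**2, 0.0))
        for c in range(3):
            feats.append(sm[..., c])
            feats.append(sd[..., c])
    for c in range(3):
        feats.append(chroma_sm[..., c] ** 2)
    feats.append(np.ones((h, w)))
    return np.stack(feats, axis=-1)  # (h, w, n_features)


class ReferenceBackend:
    """Compact trainable per-pixel classifier over local color+texture features.

    A logistic model on a small multi-scale feature stack: fast enough to
    train on one CPU in minutes and deterministic given its creation seed.
    Not a region-proposal network — the backend contract is what lets a
    heavyweight instance-segmentation model slot into the same loop.
    """

    N_FEATURES = 25  # 3 raw + 6 chroma + 2*(3 smooth + 3 sd) + 3 squared + bias
    _BATCH = 2048
    _L2 = 1e-5

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._rng = np.random.default_rng(derive_seed(seed, "refbackend"))
        self.weights = np.zeros(self.N_FEATURES)

    # -- contract ----------------------------------------------------------

    def predict(self, tile: np.ndarray) -> np.ndarray:
        f = _tile_features(tile)
        z = f @ self.weights
        return 1.0 / (1.0 + np.exp(-np.clip(z, -40, 40)))

    def fit_step(self, tile: np.ndarray, mask: np.ndarray, learning_rate: float) -> float:
        f = _tile_features(tile)
        y = np.asarray(mask, dtype=bool)
        h, w, nf = f.shape
        flat_f = f.reshape(-1, nf)
        flat_y = y.ravel()

        # class-balanced minibatch where both classes are present
        fg = np.flatnonzero(flat_y)
        bg = np.flatnonzero(~flat_y)
        half = self._BATCH // 2
        picks = []
        if len(fg):
            picks.append(self._rng.choice(fg, size=min(half, len(fg) * 4), replace=True))
        if len(bg):
            picks.append(self._rng.choice(bg, size=min(half, len(bg) * 4), replace=True))
        idx = np.concatenate(picks)
        fb, yb = flat_f[idx], flat_y[idx].astype(float)

        z = np.clip(fb @ self.weights, -40, 40)
        p = 1.0 / (1.0 + np.exp(-z))
        grad = fb.T @ (p - yb) / len(idx) + self._L2 * self.weights
        self.weights = self.weights - learning_rate * grad

        # reported training loss: recall complement on this tile (post-update
        # prediction), or the false-positive rate when the tile has no label
        prob = 1.0 / (1.0 + np.exp(-np.clip(flat_f @ self.weights, -40, 40)))
        pred = prob >= 0.5
        if flat_y.any():
            return 1.0 - float((pred & flat_y).sum() / flat_y.sum())
        return float(pred.mean())

    def save_state(self, path: str | Path) -> None:
        np.savez(Path(path), weights=self.weights, seed=self.seed, version=1)

    def load_state(self, path: str | Path) -> None:
        with np.load(Path(path)) as doc:
            self.weights = doc["weights"].copy()

    def state_bytes(self) -> bytes:
        buf = io.BytesIO()
        np.savez(buf, weights=self.weights, seed=self.seed, version=1)
        return buf.getvalue()


def reference_backend_create(seed: int = 0) -> ReferenceBackend:
    return ReferenceBackend(seed=seed)


# ---------------------------------------------------------------------------
# Training loop


@dataclass
class TrainingConfig:
    """Epoch-loop settings; defaults mirror the published run at full scale."""

    learning_rate: float = 1e-4
    steps_per_epoch: int = 450
    val_steps: int = 50
    epochs: int = 20
    tile_size: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "steps_per_epoch", "val_steps", "epochs", "tile_size"):
            if getattr(self, name) < 0 or (
                name in ("learning_rate", "val_steps", "epochs", "tile_size")
                and getattr(self, name) <= 0
            ):
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochRecord:
    epoch: int  # 1-based
    train_loss: float
    val_loss: float
    checkpoint: str | None = None


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {"epoch": r.epoch, "train_loss": r.train_loss, "val_loss": r.val_loss,
                 # basename only: content-addressed, stable across run dirs
                 "checkpoint": Path(r.checkpoint).name if r.checkpoint else ""}
                for r in self.records
            ]
        ).to_csv(path, index=False)

    def plot(self, path: str | Path) -> None:
        """Export a loss-per-epoch curve (train and validation)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        epochs = [r.epoch for r in self.records]
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(epochs, [r.train_loss for r in self.records], label="training loss")
        ax.plot(epochs, [r.val_loss for r in self.records], label="validation loss")
        best = select_epoch(self)
        ax.axvline(best, color="k", lw=1)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss (1 - pixel recall)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


class TrainSampler:
    """Photo-first-then-tile sampler over the training pool."""

    def __init__(
        self,
        photos_with_labels: Sequence[tuple[str, np.ndarray, np.ndarray]],
        tile_size: int,
        seed: int,
        augment_fn: Callable[[np.ndarray, np.random.Generator], np.ndarray] | None = None,
    ):
        if not photos_with_labels:
            raise ValueError("empty training pool")
        self.photos = list(photos_with_labels)
        self.tile_size = tile_size
        self.rng = np.random.default_rng(derive_seed(seed, "trainsampler"))
        self.augment_fn = augment_fn

    def __call__(self) -> tuple[np.ndarray, np.ndarray]:
        from .tiling import sample_training_tile

        i = int(self.rng.integers(0, len(self.photos)))
        _, photo, mask = self.photos[i]
        img_t, mask_t, _ = sample_training_tile(photo, mask, self.tile_size, self.rng)
        if self.augment_fn is not None:
            img_t = self.augment_fn(img_t, self.rng)
        return img_t, mask_t


def _validation_loss(
    backend: SegmentationBackend,
    val_set: Sequence[tuple[np.ndarray, np.ndarray]],
    val_steps: int,
) -> float:
    """Mean soft recall-complement over the first val_steps validation tiles.

    Soft recall is the mean predicted probability over label pixels: the same
    quantity as thresholded pixel recall at convergence, but continuous in
    the model state.  The thresholded version saturates to exactly 0 on easy
    validation pools, at which point argmin epoch selection can no longer
    locate the plateau onset and deploys an undertrained checkpoint.
    Evaluation never updates model state.  Tiles whose label is empty carry
    no recall information and are skipped (their count is warned about once).
    """
    losses = []
    n_empty = 0
    for img_t, mask_t in list(val_set)[:val_steps]:
        m = np.asarray(mask_t, dtype=bool)
        if not m.any():
            n_empty += 1
            continue
        prob = backend.predict(img_t)
        losses.append(1.0 - float(prob[m].mean()))
    if not losses:
        raise ValueError("no validation tile contains labeled specimen pixels")
    if n_empty:
        warnings.warn(f"{n_empty} validation tiles had empty labels and were skipped")
    return float(np.mean(losses))


def run_epoch(
    backend: SegmentationBackend,
    train_sampler: Callable[[], tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainingConfig,
    epoch: int = 1,
    checkpoint_dir: str | Path | None = None,
) -> EpochRecord:
    """One epoch: steps_per_epoch fit steps, then a no-update validation pass."""
    if cfg.val_steps > len(val_set):
        raise ValueError("val_steps exceeds the size of the validation set")
    train_losses = []
    for _ in range(cfg.steps_per_epoch):
        img_t, mask_t = train_sampler()
        step_loss = backend.fit_step(img_t, mask_t, cfg.learning_rate)
        if not np.isfinite(step_loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}; "
                "try a lower learning rate"
            )
        train_losses.append(step_loss)
    val_loss = _validation_loss(backend, val_set, cfg.val_steps)
    checkpoint = None
    if checkpoint_dir is not None:
        checkpoint = save_checkpoint(backend, checkpoint_dir, cfg, epoch)
    return EpochRecord(
        epoch=epoch,
        train_loss=float(np.mean(train_losses)) if train_losses else float("nan"),
        val_loss=val_loss,
        checkpoint=checkpoint,
    )


def train(
    backend: SegmentationBackend,
    train_sampler: Callable[[], tuple[np.ndarray, np.ndarray]],
    val_set: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainingConfig,
    checkpoint_dir: str | Path | None = None,
) -> TrainingHistory:
    """Run cfg.epochs sequential epochs, checkpointing after each."""
    history = TrainingHistory()
    for e in range(1, cfg.epochs + 1):
        history.records.append(
            run_epoch(backend, train_sampler, val_set, cfg, epoch=e, checkpoint_dir=checkpoint_dir)
        )
    return history


def select_epoch(history: TrainingHistory) -> int:
    """1-based epoch at the validation-loss minimum; earliest epoch wins ties.

    The earliest minimum marks the onset of the validation plateau, after
    which continued training tends to overfit.
    """
    if not history.records:
        raise ValueError("empty history")
    losses = [r.val_loss for r in history.records]
    return history.records[int(np.argmin(losses))].epoch


def save_checkpoint(
    backend: SegmentationBackend,
    checkpoint_dir: str | Path,
    cfg: TrainingConfig,
    epoch: int,
) -> str:
    """Write a content-addressed checkpoint file; never overwrites or deletes."""
    d = Path(checkpoint_dir)
    d.mkdir(parents=True, exist_ok=True)
    if hasattr(backend, "state_bytes"):
        blob = backend.state_bytes()
    else:  # pragma: no cover - generic backends
        tmp = d / f"_tmp_epoch{epoch}.npz"
        backend.save_state(tmp)
        blob = tmp.read_bytes()
        tmp.unlink()
    digest = hashlib.sha256(blob).hexdigest()[:16]
    path = d / f"epoch{epoch:03d}_{digest}.ckpt.npz"
    if not path.exists():
        path.write_bytes(blob)
    return str(path)
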