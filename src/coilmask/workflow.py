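"""End-to-end orchestration: simulate/load -> preblur -> split -> train ->
select -> tiled inference -> post-process -> calibrate -> export -> analyze.

A single structured config drives the run; every stage logs its inputs,
outputs and seeds into a machine-readable run record so a run can be replayed
exactly.  With the reference backend, replaying an identical config produces
byte-identical mask and CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration, granularity, postprocess, roi_io, synthetic, tiling, training
from ._util import derive_seed, read_image, read_mask_png, write_image_png, write_mask_png


class ConfigError(ValueError):
    """Raised for invalid or inconsistent pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    # data: simulate n scenes, or point at image/label directories
    simulate_n: int = 20
    simulate_test_n: int = 5
    image_size: tuple[int, int] = (256, 256)
    images_dir: str | None = None
    labels_dir: str | None = None
    # preprocessing
    preblur_kernel_px: int = 5
    # split / tiling
    train_fraction: float = 0.9
    tile_size: int = 128
    overlap: int = 32
    tiles_per_val_photo: int = 32
    # training (reference backend scale)
    learning_rate: float = 1.0
    steps_per_epoch: int = 120
    val_steps: int = 60
    epochs: int = 10
    # post-processing
    keep_components: int = 1
    # calibration
    radius_min_px: int = 8
    radius_max_px: int = 24
    standard_diameter_mm: float = 25.4
    # analysis
    pattern_sizes: list[int] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if isinstance(cfg.image_size, list):
            cfg.image_size = tuple(cfg.image_size)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        return d


def _load_photo_pool(cfg: PipelineConfig, root: Path) -> tuple[list, list]:
    """Return (labeled pool, inference pool) as (id, image, mask|None) triples."""
    if cfg.images_dir is None:
        sim_dir = root / "simulated"
        synthetic.generate_dataset(
            cfg.simulate_n + cfg.simulate_test_n, sim_dir, seed=derive_seed(cfg.seed, "sim"),
            image_size=cfg.image_size,
        )
        ids = [f"scene_{i:04d}" for i in range(cfg.simulate_n + cfg.simulate_test_n)]
        pool = []
        for sid in ids:
            img = read_image(sim_dir / "images" / f"{sid}.png")
            mask = read_mask_png(sim_dir / "masks" / f"{sid}.png")
            pool.append((sid, img, mask))
        return pool[: cfg.simulate_n], pool[cfg.simulate_n :]
    images_dir = Path(cfg.images_dir)
    labeled, unlabeled = [], []
    for p in sorted(images_dir.iterdir()):
        if p.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
            continue
        img = read_image(p)
        mask = None
        if cfg.labels_dir is not None:
            lp = Path(cfg.labels_dir) / f"{p.stem}.json"
            if lp.exists():
                mask = roi_io.labels_to_mask(roi_io.read_labels(lp))
        (labeled if mask is not None else unlabeled).append((p.stem, img, mask))
    return labeled, unlabeled


def infer_photo(
    backend: training.SegmentationBackend,
    photo: np.ndarray,
    tile_size: int,
    overlap: int,
) -> tuple[np.ndarray, np.ndarray, tiling.TileGrid]:
    """Tile a photograph, predict each tile, and stitch the probability map."""
    grid = tiling.inference_grid(photo.shape[:2], tile_size, overlap)
    preds = []
    for t in grid.tiles:
        sy, sx = t.slices()
        preds.append(backend.predict(photo[sy, sx]))
    prob, mask = tiling.stitch(preds, grid)
    return prob, mask, grid


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full workflow; returns the results directory.

    Any stage failure raises StageError naming the stage and leaves prior
    artifacts on disk for inspection.
    """
    root = Path(cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    record: dict = {"config": cfg.to_dict(), "stages": []}

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.monotonic()
                record["stages"].append({"stage": name})
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                entry = record["stages"][-1]
                entry["wall_s"] = round(time.monotonic() - self_inner.t0, 3)
                if exc is not None:
                    entry["error"] = str(exc)
                    _write_record(root, record)
                    raise StageError(name, str(exc)) from exc
                return False

        return _Ctx()

    with stage("load_or_simulate"):
        labeled_pool, infer_pool = _load_photo_pool(cfg, root)
        if len(labeled_pool) < 2:
            raise ConfigError("need at least 2 labeled photographs to split")

    with stage("preblur"):
        labeled_pool = [
            (sid, postprocess.gaussian_preblur(img, cfg.preblur_kernel_px), m)
            for sid, img, m in labeled_pool
        ]
        infer_pool = [
            (sid, postprocess.gaussian_preblur(img, cfg.preblur_kernel_px), m)
            for sid, img, m in infer_pool
        ]

    with stage("split"):
        ids = [sid for sid, _, _ in labeled_pool]
        train_ids, val_ids = tiling.split_pool(
            ids, tiling.SplitConfig(train_fraction=cfg.train_fraction, seed=derive_seed(cfg.seed, "split"))
        )
        by_id = {sid: (sid, img, m) for sid, img, m in labeled_pool}
        record["stages"][-1]["train_ids"] = train_ids
        record["stages"][-1]["val_ids"] = val_ids

    with stage("train"):
        tcfg = training.TrainingConfig(
            learning_rate=cfg.learning_rate,
            steps_per_epoch=cfg.steps_per_epoch,
            val_steps=cfg.val_steps,
            epochs=cfg.epochs,
            tile_size=cfg.tile_size,
            seed=cfg.seed,
        )
        val_set = tiling.build_validation_set(
            [by_id[i] for i in val_ids],
            tiles_per_photo=cfg.tiles_per_val_photo,
            tile_size=cfg.tile_size,
            seed=derive_seed(cfg.seed, "valset"),
        )
        backend = training.reference_backend_create(seed=derive_seed(cfg.seed, "backend"))
        sampler = training.TrainSampler(
            [by_id[i] for i in train_ids], cfg.tile_size, seed=derive_seed(cfg.seed, "sampler")
        )
        history = training.train(backend, sampler, val_set, tcfg, checkpoint_dir=root / "checkpoints")
        history.to_csv(root / "history.csv")
        history.plot(root / "loss_curve.png")

    with stage("select_epoch"):
        best = training.select_epoch(history)
        ckpt = history.records[best - 1].checkpoint
        backend.load_state(ckpt)
        record["stages"][-1].update({"selected_epoch": best, "checkpoint": ckpt})

    masks_dir = root / "masks"
    masks_dir.mkdir(exist_ok=True)
    targets = infer_pool if infer_pool else [by_id[i] for i in val_ids]
    with stage("inference"):
        inferred: list[tuple[str, np.ndarray, np.ndarray]] = []
        for sid, img, truth in targets:
            prob, mask, grid = infer_photo(backend, img, cfg.tile_size, cfg.overlap)
            (root / "grids").mkdir(exist_ok=True)
            (root / "grids" / f"{sid}.json").write_text(grid.to_json())
            write_mask_png(mask, masks_dir / f"{sid}_raw.png")
            inferred.append((sid, mask, truth))

    with stage("postprocess"):
        cleaned = []
        for sid, mask, truth in inferred:
            clean = postprocess.keep_largest_components(mask, cfg.keep_components)
            write_mask_png(clean, masks_dir / f"{sid}.png")
            cleaned.append((sid, clean, truth))

    with stage("calibrate_and_export"):
        labels_dir = root / "labels_out"
        labels_dir.mkdir(exist_ok=True)
        calib: dict[str, dict] = {}
        for (sid, img, _), (_, clean, _t) in zip(targets, cleaned):
            try:
                det = calibration.detect_gray_standard(
                    img, (cfg.radius_min_px, cfg.radius_max_px)
                )
            except calibration.StandardNotFoundError as exc:
                warnings.warn(f"{sid}: {exc}")
                calib[sid] = {"error": str(exc)}
                continue
            scale = calibration.calibrate_scale(det, cfg.standard_diameter_mm)
            calibration.export_combined_rois(clean, det, sid, labels_dir / f"{sid}.json")
            calib[sid] = {
                "px_per_mm": scale.px_per_mm,
                "center": list(det.center),
                "radius_px": det.radius,
            }
        (root / "calibration.json").write_text(json.dumps(calib, indent=1, sort_keys=True))

    with stage("analyze"):
        have_truth = [(sid, m, t) for sid, m, t in cleaned if t is not None and t.any() and m.any()]
        if have_truth:
            photos = {sid: img for sid, img, _ in targets}
            comp, sa, sb = granularity.compare_masks(
                [photos[sid] for sid, _, _ in have_truth],
                [t for _, _, t in have_truth],
                [m for _, m, _ in have_truth],
                cfg.pattern_sizes,
            )
            ids_t = [sid for sid, _, _ in have_truth]
            granularity.spectra_to_csv(sa, ids_t, root / "spectra_reference.csv")
            granularity.spectra_to_csv(sb, ids_t, root / "spectra_inferred.csv")
            granularity.plot_residuals(comp, root / "residuals.png")
            if len(have_truth) >= 2:
                tt = granularity.paired_ttest_channels(sa, sb)
                record["stages"][-1]["paired_t"] = {"t": tt.t, "df": tt.df, "p": tt.p}
            recalls = [training.recall_score(m, t) for _, m, t in have_truth]
            record["stages"][-1]["heldout_recall"] = recalls
            record["stages"][-1]["heldout_recall_mean"] = float(np.mean(recalls))

    record["selected_epoch"] = training.select_epoch(history)
    _write_record(root, record)
    return root


def parameter_recovery_experiment(
    seed: int,
    n_train_scenes: int = 20,
    n_heldout: int = 5,
    image_size: tuple[int, int] = (256, 256),
    tile_size: int = 128,
    overlap: int = 32,
    epochs: int = 10,
    steps_per_epoch: int = 120,
    val_steps: int = 60,
    learning_rate: float = 1.0,
) -> dict:
    """Train the reference backend on synthetic scenes and score held-out recall.

    The training pool is split 9:1 into training and validation photographs;
    the epoch is selected at the validation-loss argmin; held-out scenes are
    masked by tiled inference + stitching, then cleaned by keep-largest-
    component.  Returns per-scene raw and post-processed recall.
    """
    import tempfile

    scenes = []
    for i in range(n_train_scenes + n_heldout):
        spec = synthetic.random_scene_spec(
            np.random.default_rng(derive_seed(seed, "scene", i)), image_size=image_size
        )
        img, mask, _ = synthetic.generate_scene(spec)
        img = postprocess.gaussian_preblur(img, 5)
        scenes.append((f"s{i:02d}", img, mask))
    pool, held = scenes[:n_train_scenes], scenes[n_train_scenes:]
    ids = [s[0] for s in pool]
    train_ids, val_ids = tiling.split_pool(
        ids, tiling.SplitConfig(0.9, derive_seed(seed, "split"))
    )
    by = {s[0]: s for s in pool}
    val_set = tiling.build_validation_set(
        [by[i] for i in val_ids], 32, tile_size, seed=derive_seed(seed, "val")
    )
    backend = training.reference_backend_create(seed=derive_seed(seed, "be"))
    sampler = training.TrainSampler(
        [by[i] for i in train_ids], tile_size, seed=derive_seed(seed, "sam")
    )
    cfg = training.TrainingConfig(
        learning_rate=learning_rate,
        steps_per_epoch=steps_per_epoch,
        val_steps=val_steps,
        epochs=epochs,
        tile_size=tile_size,
        seed=seed,
    )
    with tempfile.TemporaryDirectory() as d:
        history = training.train(backend, sampler, val_set, cfg, checkpoint_dir=d)
        best = training.select_epoch(history)
        backend.load_state(history.records[best - 1].checkpoint)
        raw, post = [], []
        for _, img, truth in held:
            _, mask, _ = infer_photo(backend, img, tile_size, overlap)
            clean = postprocess.keep_largest_components(mask, 1)
            raw.append(training.recall_score(mask, truth))
            post.append(training.recall_score(clean, truth))
    return {
        "selected_epoch": best,
        "val_losses": [r.val_loss for r in history.records],
        "raw_recall": raw,
        "post_recall": post,
        "mean_post_recall": float(np.mean(post)),
    }


def _write_record(root: Path, record: dict) -> None:
    (root / "run_record.json").write_text(json.dumps(record, indent=1, sort_keys=True))


def overlay_sample(
    photos: list[tuple[str, np.ndarray]],
    masks: dict[str, np.ndarray],
    k: int,
    seed: int = 0,
    alpha: float = 0.45,
) -> np.ndarray:
    """Contact sheet of k random photographs with translucent mask overlays.

    Meant for qualitative QC of inference on unlabeled data.  k = 0 yields an
    empty (1-pixel) sheet; k larger than the dataset uses all photos with a
    warning; a fixed seed fixes the selection.
    """
    if k == 0 or not photos:
        return np.zeros((1, 1, 3))
    rng = np.random.default_rng(derive_seed(seed, "overlay"))
    if k > len(photos):
        warnings.warn(f"k={k} exceeds dataset size {len(photos)}; showing all")
        k = len(photos)
    idx = rng.choice(len(photos), size=k, replace=False)
    panels = []
    for i in sorted(idx.tolist()):
        sid, img = photos[i]
        img = np.asarray(img, dtype=float).copy()
        mask = masks.get(sid)
        if mask is not None:
            overlay_color = np.array([1.0, 0.1, 0.1])
            img[mask] = (1 - alpha) * img[mask] + alpha * overlay_color
        panels.append(img)
    hmax = max(p.shape[0] for p in panels)
    padded = [
        np.pad(p, ((0, hmax - p.shape[0]), (0, 2), (0, 0)), constant_values=1.0)
        for p in panels
    ]
    return np.concatenate(padded, axis=1)


def save_overlay(sheet: np.ndarray, path: str | Path) -> None:
    write_image_png(sheet, path)
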