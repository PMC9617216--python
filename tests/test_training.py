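"""Recall metric, epoch loop, checkpoint selection, reference backend."""

import numpy as np
import pytest

from coilmask import training
from coilmask.training import TrainingConfig


def brute_force_recall(mask, label):
    hits = 0
    total = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if label[r, c]:
                total += 1
                if mask[r, c]:
                    hits += 1
    return hits / total


class TestRecallAndLoss:
    def test_identity_is_one(self, rng):
        m = rng.random((16, 16)) > 0.4
        if not m.any():
            m[0, 0] = True
        assert training.recall_score(m, m) == 1.0

    def test_partial_coverage_counts_pixels(self):
        label = np.zeros((10, 10), dtype=bool)
        label[0, :8] = True
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :6] = True
        mask[5:, :] = True  # 50 false positives
        assert training.recall_score(mask, label) == 0.75
        assert training.loss(mask, label) == 0.25

    def test_disjoint_is_zero(self):
        label = np.zeros((4, 4), dtype=bool)
        label[0, 0] = True
        mask = np.zeros((4, 4), dtype=bool)
        mask[3, 3] = True
        assert training.recall_score(mask, label) == 0.0
        assert training.loss(np.zeros((4, 4), bool), label) == 1.0

    def test_empty_label_is_error(self):
        with pytest.raises(ValueError, match="empty label"):
            training.recall_score(np.ones((4, 4), bool), np.zeros((4, 4), bool))

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_random_pairs(self, seed):
        r = np.random.default_rng(seed)
        for _ in range(25):
            mask = r.random((16, 16)) > r.uniform(0.2, 0.8)
            label = r.random((16, 16)) > r.uniform(0.2, 0.8)
            if not label.any():
                label[0, 0] = True
            assert training.recall_score(mask, label) == pytest.approx(
                brute_force_recall(mask, label)
            )

    def test_insensitive_to_added_false_positives(self, rng):
        label = rng.random((16, 16)) > 0.6
        label[0, 0] = True
        mask = label & (rng.random((16, 16)) > 0.3)
        base = training.recall_score(mask, label)
        noisy = mask | (~label & (rng.random((16, 16)) > 0.2))
        assert training.recall_score(noisy, label) == base


class TestSelectEpoch:
    def _hist(self, losses):
        return training.TrainingHistory(
            records=[training.EpochRecord(i + 1, 0.0, v) for i, v in enumerate(losses)]
        )

    def test_monotone_decreasing_selects_last(self):
        assert training.select_epoch(self._hist([0.5, 0.4, 0.3, 0.2])) == 4

    def test_argmin_with_later_increase(self):
        assert training.select_epoch(self._hist([0.5, 0.3, 0.2, 0.21, 0.25])) == 3

    def test_all_equal_selects_first(self):
        assert training.select_epoch(self._hist([0.3, 0.3, 0.3])) == 1


class TestLowresUpsample:
    def test_constant_stays_constant(self):
        up = training.lowres_mask_upsample(np.full((28, 28), 0.7), 512)
        assert up.shape == (512, 512)
        assert np.allclose(up, 0.7)

    def test_identity_when_sizes_match(self):
        arr = np.random.default_rng(0).random((28, 28))
        assert np.array_equal(training.lowres_mask_upsample(arr, 28), arr)

    def test_step_crossing_within_one_coarse_cell(self):
        coarse = np.zeros((28, 28))
        coarse[:14, :] = 1.0  # boundary between rows 13 and 14
        up = training.lowres_mask_upsample(coarse, 280)
        cell = 280 / 28
        crossing_rows = np.where(np.abs(up[:, 0] - 0.5) < 0.5)[0]
        boundary = 14 * cell
        assert np.all(np.abs(crossing_rows - boundary) <= cell + 1)


def _toy_pool(n, size=64, seed=0):
    """Tiny photos: bright square specimen on dark background."""
    r = np.random.default_rng(seed)
    pool = []
    for i in range(n):
        img = np.full((size, size, 3), 0.1) + r.normal(0, 0.01, (size, size, 3))
        mask = np.zeros((size, size), dtype=bool)
        s = r.integers(8, 20)
        y0, x0 = r.integers(0, size - s, 2)
        mask[y0 : y0 + s, x0 : x0 + s] = True
        img[mask] = [0.8, 0.5, 0.2]
        pool.append((f"t{i}", np.clip(img, 0, 1), mask))
    return pool


class TestEpochLoop:
    def _setup(self, seed=0):
        pool = _toy_pool(6, seed=seed)
        backend = training.reference_backend_create(seed=seed)
        sampler = training.TrainSampler(pool[:4], tile_size=32, seed=seed)
        from coilmask import tiling

        val_set = tiling.build_validation_set(pool[4:], 8, 32, seed=seed)
        return backend, sampler, val_set

    def test_validation_does_not_change_state(self):
        backend, sampler, val_set = self._setup()
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=5, val_steps=8,
                             epochs=1, tile_size=32, seed=0)
        rec = training.run_epoch(backend, sampler, val_set, cfg)
        w = backend.weights.copy()
        v1 = training._validation_loss(backend, val_set, 8)
        v2 = training._validation_loss(backend, val_set, 8)
        assert v1 == v2 == rec.val_loss
        assert np.array_equal(backend.weights, w)

    def test_zero_training_steps_gives_validation_only_record(self):
        backend, sampler, val_set = self._setup()
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=0, val_steps=8,
                             epochs=1, tile_size=32, seed=0)
        rec = training.run_epoch(backend, sampler, val_set, cfg)
        assert np.isnan(rec.train_loss)
        assert 0.0 <= rec.val_loss <= 1.0

    def test_val_steps_cannot_exceed_val_set(self):
        backend, sampler, val_set = self._setup()
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=1, val_steps=999,
                             epochs=1, tile_size=32, seed=0)
        with pytest.raises(ValueError, match="val_steps"):
            training.run_epoch(backend, sampler, val_set, cfg)

    def test_deterministic_replay_identical_history(self, tmp_path):
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=10, val_steps=8,
                             epochs=3, tile_size=32, seed=0)
        hists = []
        for run in range(2):
            backend, sampler, val_set = self._setup(seed=0)
            hists.append(
                training.train(backend, sampler, val_set, cfg, checkpoint_dir=tmp_path / str(run))
            )
        a, b = hists
        for ra, rb in zip(a.records, b.records):
            assert ra.train_loss == rb.train_loss
            assert ra.val_loss == rb.val_loss

    def test_validation_loss_improves_early_on_toy_scenes(self, tmp_path):
        backend, sampler, val_set = self._setup()
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=30, val_steps=8,
                             epochs=3, tile_size=32, seed=0)
        hist = training.train(backend, sampler, val_set, cfg, checkpoint_dir=tmp_path)
        assert hist.records[-1].val_loss <= hist.records[0].val_loss

    def test_checkpoints_saved_and_loadable(self, tmp_path):
        backend, sampler, val_set = self._setup()
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=5, val_steps=8,
                             epochs=2, tile_size=32, seed=0)
        hist = training.train(backend, sampler, val_set, cfg, checkpoint_dir=tmp_path)
        assert all(r.checkpoint for r in hist.records)
        fresh = training.reference_backend_create(seed=0)
        fresh.load_state(hist.records[-1].checkpoint)
        assert np.array_equal(fresh.weights, backend.weights)

    def test_history_csv_export(self, tmp_path):
        backend, sampler, val_set = self._setup()
        cfg = TrainingConfig(learning_rate=0.5, steps_per_epoch=2, val_steps=4,
                             epochs=2, tile_size=32, seed=0)
        hist = training.train(backend, sampler, val_set, cfg)
        hist.to_csv(tmp_path / "h.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "h.csv")
        assert list(df["epoch"]) == [1, 2]
        assert set(df.columns) >= {"epoch", "train_loss", "val_loss"}


class TestReferenceBackend:
    def test_predict_deterministic_and_bounded(self, rng):
        backend = training.reference_backend_create(seed=3)
        tile = rng.random((32, 32, 3))
        p1, p2 = backend.predict(tile), backend.predict(tile)
        assert np.array_equal(p1, p2)
        assert (p1 >= 0).all() and (p1 <= 1).all()

    def test_fit_step_does_not_mutate_inputs(self, rng):
        backend = training.reference_backend_create(seed=3)
        tile = rng.random((32, 32, 3))
        mask = rng.random((32, 32)) > 0.5
        tile_c, mask_c = tile.copy(), mask.copy()
        backend.fit_step(tile, mask, 0.5)
        assert np.array_equal(tile, tile_c) and np.array_equal(mask, mask_c)

    def test_learns_toy_separation(self):
        pool = _toy_pool(1, size=48)
        _, img, mask = pool[0]
        backend = training.reference_backend_create(seed=0)
        for _ in range(60):
            backend.fit_step(img, mask, 1.0)
        assert training.recall_score(backend.predict(img) >= 0.5, mask) >= 0.9

    def test_state_roundtrip(self, tmp_path, rng):
        backend = training.reference_backend_create(seed=1)
        backend.fit_step(rng.random((32, 32, 3)), rng.random((32, 32)) > 0.5, 0.5)
        backend.save_state(tmp_path / "s.npz")
        other = training.reference_backend_create(seed=99)
        other.load_state(tmp_path / "s.npz")
        assert np.array_equal(other.weights, backend.weights)
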