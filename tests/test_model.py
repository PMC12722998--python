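"""Subject splitting, augmentation, and the training loop."""

import numpy as np
import pandas as pd
import pytest

from fastpool.model import (AugmentConfig, TrainConfig, augment_window,
                            load_checkpoint, save_checkpoint,
                            split_by_subject, train_model)
from fastpool.synthetic import SyntheticConfig, simulate_dataset
from fastpool.windows import WindowingConfig, make_windows


def manifest_of(groups: dict[str, list[str]]) -> pd.DataFrame:
    rows = [{"subject_id": s, "group_tag": g, "video_id": f"{s}_v",
             "label": "negative"}
            for g, subjects in groups.items() for s in subjects]
    return pd.DataFrame(rows)


class TestSplitBySubject:
    def test_single_group_80_20(self):
        m = manifest_of({"g": [f"s{i}" for i in range(10)]})
        train, val = split_by_subject(m, 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2

    def test_per_group_stratified_rounding(self):
        m = manifest_of({"a": [f"a{i}" for i in range(5)],
                         "b": [f"b{i}" for i in range(5)]})
        train, val = split_by_subject(m, 0.8, seed=1)
        for g in "ab":
            assert sum(s.startswith(g) for s in train) == 4
            assert sum(s.startswith(g) for s in val) == 1

    def test_disjoint_for_many_seeds(self):
        m = manifest_of({"a": [f"a{i}" for i in range(7)],
                         "b": [f"b{i}" for i in range(4)]})
        for seed in range(200):
            train, val = split_by_subject(m, 0.8, seed=seed)
            assert not set(train) & set(val)
            assert sorted(train + val) == sorted(m["subject_id"].unique())

    def test_singleton_group_goes_to_training(self, caplog):
        m = manifest_of({"a": ["a0", "a1", "a2"], "lone": ["x0"]})
        with caplog.at_level("WARNING"):
            train, _ = split_by_subject(m, 0.8, seed=3)
        assert "x0" in train
        assert any("single subject" in r.message for r in caplog.records)

    def test_deterministic_under_seed(self):
        m = manifest_of({"a": [f"a{i}" for i in range(9)]})
        assert split_by_subject(m, 0.8, 5) == split_by_subject(m, 0.8, 5)

    def test_kfold_driver_partitions_subjects(self):
        from fastpool.model import kfold_subject_splits
        m = manifest_of({"a": [f"a{i}" for i in range(6)],
                         "b": [f"b{i}" for i in range(4)]})
        folds = kfold_subject_splits(m, k=3, seed=1)
        holdouts = [set(h) for _, h in folds]
        # holdouts are disjoint and cover every subject
        assert not set.intersection(*holdouts)
        assert set.union(*holdouts) == set(m["subject_id"])
        for train, holdout in folds:
            assert not set(train) & set(holdout)
            # each fold holds out subjects from both capture groups
            assert {s[0] for s in holdout} == {"a", "b"}


class TestAugmentWindow:
    def identity_cfg(self):
        return AugmentConfig(crop_scale_range=(1.0, 1.0),
                             crop_aspect_range=(1.0, 1.0),
                             brightness_jitter=0.0, contrast_jitter=0.0,
                             saturation_jitter=0.0, hflip_probability=0.0)

    def test_identity_limit(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0.2, 0.8, size=(3, 32, 32)).astype(np.float32)
        out = augment_window(stack, self.identity_cfg(), rng, out_size=32)
        np.testing.assert_allclose(out, stack, atol=1e-6)

    def test_hflip_is_an_involution(self):
        cfg = AugmentConfig(crop_scale_range=(1.0, 1.0),
                            crop_aspect_range=(1.0, 1.0),
                            brightness_jitter=0.0, contrast_jitter=0.0,
                            hflip_probability=1.0)
        rng = np.random.default_rng(1)
        stack = rng.uniform(0.2, 0.8, size=(2, 16, 16)).astype(np.float32)
        once = augment_window(stack, cfg, np.random.default_rng(5), out_size=16)
        twice = augment_window(once, cfg, np.random.default_rng(5), out_size=16)
        np.testing.assert_allclose(twice, stack, atol=1e-6)

    def test_interchannel_ordering_preserved(self):
        # one shared crop/jitter/flip per window: a monotone channel pattern
        # stays monotone at every pixel
        rng = np.random.default_rng(2)
        base = rng.uniform(0.2, 0.5, size=(32, 32)).astype(np.float32)
        stack = np.stack([base + 0.04 * k for k in range(5)])
        out = augment_window(stack, AugmentConfig(), rng, out_size=32)
        assert (np.diff(out, axis=0) >= -1e-6).all()

    def test_output_size_fixed(self):
        rng = np.random.default_rng(3)
        stack = rng.uniform(size=(4, 50, 40)).astype(np.float32)
        out = augment_window(stack, AugmentConfig(), rng, out_size=32)
        assert out.shape == (4, 32, 32)


def windows_for_training(cfg, wcfg):
    videos, manifest = simulate_dataset(cfg)
    train_subj, val_subj = split_by_subject(manifest, 0.8, cfg.seed)
    tr = [w for v in videos if v.subject_id in train_subj
          for w in make_windows(v, wcfg)]
    va = [w for v in videos if v.subject_id in val_subj
          for w in make_windows(v, wcfg)]
    return tr, va


class TestTrainModel:
    def quick_cfg(self, **kw):
        defaults = dict(architecture="tiny_cnn", init="kaiming_scratch",
                        in_channels=1, max_epochs=20, early_stop_patience=19,
                        learning_rate=3e-3, input_size=48, seed=3)
        defaults.update(kw)
        return TrainConfig(**defaults)

    def separable_windows(self):
        # separable-by-mean-intensity construction: fully visible, strong
        # fluid contrast, no transient artifacts
        scfg = SyntheticConfig(image_height=48, image_width=48, fps=10.0,
                               duration_s=3.0, n_subjects=6,
                               videos_per_subject=2,
                               fluid_visibility_fraction=1.0,
                               fluid_contrast=0.7, artifact_rate=0.0, seed=3)
        return windows_for_training(scfg, WindowingConfig(window_size=1,
                                                          stride=1))

    def test_learns_separable_single_frame_task(self):
        # fully visible, high-contrast fluid: a threshold on the crescent
        # region separates classes, so the model should reach high validation
        # window accuracy quickly
        tr, va = self.separable_windows()
        _, hist = train_model(tr, va, self.quick_cfg())
        assert max(hist.val_acc) > 0.95

    def test_training_is_deterministic(self):
        tr, va = self.separable_windows()
        cfg = self.quick_cfg(max_epochs=3, early_stop_patience=2)
        _, h1 = train_model(tr, va, cfg)
        _, h2 = train_model(tr, va, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_early_stopping_and_best_weights(self):
        tr, va = self.separable_windows()
        cfg = self.quick_cfg(max_epochs=30, early_stop_patience=3)
        model, hist = train_model(tr, va, cfg)
        assert hist.n_epochs <= 30
        if hist.n_epochs < 30:  # stopped early: patience exhausted after best
            assert hist.n_epochs - 1 - hist.best_epoch >= 3
        assert hist.best_epoch == int(np.argmin(hist.val_video_loss))

    def test_empty_split_rejected(self):
        tr, va = self.separable_windows()
        with pytest.raises(ValueError):
            train_model([], va, self.quick_cfg())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            self.quick_cfg(batch_size=0)
        with pytest.raises(ValueError):
            self.quick_cfg(max_epochs=5, early_stop_patience=5)

    def test_scratch_default_epoch_cap_doubles(self):
        cfg = TrainConfig(init="kaiming_scratch")
        assert cfg.effective_max_epochs == 200
        cfg = TrainConfig(init="pretrained_inflate")
        assert cfg.effective_max_epochs == 100


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        tr, va = TestTrainModel().separable_windows()
        cfg = TestTrainModel().quick_cfg(max_epochs=2, early_stop_patience=1)
        model, _ = train_model(tr, va, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, cfg, AugmentConfig(), 1, 2)
        loaded, meta = load_checkpoint(path)
        x = np.random.default_rng(0).uniform(size=(3, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x), loaded.forward(x))
        assert meta["windowing"] == {"window_size": 1, "stride": 2}
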