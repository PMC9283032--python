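"""Classifier assembly and training: softmax contracts, determinism,
augmentation behaviour, the plateau LR rule, checkpoints, and transfer
learning."""

import numpy as np
import pytest

import tissuegrid as tg
from tissuegrid.network import ConfigError


class TestBuild:
    def test_output_is_probability_vector(self, tiny_model, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        p = tg.predict_patch(tiny_model, img)
        assert p.shape == (3,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p >= 0)

    def test_eval_mode_deterministic(self, tiny_model, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        np.testing.assert_array_equal(tg.predict_patch(tiny_model, img),
                                      tg.predict_patch(tiny_model, img))

    def test_same_seed_bit_identical_parameters(self):
        cfg = tg.ModelConfig(n_classes=3, input_size=16)
        a = tg.build_classifier(cfg, seed=5)
        b = tg.build_classifier(cfg, seed=5)
        for (ka, pa, _), (kb, pb, _) in zip(a.net.parameters(),
                                            b.net.parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa, pb)

    def test_untrained_probabilities_near_uniform_on_average(self, rng):
        cfg = tg.ModelConfig(n_classes=3, input_size=16, bilinear_m=8,
                             bilinear_k=4)
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        probs = [tg.predict_patch(tg.build_classifier(cfg, seed=s), img)
                 for s in range(100)]
        np.testing.assert_allclose(np.mean(probs, axis=0), 1 / 3, atol=0.1)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            tg.ModelConfig(n_classes=3, backbone="resnet50")
        with pytest.raises(ConfigError):
            tg.ModelConfig(n_classes=3, input_size=30)
        with pytest.raises(ConfigError):
            tg.ModelConfig(n_classes=1)

    def test_ablation_variants_change_architecture(self):
        full = tg.build_classifier(tg.ModelConfig(n_classes=2, input_size=16),
                                   seed=0)
        plain = tg.build_classifier(
            tg.ModelConfig(n_classes=2, input_size=16, use_bilinear=False,
                           use_attention=False), seed=0)
        names_full = [n for n, _ in full.net.layers]
        names_plain = [n for n, _ in plain.net.layers]
        assert "bilinear" in names_full and "attention" in names_full
        assert "bilinear" not in names_plain and "attention" not in names_plain


class TestAugment:
    def test_all_flags_off_is_identity(self, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        flags = tg.AugmentFlags(False, False, False)
        np.testing.assert_array_equal(tg.augment_patch(img, flags, rng), img)

    def test_geometric_augment_stays_in_dihedral_orbit(self, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        orbit = []
        for k in range(4):
            r = np.rot90(img, k, axes=(0, 1))
            orbit += [r, r[:, ::-1]]
        flags = tg.AugmentFlags(rotate90s=True, hflip=True)
        for _ in range(20):
            out = tg.augment_patch(img, flags, rng)
            assert out.shape == img.shape and out.dtype == img.dtype
            assert any(np.array_equal(out, o) for o in orbit)

    def test_four_quarter_rotations_return_original(self, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        out = img
        for _ in range(4):
            out = np.rot90(out, 1, axes=(0, 1))
        np.testing.assert_array_equal(out, img)

    def test_color_normalize_standardizes_channels(self, rng):
        img = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
        flags = tg.AugmentFlags(False, False, color_normalize=True)
        out = tg.augment_patch(img, flags, rng)
        np.testing.assert_allclose(out.mean(axis=(0, 1)), 0.0, atol=1e-8)
        np.testing.assert_allclose(out.std(axis=(0, 1)), 1.0, atol=1e-6)


class TestTraining:
    def test_learnable_two_class_problem_loss_decreases(self, two_class_dataset):
        tr, val = two_class_dataset
        model = tg.build_classifier(
            tg.ModelConfig(n_classes=2, input_size=32, bilinear_m=16,
                           bilinear_k=4), seed=1, class_names=tr.class_names)
        _, hist = tg.train_classifier(model, tr, val,
                                      tg.TrainConfig(epochs=10, seed=1))
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_fixed_seed_reproduces_history(self, two_class_dataset):
        tr, val = two_class_dataset
        hists = []
        for _ in range(2):
            model = tg.build_classifier(
                tg.ModelConfig(n_classes=2, input_size=32, bilinear_m=8,
                               bilinear_k=2), seed=4, class_names=tr.class_names)
            _, h = tg.train_classifier(model, tr, val,
                                       tg.TrainConfig(epochs=3, seed=4))
            hists.append(h)
        assert hists[0] == hists[1]

    def test_plateau_rule_drops_lr_by_exact_factor(self, two_class_dataset):
        """With an unreachable improvement tolerance every epoch counts as
        stale, so the LR must drop by exactly plateau_factor every
        plateau_patience epochs."""
        tr, val = two_class_dataset
        model = tg.build_classifier(
            tg.ModelConfig(n_classes=2, input_size=32, bilinear_m=8,
                           bilinear_k=2), seed=0, class_names=tr.class_names)
        cfg = tg.TrainConfig(epochs=7, seed=0, plateau_patience=3,
                             plateau_tol=10.0, lr=3e-4, plateau_factor=0.1)
        _, hist = tg.train_classifier(model, tr, val, cfg)
        np.testing.assert_allclose(
            hist["lr"], [3e-4] * 4 + [3e-5] * 3, rtol=1e-12)
        assert all(a >= b for a, b in zip(hist["lr"], hist["lr"][1:]))

    def test_empty_dataset_rejected(self, two_class_dataset):
        tr, val = two_class_dataset
        empty = tr.subset(np.array([], dtype=int))
        model = tg.build_classifier(tg.ModelConfig(n_classes=2, input_size=32),
                                    seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            tg.train_classifier(model, empty, val, tg.TrainConfig(epochs=1))

    def test_nonfinite_loss_aborts_with_diagnostic(self, two_class_dataset):
        tr, val = two_class_dataset
        model = tg.build_classifier(tg.ModelConfig(n_classes=2, input_size=32),
                                    seed=0)
        model.net["head"].params["W"][0, 0] = np.inf
        with pytest.raises(RuntimeError, match="non-finite"):
            tg.train_classifier(model, tr, val, tg.TrainConfig(epochs=1, seed=0))

    def test_predict_patch_rejects_wrong_size(self, tiny_model, rng):
        img = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="expects"):
            tg.predict_patch(tiny_model, img)


class TestCheckpointAndFineTune:
    def test_checkpoint_roundtrip_preserves_predictions(self, tmp_path,
                                                        tiny_model, rng):
        img = rng.integers(0, 255, size=(16, 16, 3), dtype=np.uint8)
        path = tg.save_checkpoint(tiny_model, tmp_path / "ckpt")
        loaded = tg.load_checkpoint(path)
        np.testing.assert_array_equal(tg.predict_patch(tiny_model, img),
                                      tg.predict_patch(loaded, img))
        assert loaded.class_names == tiny_model.class_names

    def test_finetune_zero_epochs_same_classes_is_identity(self, rng):
        specs = tg.easy_preset()[:2]
        ds = tg.generate_patch_dataset(specs, 4, 32, seed=0)
        cfg = tg.ModelConfig(n_classes=2, input_size=32, bilinear_m=8,
                             bilinear_k=2)
        src = tg.build_classifier(cfg, seed=3, class_names=ds.class_names)
        out = tg.fine_tune(src, ds, tg.TrainConfig(epochs=0, seed=0))
        img = ds.images[0]
        np.testing.assert_array_equal(tg.predict_patch(src, img),
                                      tg.predict_patch(out, img))
        assert out.config.pretrained_source == "checkpoint"

    def test_head_reinit_changes_only_head_shapes(self):
        cfg = tg.ModelConfig(n_classes=6, input_size=32, bilinear_m=8,
                             bilinear_k=2)
        src = tg.build_classifier(cfg, seed=1)
        ds = tg.generate_patch_dataset(tg.easy_preset()[:4], 3, 32, seed=0)
        out = tg.fine_tune(src, ds, tg.TrainConfig(epochs=0, seed=0))
        src_state = src.net.state_dict()
        for key, param, _ in out.net.parameters():
            if key.startswith("head."):
                assert param.shape != src_state[key].shape
            else:
                np.testing.assert_array_equal(param, src_state[key])

    def test_incompatible_backbone_checkpoint_rejected(self):
        src = tg.build_classifier(tg.ModelConfig(n_classes=2, input_size=16),
                                  seed=0)
        ds = tg.generate_patch_dataset(tg.easy_preset()[:2], 3, 32, seed=0)
        with pytest.raises(ValueError, match="patches are|incompatible"):
            tg.fine_tune(src, ds, tg.TrainConfig(epochs=1, seed=0))

    def test_pretraining_accelerates_convergence_on_new_cohort(self):
        """Fine-tuning from a model trained on one texture cohort reaches a
        fixed accuracy on a fresh cohort (same generator family, new
        palette) in fewer epochs than training from scratch."""
        from tissuegrid.synthetic import TextureClassSpec

        dsA = tg.generate_patch_dataset(tg.easy_preset(), 100, 32, seed=11)
        trA, valA = tg.stratified_split(dsA, 0.2, seed=11)
        mA = tg.build_classifier(
            tg.ModelConfig(n_classes=6, input_size=32), seed=11,
            class_names=dsA.class_names)
        mA, _ = tg.train_classifier(mA, trA, valA,
                                    tg.TrainConfig(epochs=10, seed=11))

        specsB = [
            TextureClassSpec(0, "stripes", {"orientation": (30.0, 45.0),
                                            "frequency": (0.10, 0.18),
                                            "tint": ((0.3, 0.5), (0.5, 0.7), (0.7, 0.9))}),
            TextureClassSpec(1, "blobs", {"radius": (2.0, 4.0),
                                          "tint": ((0.8, 1.0), (0.6, 0.8), (0.3, 0.5))}),
            TextureClassSpec(2, "checker", {"cell": (6.0, 10.0),
                                            "tint": ((0.7, 0.9), (0.7, 0.9), (0.3, 0.5))}),
            TextureClassSpec(3, "noise", {"noise_std": (0.05, 0.1),
                                          "tint": ((0.3, 0.5), (0.3, 0.5), (0.5, 0.7))}),
        ]
        dsB = tg.generate_patch_dataset(specsB, 50, 32, seed=12)
        trB, valB = tg.stratified_split(dsB, 0.2, seed=12)
        cfgT = tg.TrainConfig(epochs=8, seed=12)

        ft = tg.fine_tune(mA, trB, cfgT, new_val=valB)
        scratch = tg.build_classifier(
            tg.ModelConfig(n_classes=4, input_size=32), seed=12,
            class_names=dsB.class_names)
        _, hist_scratch = tg.train_classifier(scratch, trB, valB, cfgT)

        def epochs_to(acc_list, threshold=0.5):
            for i, a in enumerate(acc_list):
                if a >= threshold:
                    return i + 1
            return len(acc_list) + 1

        assert epochs_to(ft.history["val_acc"]) < epochs_to(
            hist_scratch["val_acc"])
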