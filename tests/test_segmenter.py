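"""3D U-Net segmenter: architecture contracts, training, inference."""

import dataclasses

import numpy as np
import pytest

from mslesionseg import (
    TrainConfig,
    UNetConfig,
    UNetSegmenter,
    binarize,
    build_model,
    generate_study,
    predict_volume,
    znormalize,
)
from mslesionseg.grids import VolumeGrid
from mslesionseg.nn import Adam, UNet3D, softmax, softmax_cross_entropy
from mslesionseg.segmenter import ModelCheckpoint, train


class TestUNetConfig:
    def test_depth_divisibility_contract(self):
        with pytest.raises(ValueError):
            UNetConfig(n_levels=4, patch_size=16)  # bottleneck would be 1 voxel
        with pytest.raises(ValueError):
            UNetConfig(n_levels=3, patch_size=20)  # 20 % 8 != 0
        UNetConfig(n_levels=3, patch_size=16)
        UNetConfig(n_levels=4, patch_size=32)

    def test_depth_range(self):
        with pytest.raises(ValueError):
            UNetConfig(n_levels=2, patch_size=16)


class TestBuildModel:
    def test_seeded_init_is_bit_identical(self, tiny_unet_cfg):
        a = build_model(tiny_unet_cfg, seed=3)
        b = build_model(tiny_unet_cfg, seed=3)
        assert all(np.array_equal(p, q) for (p, _), (q, _) in zip(a.params(), b.params()))
        c = build_model(tiny_unet_cfg, seed=4)
        assert any(not np.array_equal(p, q) for (p, _), (q, _) in zip(a.params(), c.params()))

    def test_forward_shape_and_softmax(self, tiny_unet_cfg):
        model = build_model(tiny_unet_cfg, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 16, 16, 16, 1)).astype(np.float32)
        logits = model.forward(x, train=False)
        assert logits.shape == (2, 16, 16, 16, 2)
        probs = softmax(logits)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)

    def test_parameter_count_monotone_in_depth(self):
        counts = [
            build_model(UNetConfig(n_levels=L, patch_size=64), seed=0).n_parameters()
            for L in (3, 4, 5)
        ]
        assert counts[0] < counts[1] < counts[2]

    def test_gradients_match_finite_differences(self):
        """Hand-written backward pass vs central differences in float64."""
        net = UNet3D(2, 1, 2, 2, seed=1).cast(np.float64)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 8, 8, 8, 1))
        y = (rng.random((2, 8, 8, 8)) > 0.7).astype(np.int64)

        def loss():
            return softmax_cross_entropy(net.forward(x, True), y)

        net.zero_grad()
        _, g = loss()
        net.backward(g)
        params = net.params()
        r2 = np.random.default_rng(3)
        for _ in range(25):
            p, grad = params[r2.integers(len(params))]
            idx = tuple(r2.integers(s) for s in p.shape)
            eps, old = 1e-6, p[idx]
            p[idx] = old + eps
            l1, _ = loss()
            p[idx] = old - eps
            l2, _ = loss()
            p[idx] = old
            num = (l1 - l2) / (2 * eps)
            if abs(num) > 1e-8:
                assert abs(num - grad[idx]) / abs(num) < 1e-5


class TestTrain:
    def test_determinism(self, ms_patches, tiny_unet_cfg):
        t = TrainConfig(epochs=2, learning_rate=1e-3, batch_size=4, seed=9)
        a = train(ms_patches[:20], t, tiny_unet_cfg)
        b = train(ms_patches[:20], t, tiny_unet_cfg)
        assert abs(a.provenance["loss_history"][-1] - b.provenance["loss_history"][-1]) < 1e-6
        assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))

    def test_loss_decreases(self, ms_checkpoint):
        h = ms_checkpoint.provenance["loss_history"]
        assert h[-1] < h[0]

    def test_single_patch_overfit(self, ms_patches, tiny_unet_cfg):
        """Gradient/architecture convergence oracle: one lesion-bearing patch
        driven by Adam at lr 1e-3 overfits to CE < 0.05 within 500 steps."""
        patch = next(p for p in ms_patches if p.label_patch.sum() > 0)
        ck = train(
            [patch], TrainConfig(epochs=500, learning_rate=1e-3, batch_size=1, seed=0), tiny_unet_cfg
        )
        h = ck.provenance["loss_history"]
        assert h[299] < 0.12  # an order of magnitude below the ~0.7 start
        assert h[499] < 0.05

    def test_empty_patches_rejected(self, tiny_unet_cfg):
        with pytest.raises(ValueError):
            train([], TrainConfig(), tiny_unet_cfg)

    def test_finetune_requires_checkpoint(self):
        with pytest.raises(ValueError):
            TrainConfig(mode="fine_tune")

    def test_finetune_architecture_mismatch(self, source_checkpoint, ms_patches):
        other = UNetConfig(n_levels=3, in_channels=1, base_features=8, out_classes=2, patch_size=16)
        with pytest.raises(ValueError):
            train(
                ms_patches[:8],
                TrainConfig(epochs=1, mode="fine_tune", init_checkpoint=source_checkpoint, learning_rate=1e-3),
                other,
            )


class TestFineTuneContract:
    def test_step0_predictions_identical_to_parent(self, source_checkpoint, ms_patches, tiny_unet_cfg, ms_study):
        """The key transfer-learning contract: before any effective gradient
        update a fine-tuned model predicts voxel-identically to its parent."""
        # lr small enough that float32 weights are bit-unchanged by the update
        ft = train(
            ms_patches[:8],
            TrainConfig(epochs=1, learning_rate=1e-30, batch_size=4, seed=0,
                        mode="fine_tune", init_checkpoint=source_checkpoint),
            tiny_unet_cfg,
        )
        vol = znormalize(ms_study.image)
        p_parent = predict_volume(source_checkpoint, vol)
        p_ft = predict_volume(ft, vol)
        assert np.array_equal(p_parent.intensities, p_ft.intensities)
        assert ft.provenance["parent"] == source_checkpoint.id


class TestPredictVolume:
    def test_output_geometry(self, source_checkpoint, ms_study):
        prob = predict_volume(source_checkpoint, znormalize(ms_study.image))
        assert prob.shape == ms_study.image.shape
        assert prob.intensities.min() >= 0 and prob.intensities.max() <= 1

    def test_constant_input_near_constant_output(self, tiny_unet_cfg):
        """Translation invariance: a constant volume maps to a near-constant
        probability map away from borders."""
        ckpt = ModelCheckpoint(build_model(tiny_unet_cfg, 0).get_weights(), tiny_unet_cfg, {"seed": 0})
        vol = VolumeGrid(np.zeros((32, 32, 32)))
        prob = predict_volume(ckpt, vol).intensities[8:-8, 8:-8, 8:-8]
        assert prob.max() - prob.min() < 0.05

    def test_small_volume_reflect_padded(self, source_checkpoint):
        vol = VolumeGrid(np.random.default_rng(0).standard_normal((10, 10, 10)))
        prob = predict_volume(source_checkpoint, vol)
        assert prob.shape == (10, 10, 10)

    def test_converged_model_dice_on_held_out(self, ms_checkpoint, ms_config):
        """End-to-end smoke benchmark: a converged model generalizes to
        held-out phantoms with Dice > 0.5 in the majority of replicates."""
        from mslesionseg import dice_score

        wins = 0
        for seed in (50, 51, 52):
            test = generate_study(ms_config, seed)
            mask = binarize(predict_volume(ms_checkpoint, znormalize(test.image)), 0.5)
            if dice_score(mask, test.lesion_mask) > 0.5:
                wins += 1
        assert wins >= 2


class TestBinarize:
    def test_extremes_and_threshold(self):
        zeros = VolumeGrid(np.zeros((4, 4, 4)))
        ones = VolumeGrid(np.ones((4, 4, 4)))
        assert binarize(zeros).labels.sum() == 0
        assert binarize(ones).labels.sum() == 64
        mixed = VolumeGrid(np.array([0.4, 0.6] * 32).reshape(4, 4, 4))
        out = binarize(mixed, 0.5)
        assert set(np.unique(out.labels)) == {0, 1}
        assert out.labels.sum() == 32

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            binarize(VolumeGrid(np.zeros((2, 2, 2))), 1.5)


class TestCheckpoint:
    def test_save_load_round_trip(self, source_checkpoint, tmp_path):
        path = tmp_path / "model.ckpt"
        source_checkpoint.save(path)
        loaded = ModelCheckpoint.load(path)
        assert loaded.id == source_checkpoint.id
        assert all(np.array_equal(a, b) for a, b in zip(loaded.weights, source_checkpoint.weights))
        assert loaded.config == source_checkpoint.config


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = UNetSegmenter(n_levels=3, base_features=4, patch_size=16, epochs=2, learning_rate=1e-3)
        params = est.get_params()
        assert params["n_levels"] == 3
        est.set_params(epochs=5)
        assert est.epochs == 5

    def test_fit_predict(self, ms_patches, ms_study):
        est = UNetSegmenter(
            n_levels=3, base_features=4, patch_size=16, epochs=2, learning_rate=1e-3, seed=0
        )
        est.fit(ms_patches[:12])
        assert len(est.loss_history_) == 2
        mask = est.predict(znormalize(ms_study.image))
        assert mask.shape == ms_study.image.shape

    def test_unfitted_raises(self, ms_study):
        with pytest.raises(RuntimeError):
            UNetSegmenter().predict_proba(znormalize(ms_study.image))
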