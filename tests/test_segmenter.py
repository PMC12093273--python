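"""Segmentation network: window geometry, attention oracle, loss, training."""

import numpy as np
import pytest

from somamapper.metrics import dice as dice_score
from somamapper.nn import Tensor
from somamapper.segmenter import (
    SegmenterConfig,
    SegMask,
    SwinSubLayer,
    WindowAttention,
    augment,
    build_segmenter,
    dice_loss,
    lr_at_epoch,
    train_segmenter,
    window_partition,
    window_reverse,
)
from tests.conftest import phantom_block


def tiny_cfg(**overrides):
    base = dict(K=8, window=(2, 2, 2), heads=2, crop=16, seed=0)
    base.update(overrides)
    return SegmenterConfig(**base)


class TestWindowGeometry:
    def test_partition_reverse_exact_inverse_on_integers(self):
        rng = np.random.default_rng(0)
        x = Tensor(rng.integers(0, 100, (2, 4, 6, 4, 3)).astype(np.float32))
        back = window_reverse(window_partition(x, (2, 3, 2)), (2, 3, 2), x.shape)
        assert np.array_equal(back.data, x.data)

    def test_cyclic_shift_unshift_identity(self):
        rng = np.random.default_rng(1)
        x = Tensor(rng.integers(0, 100, (1, 4, 4, 4, 2)).astype(np.float32))
        s = (1, 2, 1)
        back = x.roll(tuple(-v for v in s), axis=(1, 2, 3)).roll(s, axis=(1, 2, 3))
        assert np.array_equal(back.data, x.data)

    def test_partition_rejects_indivisible(self):
        with pytest.raises(ValueError):
            window_partition(Tensor(np.zeros((1, 5, 4, 4, 2))), (2, 2, 2))


class TestAttention:
    def test_full_window_equals_direct_attention(self):
        """W-MSA over one full-extent window must equal plain self-attention."""
        rng = np.random.default_rng(2)
        dim, heads, t = 8, 2, 4 * 4 * 4
        attn = WindowAttention(dim, (4, 4, 4), heads, rel_pos_bias=False, rng=rng)
        x = rng.standard_normal((1, t, dim)).astype(np.float32)
        out = attn(Tensor(x)).data[0]

        q = x[0] @ attn.q.weight.data + attn.q.bias.data
        k = x[0] @ attn.k.weight.data + attn.k.bias.data
        v = x[0] @ attn.v.weight.data + attn.v.bias.data
        dk = dim // heads
        merged = np.zeros((t, dim), np.float32)
        for h in range(heads):
            qh = q[:, h * dk:(h + 1) * dk] * attn.scale
            kh = k[:, h * dk:(h + 1) * dk]
            vh = v[:, h * dk:(h + 1) * dk]
            logits = qh @ kh.T
            weights = np.exp(logits - logits.max(axis=1, keepdims=True))
            weights /= weights.sum(axis=1, keepdims=True)
            merged[:, h * dk:(h + 1) * dk] = weights @ vh
        expected = merged @ attn.proj.weight.data + attn.proj.bias.data
        assert np.abs(out - expected).max() < 1e-5

    def test_full_extent_shifted_sublayer_equals_unshifted(self):
        """When the window spans the feature, the shift is a no-op."""
        rng = np.random.default_rng(3)
        x = Tensor(rng.standard_normal((1, 4, 4, 4, 8)).astype(np.float32))
        plain = SwinSubLayer(8, (4, 4, 4), 2, 2.0, shifted=False,
                             rel_pos_bias=True, rng=np.random.default_rng(9))
        shifted = SwinSubLayer(8, (4, 4, 4), 2, 2.0, shifted=True,
                               rel_pos_bias=True, rng=np.random.default_rng(9))
        assert np.allclose(plain(x).data, shifted(x).data, atol=1e-5)

    def test_window_larger_than_feature_rejected(self):
        layer = SwinSubLayer(8, (8, 8, 8), 2, 2.0, shifted=False,
                             rel_pos_bias=False, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer(Tensor(np.zeros((1, 4, 4, 4, 8))))


class TestNetworkContracts:
    @pytest.mark.parametrize("shape", [(16, 16, 16), (16, 16, 32)])
    def test_output_shape_matches_input(self, shape):
        model = build_segmenter(tiny_cfg())
        x = Tensor(np.random.default_rng(0).random((1, 1) + shape).astype(np.float32))
        out = model(x)
        assert out.shape == (1, 1) + shape
        assert (out.data > 0).all() and (out.data < 1).all()  # sigmoid head

    def test_rejects_indivisible_input(self):
        model = build_segmenter(tiny_cfg())
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 1, 12, 16, 16))))
        with pytest.raises(ValueError):  # 1/8 scale not divisible by window
            model(Tensor(np.zeros((1, 1, 8, 16, 16))))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SegmenterConfig(K=8, heads=3)
        with pytest.raises(ValueError):
            SegmenterConfig(crop=30)


class TestDiceLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((4, 4, 4), np.float32)
        t[:2] = 1
        assert float(dice_loss(Tensor(t), t).data) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_prediction_near_one(self):
        t = np.zeros((4, 4, 4), np.float32)
        t[:2] = 1
        assert float(dice_loss(Tensor(1 - t), t).data) == pytest.approx(1.0, abs=1e-4)

    def test_hand_computed_half_overlap(self):
        """Uniform 0.5 prediction vs 4 foreground voxels on a 2x2x2 grid:
        1 - (2*0.5*4)/(0.5*8 + 4) = 0.5."""
        pred = Tensor(np.full((2, 2, 2), 0.5, np.float32))
        target = np.zeros((2, 2, 2), np.float32)
        target[0] = 1
        assert float(dice_loss(pred, target).data) == pytest.approx(0.5, abs=1e-4)

    def test_binary_pred_consistent_with_dice_metric(self):
        rng = np.random.default_rng(5)
        pred = (rng.random((6, 6, 6)) > 0.5).astype(np.float32)
        target = (rng.random((6, 6, 6)) > 0.5).astype(np.float32)
        loss = float(dice_loss(Tensor(pred), target).data)
        assert loss == pytest.approx(1.0 - dice_score(pred, target), abs=1e-4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(Tensor(np.zeros((2, 2, 2))), np.zeros((2, 2, 4)))


class TestAugment:
    def test_double_flip_is_identity(self):
        rng_img = np.random.default_rng(6)
        img = rng_img.random((8, 8, 8)).astype(np.float32)

        class AlwaysFlip:
            def integers(self, lo, hi):
                return 0

            def random(self):
                return 0.0  # < flip_prob -> always flip

        once_i, once_l = augment(img, img, 8, 1.0, AlwaysFlip())
        twice_i, _ = augment(once_i, once_l, 8, 1.0, AlwaysFlip())
        assert np.array_equal(twice_i, img)

    def test_crop_equal_size_is_identity_modulo_flips(self):
        img = np.random.default_rng(7).random((8, 8, 8)).astype(np.float32)
        out_i, out_l = augment(img, img, 8, 0.0, np.random.default_rng(0))
        assert np.array_equal(out_i, img)
        assert np.array_equal(out_i, out_l)

    def test_seeded_determinism_and_joint_transform(self):
        img = np.random.default_rng(8).random((12, 12, 12)).astype(np.float32)
        lab = (img > 0.5).astype(np.float32)
        a_i, a_l = augment(img, lab, 8, 0.5, np.random.default_rng(42))
        b_i, b_l = augment(img, lab, 8, 0.5, np.random.default_rng(42))
        assert np.array_equal(a_i, b_i) and np.array_equal(a_l, b_l)
        assert np.array_equal(a_l, (a_i > 0.5).astype(np.float32))

    def test_oversized_crop_rejected(self):
        img = np.zeros((8, 8, 8), np.float32)
        with pytest.raises(ValueError):
            augment(img, img, 16, 0.5, np.random.default_rng(0))


class TestTraining:
    def test_lr_schedule_arithmetic(self):
        """10% decay every 10 epochs: epoch 25 runs at 1e-4 * 0.9**2."""
        assert lr_at_epoch(1e-4, 25, (0.9, 10)) == pytest.approx(8.1e-5)
        assert lr_at_epoch(1e-4, 1, (0.9, 10)) == pytest.approx(1e-4)
        assert lr_at_epoch(1e-4, 10, (0.9, 10)) == pytest.approx(1e-4)
        assert lr_at_epoch(1e-4, 11, (0.9, 10)) == pytest.approx(9e-5)

    def test_constant_dice_stops_at_patience_plus_one(self):
        """With a vanishing learning rate the validation Dice never moves,
        so training halts at epoch patience + 1."""
        cfg = tiny_cfg(crop=8, lr=1e-12, max_epochs=40, iters_per_epoch=1,
                       patience=5, window=(1, 1, 1), heads=1)
        model = build_segmenter(cfg)
        vol = np.random.default_rng(0).random((8, 8, 8)).astype(np.float32)
        lab = (vol > 0.7).astype(np.float32)
        _, history = train_segmenter(model, [(vol, lab)], [(vol, lab)], cfg)
        assert len(history) == cfg.patience + 1

    def test_empty_sets_rejected(self):
        cfg = tiny_cfg()
        model = build_segmenter(cfg)
        with pytest.raises(ValueError):
            train_segmenter(model, [], [phantom_block(0)], cfg)

    def test_heldout_dice_above_threshold(self, trained_segmenter, seg_dataset):
        model, history = trained_segmenter
        assert len(history) <= 30
        dices = []
        for vol, lab in seg_dataset["test"]:
            mask = model.predict_mask(vol)
            assert isinstance(mask, SegMask)
            dices.append(dice_score(mask.data, lab))
        assert float(np.mean(dices)) >= 0.7

    def test_training_loss_trends_down(self, trained_segmenter):
        _, history = trained_segmenter
        losses = [h["train_loss"] for h in history]
        assert losses[4] < losses[0]

    def test_checkpoint_roundtrip(self, trained_segmenter, tmp_path):
        model, _ = trained_segmenter
        vol = phantom_block(999)[0]
        before = model.predict_mask(vol).data
        path = tmp_path / "seg.npz"
        model.save(path, config={"K": model.cfg.K})
        fresh = build_segmenter(model.cfg)
        fresh.load(path)
        assert np.array_equal(fresh.predict_mask(vol).data, before)
        assert (tmp_path / "seg.json").exists()
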