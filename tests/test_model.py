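"""U-Net architecture, dice loss, backprop correctness, inference."""

import numpy as np
import pytest

from cmapaug.model import (SegModelConfig, TrainConfig, build_model, dice_loss,
                           dice_loss_grad, load_checkpoint, predict_volume,
                           save_checkpoint, train_step)
from cmapaug.nn import Adam, sigmoid
from cmapaug.preprocessing import GrayVolume


class TestArchitecture:
    @pytest.mark.parametrize("stages,size,channels", [
        (5, 64, 3), (2, 64, 1), (3, 32, 1)])
    def test_output_preserves_spatial_size(self, stages, size, channels, rng):
        model = build_model(SegModelConfig(stages=stages, base_width=4,
                                           in_channels=channels), seed=0)
        x = rng.random((2, channels, size, size)).astype(np.float32)
        assert model.forward(x, train=False).shape == (2, 1, size, size)

    def test_indivisible_input_rejected(self, rng):
        model = build_model(SegModelConfig(stages=3, base_width=4), seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.random((1, 1, 30, 30)).astype(np.float32))

    def test_parameter_count_matches_closed_form(self):
        cfg = SegModelConfig(stages=2, base_width=4, in_channels=1)
        model = build_model(cfg, seed=0)
        # independent sum over layers: conv = Co*Ci*9 + Co, bn = 2*C,
        # transposed conv = Ci*Co*4 + Co, head = Ci*Co + Co
        def conv(ci, co):
            return co * ci * 9 + co

        def bn(c):
            return 2 * c

        expected = (
            conv(1, 4) + bn(4) + conv(4, 4) + bn(4)          # encoder stage 1
            + conv(4, 8) + bn(8) + conv(8, 8) + bn(8)        # bottleneck
            + 8 * 4 * 4 + 4                                   # up-convolution
            + conv(8, 4) + bn(4) + conv(4, 4) + bn(4)        # decoder stage
            + 4 * 1 + 1                                       # 1x1 head
        )
        assert model.n_parameters() == expected

    def test_same_seed_same_forward(self, rng):
        x = rng.random((1, 1, 16, 16)).astype(np.float32)
        y1 = build_model(SegModelConfig(stages=2, base_width=4), seed=5).forward(
            x, train=False)
        y2 = build_model(SegModelConfig(stages=2, base_width=4), seed=5).forward(
            x, train=False)
        assert np.array_equal(y1, y2)


class TestDiceLoss:
    def test_perfect_overlap_is_zero(self):
        target = np.zeros((1, 1, 4, 4))
        target[..., :2] = 1
        assert dice_loss(target, target) == pytest.approx(0.0, abs=1e-6)

    def test_complement_is_one(self):
        target = np.zeros((1, 1, 4, 4))
        target[..., :2] = 1
        assert dice_loss(1 - target, target) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_half_prediction_hand_value(self):
        # pred uniformly 0.5 on 4 pixels, target has 2 ones:
        # intersection = 1.0, sums = 2 + 2 -> loss = 1 - 2/4 = 0.5
        pred = np.full((1, 1, 2, 2), 0.5)
        target = np.array([[[[1.0, 1.0], [0.0, 0.0]]]])
        assert dice_loss(pred, target) == pytest.approx(0.5, abs=1e-6)

    def test_symmetric_and_bounded_for_binary_inputs(self, rng):
        a = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        b = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        assert dice_loss(a, b) == pytest.approx(dice_loss(b, a))
        assert 0.0 <= dice_loss(a, b) <= 1.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 2, 2)))

    def test_gradient_matches_finite_differences(self, rng):
        pred = rng.random((1, 1, 4, 4))
        target = (rng.random((1, 1, 4, 4)) > 0.5).astype(float)
        _, grad = dice_loss_grad(pred, target)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 0, 1, 2), (0, 0, 3, 3)]:
            plus = pred.copy()
            plus[idx] += eps
            minus = pred.copy()
            minus[idx] -= eps
            numeric = (dice_loss(plus, target) - dice_loss(minus, target)) / (2 * eps)
            assert grad[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


def test_backprop_matches_numerical_gradients(rng):
    """End-to-end finite-difference check through conv/BN/pool/up-conv."""
    model = build_model(SegModelConfig(stages=3, base_width=2), seed=1)
    x = rng.random((2, 1, 16, 16)).astype(np.float32)
    target = (rng.random((2, 1, 16, 16)) > 0.5).astype(np.float32)

    def loss_value():
        probs = sigmoid(model.forward(x, train=True))
        return dice_loss_grad(probs, target)[0]

    probs = sigmoid(model.forward(x, train=True))
    _, dprobs = dice_loss_grad(probs, target)
    optimizer = Adam(model.parameters())
    optimizer.zero_grad()
    model.backward((dprobs * probs * (1 - probs)).astype(np.float32))

    params = model.parameters()
    checked = 0
    for pi in rng.choice(len(params), size=10, replace=False):
        arr, grad = params[pi]
        idx = tuple(rng.integers(0, s) for s in arr.shape)
        analytic = float(grad[idx])
        if abs(analytic) < 1e-3:  # below float32 finite-difference noise
            continue
        eps = 1e-3
        original = arr[idx]
        arr[idx] = original + eps
        plus = loss_value()
        arr[idx] = original - eps
        minus = loss_value()
        arr[idx] = original
        numeric = (plus - minus) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=0.05, abs=1e-4)
        checked += 1
    assert checked >= 3


class TestInference:
    def test_volume_prediction_preserves_depth(self, rng):
        model = build_model(SegModelConfig(stages=2, base_width=4), seed=0)
        vol = GrayVolume(voxels=rng.random((5, 16, 16)).astype(np.float32),
                         patient_id="p")
        pred = predict_volume(model, vol)
        assert pred.voxels.shape == (5, 16, 16)
        assert set(np.unique(pred.voxels)) <= {0, 1}
        assert pred.patient_id == "p"

    def test_channel_mismatch_rejected(self, rng):
        model = build_model(SegModelConfig(stages=2, base_width=4,
                                           in_channels=3), seed=0)
        with pytest.raises(ValueError):
            predict_volume(model, rng.random((2, 16, 16)))

    def test_prediction_is_deterministic(self):
        model = build_model(SegModelConfig(stages=2, base_width=4), seed=2)
        zeros = np.zeros((3, 16, 16), dtype=np.float32)
        a = predict_volume(model, zeros)
        b = predict_volume(model, zeros)
        assert np.array_equal(a.voxels, b.voxels)


def test_checkpoint_roundtrip(tmp_path, rng):
    model = build_model(SegModelConfig(stages=2, base_width=4), seed=3)
    x = rng.random((4, 16, 16)).astype(np.float32)
    before = predict_volume(model, x).voxels
    save_checkpoint(tmp_path / "model.npz", model, TrainConfig(epochs=1),
                    extra={"strategy": "baseline"})
    restored, meta = load_checkpoint(tmp_path / "model.npz")
    assert meta["extra"]["strategy"] == "baseline"
    assert meta["model_config"]["stages"] == 2
    assert np.array_equal(predict_volume(restored, x).voxels, before)


def test_short_training_reduces_dice_loss(rng):
    """Learnability: a few dozen steps on one slice make clear progress."""
    model = build_model(SegModelConfig(stages=3, base_width=8), seed=0)
    optimizer = Adam(model.parameters(), lr=1e-2)
    image = rng.random((1, 1, 32, 32)).astype(np.float32)
    mask = np.zeros((1, 1, 32, 32), dtype=np.float32)
    mask[..., 8:24, 8:24] = 1
    losses = [train_step(model, optimizer, image, mask) for _ in range(60)]
    assert losses[-1] < 0.5 * losses[0]
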