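"""Augmentation stack: configuration fidelity, stochastic contracts,
geometric/intensity oracles."""

import numpy as np
import pytest

from cmapaug.augment import (AugmentationStrategy, OneOfGroup, TransformSpec,
                             apply_stack, apply_transform,
                             augment_training_sample, builtin_strategy,
                             flatten_stack, load_strategy_file,
                             make_bigaug_stack, make_exaug_stack,
                             save_strategy_file)
from cmapaug.colormaps import apply_colormap, default_package, draw_training_map


@pytest.fixture()
def sample(rng):
    image = rng.random((32, 32))
    mask = np.zeros((32, 32), dtype=np.uint8)
    mask[10:20, 12:22] = 1
    return image, mask


class TestExaugConfiguration:
    def test_fourteen_members_in_tabulated_order(self):
        names = [t.name for t in flatten_stack(make_exaug_stack().stack)]
        assert names == [
            "centercrop_resize", "rotation", "affine_scale",
            "affine_translate", "optical_distortion", "elastic",
            "sharpen", "gaussian_blur", "gaussian_noise", "motion_blur",
            "intensity_shift",
            "brightness_contrast", "gamma", "color_jitter",
        ]

    def test_rotation_entry(self):
        rotation = make_exaug_stack().stack[1]
        assert rotation.name == "rotation"
        assert rotation.probability == 0.5
        assert rotation.param_dict()["angle"] == (-10.0, 10.0)

    def test_elastic_entry_carries_fixed_alpha_sigma(self):
        elastic = make_exaug_stack().stack[5]
        params = elastic.param_dict()
        assert params["alpha"] == 4.0
        assert params["sigma"] == 2.0
        assert params["alpha_affine"] == (-2.0, 2.0)

    def test_oneof_groups(self):
        stack = make_exaug_stack().stack
        quality, final = stack[6], stack[8]
        assert isinstance(quality, OneOfGroup) and quality.probability == 0.5
        assert [m.probability for m in quality.members] == [0.3, 0.2, 0.3, 0.2]
        assert isinstance(final, OneOfGroup)
        assert [m.name for m in final.members] == [
            "brightness_contrast", "gamma", "color_jitter"]

    def test_bigaug_loads(self):
        strategy = make_bigaug_stack()
        assert strategy.name == "bigaug"
        assert len(strategy.stack) > 0

    def test_strategy_file_roundtrip(self, tmp_path):
        strategy = make_exaug_stack()
        path = tmp_path / "exaug.cfg"
        save_strategy_file(strategy, path)
        assert load_strategy_file(path) == strategy


class TestStochasticContracts:
    def test_zero_probability_is_bitwise_identity(self, sample, rng):
        image, mask = sample
        stack = tuple(
            TransformSpec(t.name, 0.0, t.params)
            for t in flatten_stack(make_exaug_stack().stack)
            if t.name != "color_jitter"
        )
        out_img, out_mask = apply_stack(
            AugmentationStrategy("noop", stack), image, mask, rng)
        assert out_img is image or np.array_equal(out_img, image)
        assert np.array_equal(out_mask, mask)

    def test_seeded_stack_is_reproducible(self, sample):
        image, mask = sample
        strategy = builtin_strategy("exaug+cmapaug")
        pkg = default_package()
        out1 = augment_training_sample(strategy, pkg, image, mask,
                                       np.random.default_rng(11))
        out2 = augment_training_sample(strategy, pkg, image, mask,
                                       np.random.default_rng(11))
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_mask_binary_and_image_in_range(self, sample, seed):
        image, mask = sample
        strategy = builtin_strategy("exaug+cmapaug")
        out_img, out_mask = augment_training_sample(
            strategy, default_package(), image, mask,
            np.random.default_rng(seed))
        assert set(np.unique(out_mask)) <= {0, 1}
        assert out_img.min() >= 0.0 and out_img.max() <= 1.0
        assert out_img.shape[:2] == mask.shape

    def test_shape_mismatch_rejected(self, rng):
        spec = TransformSpec("rotation", 1.0, (("angle", (-10.0, 10.0)),))
        with pytest.raises(ValueError):
            apply_transform(spec, np.zeros((8, 8)), np.zeros((4, 4), np.uint8), rng)


class TestTransformOracles:
    def test_forced_translate_moves_hot_pixel_exactly(self, rng):
        image = np.zeros((32, 32))
        image[10, 12] = 1.0
        mask = (image > 0).astype(np.uint8)
        spec = TransformSpec("affine_translate", 0.0, (("px", 5.0),))
        out_img, out_mask = apply_transform(spec, image, mask, rng, force=True)
        assert out_img[15, 17] == pytest.approx(1.0)
        assert np.argwhere(out_mask).tolist() == [[15, 17]]

    def test_forced_rotation_quarter_turn_matches_rot90(self, sample, rng):
        image, mask = sample
        spec = TransformSpec("rotation", 0.0, (("angle", 90.0),))
        out_img, out_mask = apply_transform(spec, image, mask, rng, force=True)
        assert np.array_equal(out_mask, np.rot90(mask, -1))
        assert np.allclose(out_img, np.rot90(image, -1), atol=1e-6)

    def test_deterministic_pair_composes_in_order(self, rng):
        image = np.zeros((32, 32))
        image[10:14, 10:14] = np.arange(16).reshape(4, 4) / 16.0
        mask = (image > 0).astype(np.uint8)
        t1 = TransformSpec("affine_translate", 1.0, (("px", 3.0),))
        t2 = TransformSpec("affine_translate", 1.0, (("px", 4.0),))
        stacked = apply_stack(AugmentationStrategy("two", (t1, t2)),
                              image, mask, rng)
        direct = apply_transform(
            TransformSpec("affine_translate", 1.0, (("px", 7.0),)),
            image, mask, rng, force=True)
        assert np.allclose(stacked[0], direct[0], atol=1e-12)
        assert np.array_equal(stacked[1], direct[1])

    @pytest.mark.parametrize("spec", [
        TransformSpec("sharpen", 0.0, (("alpha", 0.2),)),
        TransformSpec("gaussian_blur", 0.0, (("sigma", 1.0),)),
        TransformSpec("gaussian_noise", 0.0, (("var", 0.01),)),
        TransformSpec("motion_blur", 0.0, (("ksize", 5.0),)),
        TransformSpec("intensity_shift", 0.0, (("shift", 0.07),)),
        TransformSpec("brightness_contrast", 0.0,
                      (("brightness", 0.1), ("contrast", 0.0))),
        TransformSpec("gamma", 0.0, (("gamma", 70.0),)),
    ], ids=lambda s: s.name)
    def test_intensity_transforms_leave_mask_untouched(self, sample, rng, spec):
        image, mask = sample
        out_img, out_mask = apply_transform(spec, image, mask, rng, force=True)
        assert np.array_equal(out_mask, mask)
        assert not np.array_equal(out_img, image) or spec.name == "motion_blur"

    def test_gamma_100_is_identity(self, sample, rng):
        image, mask = sample
        spec = TransformSpec("gamma", 0.0, (("gamma", 100.0),))
        out_img, _ = apply_transform(spec, image, mask, rng, force=True)
        assert np.allclose(out_img, image)

    def test_color_jitter_identity_factors(self, rng):
        image = rng.random((16, 16, 3))
        mask = np.zeros((16, 16), np.uint8)
        spec = TransformSpec("color_jitter", 0.0, (
            ("brightness", 1.0), ("contrast", 1.0),
            ("saturation", 1.0), ("hue", 0.0)))
        out_img, _ = apply_transform(spec, image, mask, rng, force=True)
        assert np.allclose(out_img, image, atol=1e-12)


class TestStrategies:
    def test_baseline_is_passthrough(self, sample, rng):
        image, mask = sample
        out = augment_training_sample(builtin_strategy("baseline"), None,
                                      image, mask, rng)
        assert np.array_equal(out[0], image)
        assert np.array_equal(out[1], mask)

    def test_cmapaug_reduces_to_seeded_colormap_draw(self, sample):
        image, mask = sample
        pkg = default_package()
        out_img, out_mask = augment_training_sample(
            builtin_strategy("cmapaug"), pkg, image, mask,
            np.random.default_rng(3))
        expected = apply_colormap(
            image, draw_training_map(pkg, np.random.default_rng(3))).pixels
        assert np.array_equal(out_img, expected)
        assert np.array_equal(out_mask, mask)

    def test_exaug_alone_replicates_gray_to_rgb(self, sample):
        image, mask = sample
        out_img, _ = augment_training_sample(
            builtin_strategy("exaug"), None, image, mask,
            np.random.default_rng(0))
        assert out_img.ndim == 3 and out_img.shape[-1] == 3

    @pytest.mark.parametrize("name", ["styleaug", "bigaug+styleaug",
                                      "exaug+styleaug"])
    def test_style_transfer_slots_are_placeholders(self, name):
        with pytest.raises(NotImplementedError):
            builtin_strategy(name)

    def test_unknown_strategy_rejected(self):
        with pytest.raises(KeyError):
            builtin_strategy("mixup")
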