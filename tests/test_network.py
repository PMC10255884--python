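"""Architecture contracts of the segmentation network: receptive-field
arithmetic, DAC/RMP block behavior, pyramid shapes and whole-image
prediction.  Shape contracts are exercised on width-reduced models; the
full-width checks live in the acceptance suite."""

import numpy as np
import pytest

from marblingnet import autograd as ag
from marblingnet.network import (DacBlock, MarblingNet, ModelConfig, RmpBlock,
                                 load_checkpoint, predict_image, receptive_field,
                                 save_checkpoint)


class TestReceptiveField:
    @pytest.mark.parametrize("stack,expected", [
        ([(3, 1)], 3),
        ([(3, 3)], 7),
        ([(3, 1), (3, 3)], 9),
        ([(3, 1), (3, 3), (3, 5)], 19),
        ([(1, 1)], 1),
        ([], 1),
    ])
    def test_cascade_arithmetic(self, stack, expected):
        assert receptive_field(stack) == expected

    def test_invalid_kernels_rejected(self):
        with pytest.raises(ValueError):
            receptive_field([(2, 1)])
        with pytest.raises(ValueError):
            receptive_field([(3, 0)])

    def test_configured_branches_realize_published_fields(self):
        cfg = ModelConfig()
        fields = [receptive_field([(3, r) for r in rates])
                  for rates in cfg.dac_branch_rates]
        assert fields == [3, 7, 9, 19]


class TestBlocks:
    def test_dac_zero_weights_is_residual_identity(self, rng):
        block = DacBlock(8, [(1,), (3,), (1, 3)], np.random.default_rng(0))
        for _, p in block.named_parameters():
            p.data[:] = 0
        x = rng.normal(0, 1, (2, 8, 12, 12)).astype(np.float32)
        out = block(ag.Tensor(x))
        np.testing.assert_array_equal(out.data, x)

    def test_dac_preserves_shape(self, rng):
        block = DacBlock(8, ModelConfig().dac_branch_rates, np.random.default_rng(0))
        x = rng.normal(0, 1, (1, 8, 16, 16)).astype(np.float32)
        assert block(ag.Tensor(x)).data.shape == (1, 8, 16, 16)

    def test_rmp_appends_four_channels(self, rng):
        block = RmpBlock(16, [2, 3, 5, 6], np.random.default_rng(0))
        x = rng.normal(0, 1, (2, 16, 10, 14)).astype(np.float32)
        out = block(ag.Tensor(x))
        assert out.data.shape == (2, 20, 10, 14)

    def test_rmp_constant_plane_pools_to_constant(self):
        block = RmpBlock(1, [2, 3, 5, 6], np.random.default_rng(0))
        x = np.full((1, 1, 12, 12), 3.0, np.float32)
        out = block(ag.Tensor(x)).data
        for ch in range(1, 5):  # each pooled-and-resized branch plane
            plane = out[0, ch]
            assert np.allclose(plane, plane.flat[0], atol=1e-5)

    def test_rmp_rejects_too_small_input(self):
        block = RmpBlock(4, [2, 3, 5, 6], np.random.default_rng(0))
        with pytest.raises(ValueError):
            block(ag.Tensor(np.zeros((1, 4, 5, 5), np.float32)))


@pytest.fixture(scope="module")
def tiny():
    return MarblingNet(ModelConfig.scaled(base_width=2, seed=0))


class TestModel:
    def test_output_side_is_input_times_upsample_factor(self, tiny):
        x = np.random.default_rng(0).random((1, 3, 40, 40), dtype=np.float32)
        with ag.no_grad():
            out = tiny.eval().forward(x)
        assert out.data.shape == (1, 2, 80, 80)

    def test_encoder_pyramid_halves_and_doubles(self, tiny):
        x = np.random.default_rng(0).random((1, 3, 40, 40), dtype=np.float32)
        with ag.no_grad():
            _, feats = tiny.eval().forward(x, return_features=True)
        assert [f.data.shape[2] for f in feats] == [80, 40, 20, 10]
        assert [f.data.shape[1] for f in feats] == [2, 4, 8, 16 + 4]

    def test_batching_preserves_per_sample_outputs(self, tiny):
        rng = np.random.default_rng(1)
        xs = rng.random((4, 3, 24, 24), dtype=np.float32)
        with ag.no_grad():
            batch = tiny.eval().forward(xs).data
            singles = [tiny.forward(xs[i:i + 1]).data[0] for i in range(4)]
        for i in range(4):
            np.testing.assert_allclose(batch[i], singles[i], atol=2e-4)

    def test_eval_forward_is_deterministic(self, tiny):
        x = np.random.default_rng(2).random((1, 3, 24, 24), dtype=np.float32)
        with ag.no_grad():
            a = tiny.eval().forward(x).data
            b = tiny.eval().forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_without_context_module_reduces_to_unet(self):
        net = MarblingNet(ModelConfig.scaled(base_width=2, use_context_module=False,
                                             seed=0))
        assert not hasattr(net, "dac") and not hasattr(net, "rmp")
        x = np.random.default_rng(0).random((1, 3, 24, 24), dtype=np.float32)
        with ag.no_grad():
            _, feats = net.eval().forward(x, return_features=True)
        assert [f.data.shape[1] for f in feats] == [2, 4, 8, 16]

    def test_parameter_count_invariant_to_input_size(self, tiny):
        n0 = tiny.num_parameters()
        for side in (24, 40):
            with ag.no_grad():
                tiny.eval().forward(np.zeros((1, 3, side, side), np.float32))
        assert tiny.num_parameters() == n0

    def test_non_divisible_sides_padded_and_cropped(self, tiny):
        x = np.random.default_rng(3).random((1, 3, 25, 37), dtype=np.float32)
        with ag.no_grad():
            out = tiny.eval().forward(x)
        assert out.data.shape == (1, 2, 50, 74)

    def test_full_width_parameter_count_order_of_magnitude(self):
        """The published model size is ~31 M parameters; the default
        configuration lands in the same order (about 28 M here)."""
        n = MarblingNet(ModelConfig(seed=0)).num_parameters()
        assert 2e7 < n < 4e7

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ModelConfig(upsample_factor=3)
        with pytest.raises(ValueError):
            ModelConfig(decoder_channels=[64, 32])  # stages != blocks - 1


class TestPredictImage:
    def test_mask_matches_image_resolution(self, tiny_net_and_image):
        net, image = tiny_net_and_image
        mask = predict_image(net, image)
        assert mask.shape == image.shape[:2]
        assert set(np.unique(mask)) <= {0, 1}

    def test_tied_scores_break_to_background(self):
        net = MarblingNet(ModelConfig.scaled(base_width=2, seed=0))
        for _, p in net.named_parameters():
            p.data[:] = 0  # all-zero head -> exactly tied class scores
        image = np.zeros((24, 48, 3), np.uint8)
        assert predict_image(net, image).sum() == 0

    def test_checkpoint_round_trip_reproduces_predictions(self, tmp_path,
                                                          tiny_net_and_image):
        net, image = tiny_net_and_image
        before = predict_image(net, image)
        save_checkpoint(net, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(predict_image(restored, image), before)
        assert restored.cfg.encoder == net.cfg.encoder


@pytest.fixture(scope="module")
def tiny_net_and_image():
    net = MarblingNet(ModelConfig.scaled(base_width=2, seed=1))
    image = np.random.default_rng(4).integers(0, 256, (32, 48, 3), dtype=np.uint8)
    return net, image
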