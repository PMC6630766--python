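"""Architecture contracts: residual unit, encoder, FPA, full model, params."""

import numpy as np
import pytest

from paraseg import nn
from paraseg.network import (FPA, NetworkConfig, ResidualBlock, build_encoder,
                             build_fpa, build_network, conv_param_count,
                             count_parameters, fpa_pyramid_sides, predict_proba)
from paraseg.nn import autodiff as ad


class TestResidualBlock:
    def test_zero_weights_give_identity_on_nonnegative_input(self, rng):
        block = ResidualBlock(4, 4, norm="none", rng=np.random.default_rng(0))
        for p in block.parameters():
            p.data = np.zeros_like(p.data)
        x = rng.random((1, 4, 8, 8)).astype(np.float32)   # x >= 0
        y = block(ad.Tensor(x))
        np.testing.assert_allclose(y.data, x, atol=1e-7)

    def test_outer_relu_clamps_negative_entries(self):
        block = ResidualBlock(1, 1, norm="none", rng=np.random.default_rng(0))
        for p in block.parameters():
            p.data = np.zeros_like(p.data)
        x = np.array([[[[-1.0, 2.0], [3.0, -4.0]]]], dtype=np.float32)
        y = block(ad.Tensor(x)).data
        np.testing.assert_allclose(y, np.maximum(x, 0.0), atol=1e-7)

    def test_matches_hand_composed_operations(self, rng):
        """y == relu(conv2(relu(conv1(x))) + x) evaluated independently."""
        block = ResidualBlock(3, 3, norm="none", rng=np.random.default_rng(3))
        x = rng.normal(size=(2, 3, 8, 8)).astype(np.float32)
        y = block(ad.Tensor(x)).data
        h = ad.conv2d(ad.Tensor(x), block.conv1.weight, block.conv1.bias).data
        h = np.maximum(h, 0.0)
        f = ad.conv2d(ad.Tensor(h), block.conv2.weight, block.conv2.bias).data
        np.testing.assert_allclose(y, np.maximum(f + x, 0.0), atol=1e-5)

    def test_projection_shortcut_changes_shape(self, rng):
        block = ResidualBlock(4, 8, stride=2, norm="none",
                              rng=np.random.default_rng(1))
        y = block(ad.Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32)))
        assert y.shape == (1, 8, 4, 4)


class TestEncoder:
    @pytest.mark.parametrize("side", [128, 256])
    def test_five_maps_halving_to_one_sixteenth(self, side):
        cfg = NetworkConfig(input_side=side, use_fpa=(side >= 128))
        enc = build_encoder(cfg, seed=0)
        x = ad.Tensor(np.zeros((1, 1, side, side), dtype=np.float32))
        feats = enc(x)
        sides = [f.shape[2] for f in feats]
        assert sides == [side, side // 2, side // 4, side // 8, side // 16]

    def test_stage_channel_widths_follow_config(self):
        cfg = NetworkConfig(input_side=128)
        feats = build_encoder(cfg, seed=0)(
            ad.Tensor(np.zeros((1, 1, 128, 128), dtype=np.float32)))
        assert [f.shape[1] for f in feats] == [16, 16, 32, 64, 128]

    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError, match="multiple of 16"):
            NetworkConfig(input_side=100)


class TestFPA:
    def test_pyramid_sides_from_32(self):
        assert fpa_pyramid_sides(32) == (16, 8, 4)

    def test_too_small_side_rejected(self):
        with pytest.raises(ValueError, match="at least 8"):
            fpa_pyramid_sides(4)

    @pytest.mark.parametrize("side", [8, 16, 32])
    def test_output_side_equals_input_side(self, rng, side):
        fpa = build_fpa(8, side, norm="none", seed=0)
        y = fpa(ad.Tensor(rng.normal(size=(1, 8, side, side)).astype(np.float32)))
        assert y.shape == (1, 8, side, side)

    def test_closed_gate_zeroes_output(self, rng):
        """Zero pyramid and global branches with an identity main branch:
        the multiplicative gate closes and the output is exactly zero."""
        fpa = build_fpa(2, 16, norm="none", seed=0)
        for name, p in fpa.named_parameters():
            if name.startswith("main."):
                # 1x1 identity convolution
                p.data = (np.eye(2, dtype=np.float32).reshape(2, 2, 1, 1)
                          if p.data.ndim == 4 else np.zeros_like(p.data))
            else:
                p.data = np.zeros_like(p.data)
        x = rng.normal(size=(1, 2, 16, 16)).astype(np.float32)
        y = fpa(ad.Tensor(x))
        np.testing.assert_allclose(y.data, 0.0, atol=1e-7)


class TestFullModel:
    def test_forward_shape_and_range(self, rng):
        model = build_network(NetworkConfig(input_side=128), seed=0)
        p = predict_proba(model, rng.random((1, 128, 128)))
        assert p.shape == (1, 1, 128, 128)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_variant_table(self):
        assert NetworkConfig.unet().use_residual is False
        assert NetworkConfig.unet().use_fpa is False
        assert NetworkConfig.resunet().use_residual is True
        assert NetworkConfig.resunet().use_fpa is False
        assert NetworkConfig.ours().use_residual and NetworkConfig.ours().use_fpa

    def test_fpa_needs_large_enough_input(self):
        with pytest.raises(ValueError, match="bottleneck side"):
            NetworkConfig(input_side=64, use_fpa=True)

    def test_gradients_finite_everywhere(self, rng):
        model = build_network(NetworkConfig(input_side=128), seed=0)
        x = rng.random((2, 128, 128)).astype(np.float32)
        g = (rng.random((2, 1, 128, 128)) > 0.8).astype(np.float32)
        loss = ad.soft_dice_loss(model(x), g)
        loss.backward()
        for name, p in model.named_parameters():
            assert p.grad is not None, name
            assert np.isfinite(p.grad).all(), name

    def test_determinism_same_seed_same_output(self, rng):
        x = rng.random((1, 128, 128)).astype(np.float32)
        a = predict_proba(build_network(NetworkConfig(input_side=128), seed=5), x)
        b = predict_proba(build_network(NetworkConfig(input_side=128), seed=5), x)
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_round_trip_preserves_output(self, tmp_path, rng):
        from paraseg import io as pio
        cfg = NetworkConfig(input_side=128)
        model = build_network(cfg, seed=3)
        x = rng.random((1, 128, 128)).astype(np.float32)
        before = predict_proba(model, x)
        pio.save_checkpoint(tmp_path / "m.npz", model.state_dict(), cfg.to_dict())
        state, sidecar = pio.load_checkpoint(tmp_path / "m.npz")
        other = build_network(NetworkConfig.from_dict(sidecar["network_config"]),
                              seed=99)
        other.load_state_dict(state)
        np.testing.assert_array_equal(before, predict_proba(other, x))


class TestParameterBudget:
    def test_default_model_under_budget(self):
        n = count_parameters(build_network(NetworkConfig(), seed=0))
        assert n <= 5_000_000

    def test_lone_1x1_conv(self):
        conv = nn.Conv2d(1, 1, 1, rng=np.random.default_rng(0))
        assert count_parameters(conv) == 2 == conv_param_count(1, 1, 1, bias=True)

    def test_doubling_widths_increases_count(self):
        base = count_parameters(build_network(NetworkConfig(), seed=0))
        wide = count_parameters(build_network(
            NetworkConfig(base_channels=32, stage_channels=(32, 64, 128, 256)),
            seed=0))
        assert wide > base

    def test_conv_layers_match_closed_form(self):
        model = build_network(NetworkConfig(norm="none"), seed=0)
        total = 0
        for m in model.modules():
            if isinstance(m, nn.Conv2d):
                total += conv_param_count(m.kernel_size, m.in_channels,
                                          m.out_channels, bias=m.bias is not None)
        assert total == count_parameters(model)

    def test_full_width_unet_dwarfs_quarter_width_residual(self):
        full = count_parameters(build_network(NetworkConfig.unet_full_width(), seed=0))
        quarter = count_parameters(build_network(NetworkConfig.resunet(), seed=0))
        assert full > 4 * quarter
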