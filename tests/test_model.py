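"""Architecture contracts: projections, shape pipeline, mixers, decoder."""

import numpy as np
import pytest

from axisppg.autograd import Tensor
from axisppg.losses import neg_pearson_loss
from axisppg.model import (AxisProjectionNet, AxisTag, ModelConfig,
                           axis_project, count_parameters, interp_to_T,
                           mix_features, st_translate)


@pytest.fixture(scope="module")
def small_model(small_config):
    return AxisProjectionNet(small_config)


@pytest.fixture(scope="module")
def small_batch():
    return np.random.default_rng(0).random((2, 3, 8, 16, 16))


class TestAxisProject:
    @pytest.mark.parametrize("axis,expected", [
        ("T", (2 * 8, 3, 16, 16)), ("H", (2 * 16, 3, 8, 16)), ("W", (2 * 16, 3, 8, 16))])
    def test_projected_shapes(self, small_batch, axis, expected):
        assert axis_project(small_batch, axis).shape == expected

    def test_projection_is_invertible(self, small_batch):
        y = axis_project(small_batch, "H")
        back = y.reshape(2, 16, 3, 8, 16).transpose(0, 2, 3, 1, 4)
        np.testing.assert_array_equal(back.numpy(), small_batch)

    def test_dims_accessor_matches_projection(self):
        assert AxisTag("T").dims(8, 16, 12) == (8, 16, 12)
        assert AxisTag("H").dims(8, 16, 12) == (16, 8, 12)
        assert AxisTag("W").dims(8, 16, 12) == (12, 8, 16)

    def test_bad_rank_rejected(self):
        with pytest.raises(ValueError):
            axis_project(np.zeros((3, 8, 16, 16)), "T")


class TestSTTranslate:
    def test_layout_contract_impulse(self):
        x = np.zeros((2 * 8, 3, 4, 5))
        x[2 * 8 - 8 + 3, 1, 2, 4] = 7.0   # batch item 1, slice 3, pixel (2,4)
        out = st_translate(x, 2).numpy()
        assert out.shape == (2, 3, 8, 20)
        nz = np.argwhere(out != 0)
        assert nz.tolist() == [[1, 1, 3, 2 * 5 + 4]]

    def test_inverse_roundtrip(self, rng):
        x = rng.random((6, 3, 4, 4))
        y = st_translate(x, 2)
        back = y.reshape(2, 3, 3, 4, 4).transpose(0, 2, 1, 3, 4).reshape(6, 3, 4, 4)
        np.testing.assert_array_equal(back.numpy(), x)

    def test_indivisible_batch_rejected(self):
        with pytest.raises(ValueError):
            st_translate(np.zeros((5, 3, 4, 4)), 2)


class TestInterp:
    def test_constant_preserved(self):
        x = np.full((2, 3, 4, 128, 4), 0.77)
        out = interp_to_T(Tensor(x), 32)
        assert out.shape == (2, 3, 32, 4, 4)
        np.testing.assert_allclose(out.numpy(), 0.77, atol=1e-6)

    def test_linear_ramp_preserved(self):
        ramp = np.linspace(0.0, 1.0, 4)
        x = np.broadcast_to(ramp[None, None, :, None, None], (1, 3, 4, 8, 4)).copy()
        out = interp_to_T(Tensor(x), 16).numpy()
        expected = np.linspace(0.0, 1.0, 16)
        np.testing.assert_allclose(out[0, 0, :, 0, 0], expected, atol=1e-6)

    def test_t_axis_feature_passes_through(self, small_model, small_batch):
        feats = small_model.extract_features(small_batch)
        out = interp_to_T(feats["T"], 8)
        np.testing.assert_array_equal(out.numpy(), feats["T"].tensor.numpy())


class TestMixers:
    @staticmethod
    def _random_feats(rng):
        return [rng.standard_normal((2, 3, 32, 4, 4)) for _ in range(3)]

    def test_all_cases_match_direct_formula(self, rng):
        """Independent numpy evaluation of each mixer formula."""
        et, eh, ew = self._random_feats(rng)
        expected = {
            1: np.matmul(ew, eh) * et + et,
            2: et,
            3: ew * et + et,
            4: eh * et + et,
            5: (ew + eh) * et + et,
            6: (ew + eh) * et,
            7: ew * et,
            8: eh * et,
            9: ew,
            10: eh,
        }
        for case, want in expected.items():
            got = mix_features(Tensor(et), Tensor(eh), Tensor(ew), case).tensor.numpy()
            assert np.abs(got - want).max() < 1e-5, f"case {case}"

    def test_case2_is_bit_identical_passthrough(self, rng):
        et, eh, ew = self._random_feats(rng)
        out = mix_features(Tensor(et), Tensor(eh), Tensor(ew), 2).tensor.numpy()
        np.testing.assert_array_equal(out, et)

    def test_case7_with_unit_w_is_identity(self, rng):
        et, eh, _ = self._random_feats(rng)
        out = mix_features(Tensor(et), Tensor(eh), Tensor(np.ones_like(et)), 7)
        np.testing.assert_allclose(out.tensor.numpy(), et, atol=1e-12)

    def test_case5_minus_case6_equals_et(self, rng):
        et, eh, ew = self._random_feats(rng)
        m5 = mix_features(Tensor(et), Tensor(eh), Tensor(ew), 5).tensor.numpy()
        m6 = mix_features(Tensor(et), Tensor(eh), Tensor(ew), 6).tensor.numpy()
        assert np.abs((m5 - m6) - et).max() < 1e-10

    def test_invalid_case_rejected(self, rng):
        et, eh, ew = self._random_feats(rng)
        with pytest.raises(ValueError):
            mix_features(Tensor(et), Tensor(eh), Tensor(ew), 11)


class TestForward:
    @pytest.mark.parametrize("case", range(1, 11))
    def test_all_mixer_cases_produce_bt_output(self, small_batch, case):
        model = AxisProjectionNet(ModelConfig(T=8, size=16, mixer_case=case, seed=0))
        out = model.predict(small_batch)
        assert out.shape == (2, 8)
        assert np.isfinite(out).all()

    def test_eval_forward_is_deterministic(self, small_model, small_batch):
        a = small_model.predict(small_batch)
        b = small_model.predict(small_batch)
        np.testing.assert_array_equal(a, b)

    def test_axis_features_finite_with_expected_shapes(self, small_model, small_batch):
        feats = small_model.extract_features(small_batch)
        assert feats["T"].tensor.shape == (2, 3, 8, 4, 4)
        assert feats["H"].tensor.shape == (2, 3, 4, 16, 4)
        assert feats["W"].tensor.shape == (2, 3, 4, 16, 4)
        for f in feats.values():
            assert np.isfinite(f.tensor.numpy()).all()

    def test_temporal_sensitivity_comes_from_frame_dynamics(self, small_config):
        """Shuffling frames changes the output of a dynamic clip but leaves a
        static (constant-in-time) clip's output exactly unchanged: the
        network's temporal response is driven by frame-to-frame variation."""
        model = AxisProjectionNet(small_config)
        rng = np.random.default_rng(5)
        x = rng.random((1, 3, 8, 16, 16))
        perm = rng.permutation(8)
        base = model.predict(x)
        assert np.abs(model.predict(x[:, :, perm]) - base).max() > 1e-8
        static = np.broadcast_to(x[:, :, :1], x.shape).copy()
        np.testing.assert_array_equal(model.predict(static[:, :, perm]),
                                      model.predict(static))

    def test_gradient_flow_per_mixer_case(self, small_batch):
        """Cases using all three axes propagate gradients to all extractors;
        case 2 leaves the H/W extractors untouched."""
        target = np.random.default_rng(6).standard_normal((2, 8))
        for case, expect_hw in [(6, True), (2, False)]:
            model = AxisProjectionNet(ModelConfig(T=8, size=16, mixer_case=case, seed=0))
            out = model(Tensor(small_batch))
            neg_pearson_loss(target, out).backward()
            t_grads = [p.grad for p in model.extractor_t.parameters()]
            hw_grads = [p.grad for p in model.extractor_h.parameters()]
            hw_grads += [p.grad for p in model.extractor_w.parameters()]
            assert any(g is not None and np.abs(g).max() > 0 for g in t_grads)
            touched = any(g is not None and np.abs(g).max() > 0 for g in hw_grads)
            assert touched == expect_hw, f"case {case}"


class TestMaxViTAndGate:
    def test_identity_initialised_layer_passes_input_through(self):
        from axisppg.model import MaxViTLayer, STFeatureBlock
        rng = np.random.default_rng(0)
        layer = MaxViTLayer(3, 1, (8, 8), rng)
        layer.init_identity()
        x = rng.random((2, 3, 8, 64))
        np.testing.assert_allclose(layer(Tensor(x)).numpy(), x, atol=1e-6)
        # with the gate bypassed as well, the whole block is the identity
        block = STFeatureBlock(3, 1, (8, 8), 1, np.random.default_rng(1))
        block.layers[0].init_identity()
        block.gate.bypass = True
        np.testing.assert_allclose(block(Tensor(x)).numpy(), x, atol=1e-6)

    def test_gate_mask_in_unit_interval_and_contractive(self, rng):
        from axisppg.model import SpatialAttention
        gate = SpatialAttention(np.random.default_rng(1))
        x = Tensor(rng.standard_normal((2, 3, 8, 16)))
        mask = gate.mask(x).numpy()
        assert (mask > 0).all() and (mask < 1).all()
        out = gate(x).numpy()
        assert (np.abs(out) <= np.abs(x.numpy()) + 1e-12).all()


class TestDecoderAndParams:
    def test_zeroed_head_yields_zero_signal(self, small_config, small_batch):
        model = AxisProjectionNet(small_config)
        model.decoder.head.weight.data[:] = 0.0
        model.decoder.head.bias.data[:] = 0.0
        np.testing.assert_array_equal(model.predict(small_batch), 0.0)

    def test_count_matches_hand_count_for_single_conv(self):
        from axisppg import nn
        conv = nn.Conv2d(3, 3, 3, np.random.default_rng(0))
        n = sum(p.data.size for p in conv.parameters())
        assert n == 3 * 3 * 3 * 3 + 3 == 84

    def test_count_invariant_to_batch_size_and_bounded(self):
        n, nbytes = count_parameters(ModelConfig())
        n2, _ = count_parameters(ModelConfig())
        assert n == n2 > 0
        assert nbytes == 4 * n
        assert nbytes <= 8 * 2**20  # well under the 8 MB budget

    def test_checkpoint_roundtrip(self, tmp_path, small_config, small_batch):
        model = AxisProjectionNet(small_config)
        before = model.predict(small_batch)
        model.save(tmp_path / "ckpt.npz")
        loaded = AxisProjectionNet.load(tmp_path / "ckpt.npz")
        np.testing.assert_allclose(loaded.predict(small_batch), before, atol=1e-7)
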