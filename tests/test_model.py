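"""Architecture components against brute-force oracles, plus training."""

import math

import numpy as np
import pytest

import oracles
from fcaunet.model import (
    AttentionGate,
    ConvSpec,
    FCAUNet,
    FFCFuse,
    ModelConfig,
    TrainParams,
    attention_gate,
    build_fcau_net,
    channel_attention,
    conv2d,
    ffc_fuse,
    position_attention,
    predict,
    sigmoid,
    train_model,
)
from fcaunet.nn.engine import Tensor
from fcaunet.preprocess import split_dataset
from fcaunet.types import SplitPlan


class TestConv2d:
    def test_one_by_one_kernel_scales(self):
        fm = np.ones((1, 3, 3))
        out = conv2d(fm, ConvSpec(kernel=np.full((1, 1, 1, 1), 2.0)))
        np.testing.assert_allclose(out, np.full((1, 3, 3), 2.0))

    def test_delta_kernel_is_identity(self, rng):
        fm = rng.normal(size=(2, 5, 5))
        k = np.zeros((2, 2, 3, 3))
        k[0, 0, 1, 1] = 1.0
        k[1, 1, 1, 1] = 1.0
        np.testing.assert_allclose(conv2d(fm, ConvSpec(kernel=k)), fm)

    def test_matches_four_loop_oracle(self, rng):
        fm = rng.normal(size=(1, 5, 5))
        k = rng.normal(size=(2, 1, 3, 3))
        got = conv2d(fm, ConvSpec(kernel=k, padding=0))
        want = oracles.conv_loop(fm, k, pad=0)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_depthwise_matches_loop_oracle(self, rng):
        fm = rng.normal(size=(3, 6, 6))
        k = rng.normal(size=(3, 3, 3))
        got = conv2d(fm, ConvSpec(kernel=k, depthwise=True, padding=1))
        want = oracles.depthwise_loop(fm, k, pad=1)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_sigmoid_closed_forms(self):
        assert sigmoid(np.zeros((1, 1, 1)))[0, 0, 0] == pytest.approx(0.5)
        assert sigmoid(np.full((1, 1, 1), math.log(3)))[0, 0, 0] == pytest.approx(0.75)
        x = np.array([[[0.7]]])
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)


class TestAttentionOps:
    def test_channel_attention_beta_zero_is_identity(self, rng):
        fm = rng.normal(size=(4, 3, 3))
        np.testing.assert_allclose(channel_attention(fm, 0.0), fm)

    def test_channel_attention_matches_oracle(self, rng):
        fm = rng.normal(size=(2, 2, 1))
        got = channel_attention(fm, 1.0)
        want = oracles.channel_attention_oracle(fm, 1.0)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_position_attention_beta_zero_is_identity(self, rng):
        fm = rng.normal(size=(2, 4, 4))
        np.testing.assert_allclose(position_attention(fm, 0.0), fm)

    def test_position_attention_matches_oracle(self, rng):
        fm = rng.normal(size=(1, 2, 2))
        got = position_attention(fm, 1.0)
        want = oracles.position_attention_oracle(fm, 1.0)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_uniform_input_gives_uniform_position_weights(self):
        fm = np.full((2, 2, 2), 3.0)
        # every pixel identical: attending uniformly, output = input + beta*input
        np.testing.assert_allclose(position_attention(fm, 1.0), 2 * fm)

    def test_softmax_rows_sum_to_one_inside_modules(self, rng):
        from fcaunet.model import ChannelAttentionBlock, PositionAttentionBlock
        from fcaunet.nn import engine as E
        x = rng.normal(size=(1, 3, 4, 4))
        a = E.reshape(Tensor(x), (1, 3, 16))
        gram = E.matmul(a, E.transpose(a, (0, 2, 1)))
        rows = E.softmax(gram, axis=-1).data.sum(axis=-1)
        np.testing.assert_allclose(rows, 1.0, atol=1e-6)


class TestAttentionGateAndFuse:
    def test_gate_matches_straight_line_oracle(self, rng):
        gate = AttentionGate(2, 4, np.random.default_rng(3), variant="modified")
        gate.eval()
        x = rng.normal(size=(2, 4, 4))
        g = rng.normal(size=(4, 2, 2))
        got = gate(Tensor(x[None]), Tensor(g[None])).data[0]
        want = oracles.attention_gate_oracle(gate, x, g)
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-8)

    def test_default_gate_matches_oracle_too(self, rng):
        gate = AttentionGate(2, 2, np.random.default_rng(5), variant="default")
        gate.eval()
        x = rng.normal(size=(2, 4, 4))
        g = rng.normal(size=(2, 4, 4))
        got = gate(Tensor(x[None]), Tensor(g[None])).data[0]
        want = oracles.attention_gate_oracle(gate, x, g)
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-8)

    def test_gate_coefficients_bounded_and_alpha_one_passthrough(self, rng):
        gate = AttentionGate(2, 2, np.random.default_rng(0))
        gate.eval()
        x = rng.normal(size=(1, 2, 4, 4))
        g = rng.normal(size=(1, 2, 4, 4))
        out = gate(Tensor(x), Tensor(g)).data
        alpha = out / np.where(np.abs(x) < 1e-12, 1.0, x)
        assert np.all((alpha > 0) & (alpha < 1) | (np.abs(x) < 1e-12))
        # forcing alpha to 1 via a huge psi bias returns x unchanged
        gate.psi.bias.data[:] = 1e3
        np.testing.assert_allclose(gate(Tensor(x), Tensor(g)).data, x, atol=1e-12)

    def test_functional_gate_shape_contract(self, rng):
        x = rng.normal(size=(3, 8, 8))
        g = rng.normal(size=(6, 4, 4))
        assert attention_gate(x, g, seed=1).shape == x.shape

    def test_ffc_fuse_matches_straight_line_oracle(self, rng):
        fuse = FFCFuse(4, np.random.default_rng(11))
        fuse.eval()
        fm_o = rng.normal(size=(4, 8, 8))
        fm_s = rng.normal(size=(4, 2, 2))
        got = fuse(Tensor(fm_o[None]), Tensor(fm_s[None])).data[0]
        want = oracles.ffc_fuse_oracle(fuse, fm_o, fm_s)
        np.testing.assert_allclose(got, want, rtol=1e-5, atol=1e-8)

    def test_ffc_fuse_zero_small_map_reduces_to_original_branch(self, rng):
        # context_block1(0) is not zero (BN/bias), so zero the whole branch
        fuse = FFCFuse(2, np.random.default_rng(2))
        fuse.eval()
        fm_o = rng.normal(size=(2, 8, 8))
        fm_s = np.zeros((2, 2, 2))
        os_only = oracles.ffc_fuse_oracle(fuse, fm_o, fm_s)
        got = fuse(Tensor(fm_o[None]), Tensor(fm_s[None])).data[0]
        np.testing.assert_allclose(got, os_only, rtol=1e-5, atol=1e-8)

    def test_ffc_fuse_shape_contract_and_scale_mismatch(self, rng):
        fm_o = rng.normal(size=(2, 8, 8))
        assert ffc_fuse(fm_o, rng.normal(size=(2, 2, 2))).shape == fm_o.shape
        with pytest.raises(ValueError):
            ffc_fuse(fm_o, rng.normal(size=(2, 3, 3)))


class TestBuildFCAUNet:
    def test_forward_probabilities_sum_to_one(self, rng):
        model = build_fcau_net(ModelConfig(base_channels=4, seed=0))
        x = rng.random((2, 1, 64, 64))
        _, probs, _ = predict(model, x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_same_seed_gives_identical_weights(self):
        cfg = ModelConfig(base_channels=4, seed=9)
        a = build_fcau_net(cfg)
        b = build_fcau_net(cfg)
        assert a.num_parameters() == b.num_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_ablation_reduces_to_plain_unet(self):
        cfg = ModelConfig(base_channels=4, attention_gate="none",
                          ffcm_enabled=False, seed=0)
        model = build_fcau_net(cfg)
        assert model.ffc is None
        assert model.gates == []

    def test_shape_algebra_of_recorded_activations(self, rng):
        model = build_fcau_net(ModelConfig(base_channels=4, seed=0))
        model.eval()
        model(Tensor(rng.random((1, 1, 64, 64))))
        for k, size in [("encoder0", 64), ("encoder1", 32), ("encoder2", 16),
                        ("encoder3", 8), ("bottleneck", 4), ("decoder0", 8),
                        ("decoder3", 64)]:
            assert model.activations[k].data.shape[2] == size

    def test_parameter_count_monotone_in_base_channels(self):
        counts = [build_fcau_net(ModelConfig(base_channels=b, seed=0)).num_parameters()
                  for b in (2, 4, 8)]
        assert counts[0] < counts[1] < counts[2]

    def test_indivisible_input_size_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=(60, 60), depth=4)


@pytest.fixture(scope="module")
def tiny_split(easy_dataset):
    tr, va, te = split_dataset(easy_dataset,
                               SplitPlan(test_fraction=0.25, val_fraction=0.2, seed=0))
    pick = ([s for s in tr if s.label == "healthy"][:4]
            + [s for s in tr if s.label == "infected"][:4])
    return pick, va[:4]


class TestTraining:

    def test_one_epoch_history_and_finite_loss(self, tiny_split):
        tr, va = tiny_split
        model = build_fcau_net(ModelConfig(base_channels=2, seed=0))
        model, hist = train_model(model, tr, va, TrainParams(epochs=1), seed=0)
        assert len(hist) == 1
        assert np.isfinite(hist[0]["loss"])
        assert "val_accuracy" in hist[0]

    def test_single_class_training_rejected(self, tiny_split):
        tr, _ = tiny_split
        one_class = [s for s in tr if s.label == tr[0].label]
        model = build_fcau_net(ModelConfig(base_channels=2, seed=0))
        with pytest.raises(ValueError):
            train_model(model, one_class, [], TrainParams(epochs=1))

    def test_training_is_seed_deterministic(self, tiny_split):
        tr, va = tiny_split
        finals = []
        for _ in range(2):
            model = build_fcau_net(ModelConfig(base_channels=2, seed=4))
            model, _ = train_model(model, tr, va, TrainParams(epochs=2), seed=4)
            finals.append([p.data.copy() for p in model.parameters()])
        for pa, pb in zip(*finals):
            np.testing.assert_array_equal(pa, pb)

    def test_eval_mode_prediction_deterministic(self, tiny_split, rng):
        tr, _ = tiny_split
        model = build_fcau_net(ModelConfig(base_channels=2, seed=0))
        x = rng.random((3, 1, 64, 64))
        _, p1, _ = predict(model, x)
        _, p2, _ = predict(model, x)
        np.testing.assert_array_equal(p1, p2)

    def test_checkpoint_round_trip_reproduces_predictions(self, tiny_split, rng,
                                                          tmp_path):
        from fcaunet.model import load_checkpoint, save_checkpoint
        tr, va = tiny_split
        model = build_fcau_net(ModelConfig(base_channels=2, seed=1))
        model, _ = train_model(model, tr, va, TrainParams(epochs=1), seed=1)
        x = rng.random((3, 1, 64, 64))
        _, p1, _ = predict(model, x)
        save_checkpoint(model, str(tmp_path / "ckpt"))
        restored = load_checkpoint(str(tmp_path / "ckpt.npz"))
        _, p2, _ = predict(restored, x)
        np.testing.assert_array_equal(p1, p2)
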