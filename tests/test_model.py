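import numpy as np
import pytest

from boneage.autograd import Tensor
from boneage.model import (
    AgeDistribution,
    BoneAgeModel,
    ModelConfig,
    PatchMerge,
    SexToken,
    SwinBlock,
    WindowAttention,
    fuse_sex,
    predict_age,
)
from boneage.patches import RoiStack

from conftest import micro_config


def _softmax(x):
    e = np.exp(x - x.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def global_attention_reference(x, layer):
    """Brute-force full self-attention over the flattened map, same weights."""
    b, h, w, c = x.shape
    heads, hd = layer.num_heads, c // layer.num_heads
    tokens = x.reshape(b, h * w, c)

    def project(lin):
        out = tokens @ lin.w.data + lin.b.data
        return out.reshape(b, h * w, heads, hd).transpose(0, 2, 1, 3)

    q, k, v = project(layer.q) / np.sqrt(hd), project(layer.k), project(layer.v)
    attn = _softmax(q @ k.transpose(0, 1, 3, 2))
    out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, h * w, c)
    out = out @ layer.proj.w.data + layer.proj.b.data
    return out.reshape(b, h, w, c)


class TestConfig:
    def test_tiny_is_valid(self):
        ModelConfig.tiny().validate()

    def test_default_is_valid(self):
        ModelConfig().validate()

    def test_window_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(
                embed_channels=8, embed_patch=2, stage_depths=(1,),
                head_counts=(1,), window_size=5,
            ).validate()

    def test_halving_doubling_contract(self):
        cfg = ModelConfig()  # 56 -> 28 -> 14 -> 7; 144 -> 288 -> 576 -> 1152
        assert [cfg.stage_side(s) for s in range(4)] == [56, 28, 14, 7]
        assert [cfg.stage_channels(s) for s in range(4)] == [144, 288, 576, 1152]


class TestSexToken:
    def test_gate_in_unit_interval(self):
        model = BoneAgeModel(micro_config())
        for sex in ("male", "female"):
            gate = model.encode_sex_token(sex).gate
            assert gate.shape == (8,)
            assert np.all((gate > 0) & (gate < 1))

    def test_sexes_get_distinct_gates(self):
        model = BoneAgeModel(micro_config())
        assert not np.allclose(
            model.encode_sex_token("male").gate, model.encode_sex_token("female").gate
        )

    def test_zero_weight_map_gives_sigmoid_bias(self):
        model = BoneAgeModel(micro_config())
        model.sex_linear.w.data[:] = 0.0
        model.sex_linear.b.data[:] = 0.3
        gate = model.encode_sex_token("male").gate
        np.testing.assert_allclose(gate, 1 / (1 + np.exp(-0.3)))

    def test_unknown_sex_rejected(self):
        model = BoneAgeModel(micro_config())
        with pytest.raises(ValueError):
            model.encode_sex_token("unknown")


class TestFuseSex:
    def _token(self, gate):
        return SexToken(code=np.array([0.0, 1.0]), gate=np.asarray(gate, dtype=float))

    def test_half_gate_halves_constant_channel(self):
        features = np.ones((2, 4, 4))
        out = fuse_sex(features, self._token([0.5, 1.0]))
        np.testing.assert_allclose(out[0], 0.5)
        np.testing.assert_allclose(out[1], 1.0)

    def test_linearity_in_features(self):
        rng = np.random.default_rng(0)
        features = rng.normal(size=(3, 5, 5))
        token = self._token(rng.random(3))
        np.testing.assert_allclose(
            fuse_sex(3.0 * features, token), 3.0 * fuse_sex(features, token)
        )

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_sex(np.ones((4, 2, 2)), self._token([0.5, 0.5]))


class TestEmbedding:
    def test_output_shape(self):
        model = BoneAgeModel(micro_config())
        out = model.embed_rois(np.zeros((2, 18, 58, 58)))
        assert out.shape == (2, 14, 14, 8)

    def test_zero_input_gives_bias_only(self):
        model = BoneAgeModel(micro_config())
        model.embed.b.data[:] = 0.7
        out = model.embed_rois(np.zeros((1, 18, 58, 58)))
        np.testing.assert_allclose(out.data, 0.7)

    def test_deterministic_under_seed(self):
        a = BoneAgeModel(micro_config(seed=5))
        b = BoneAgeModel(micro_config(seed=5))
        x = np.random.default_rng(1).random((1, 18, 58, 58))
        np.testing.assert_array_equal(a.embed_rois(x).data, b.embed_rois(x).data)


class TestWindowAttention:
    def test_full_window_equals_global_attention(self):
        """W-MSA with window = map size must match brute-force attention."""
        rng = np.random.default_rng(2)
        layer = WindowAttention(rng, channels=8, num_heads=2)
        x = rng.normal(size=(2, 4, 4, 8))
        ours = layer(Tensor(x), window=4, shifted=False).data
        ref = global_attention_reference(x, layer)
        assert np.abs(ours - ref).max() <= 1e-5

    def test_window_independence_under_permutation(self):
        """Swapping the contents of two windows swaps their outputs."""
        rng = np.random.default_rng(3)
        layer = WindowAttention(rng, channels=4, num_heads=1)
        x = rng.normal(size=(1, 4, 4, 4))
        swapped = x.copy()
        swapped[0, :2, :2], swapped[0, 2:, 2:] = (
            x[0, 2:, 2:].copy(),
            x[0, :2, :2].copy(),
        )
        out = layer(Tensor(x), window=2).data
        out_swapped = layer(Tensor(swapped), window=2).data
        np.testing.assert_allclose(out[0, :2, :2], out_swapped[0, 2:, 2:], atol=1e-12)
        np.testing.assert_allclose(out[0, 2:, 2:], out_swapped[0, :2, :2], atol=1e-12)

    def test_shifted_windows_have_no_cross_boundary_attention(self):
        """On a 4x4 map the shifted pass must not mix wrap-around regions."""
        from boneage.model import _shifted_attention_mask

        rng = np.random.default_rng(4)
        layer = WindowAttention(rng, channels=4, num_heads=1)
        x = rng.normal(size=(1, 4, 4, 4))
        layer(Tensor(x), window=2, shifted=True, shift=1, keep_attn=True)
        attn = layer.last_attn  # (1, 2, 2, heads, 4, 4)
        mask = _shifted_attention_mask(4, 2, 1)
        blocked = mask < 0
        cross = attn[0, :, :, 0][blocked]
        assert cross.size > 0
        assert np.abs(cross).max() < 1e-12

    def test_shifted_equals_roll_mask_roll_back(self):
        """SW-MSA == cyclic shift, masked W-MSA, shift back (numpy oracle)."""
        from boneage.model import _shifted_attention_mask

        rng = np.random.default_rng(5)
        layer = WindowAttention(rng, channels=4, num_heads=1)
        x = rng.normal(size=(1, 4, 4, 4))
        ours = layer(Tensor(x), window=2, shifted=True, shift=1).data

        xr = np.roll(x, (-1, -1), axis=(1, 2))
        mask = _shifted_attention_mask(4, 2, 1)
        ref = np.empty_like(xr)
        for wi in range(2):
            for wj in range(2):
                tile = xr[0, 2 * wi : 2 * wi + 2, 2 * wj : 2 * wj + 2]
                tokens = tile.reshape(4, 4)
                q = (tokens @ layer.q.w.data + layer.q.b.data) / 2.0
                k = tokens @ layer.k.w.data + layer.k.b.data
                v = tokens @ layer.v.w.data + layer.v.b.data
                attn = _softmax(q @ k.T + mask[wi, wj])
                out = (attn @ v) @ layer.proj.w.data + layer.proj.b.data
                ref[0, 2 * wi : 2 * wi + 2, 2 * wj : 2 * wj + 2] = out.reshape(2, 2, 4)
        ref = np.roll(ref, (1, 1), axis=(1, 2))
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_divisibility_enforced(self):
        rng = np.random.default_rng(6)
        layer = WindowAttention(rng, channels=4, num_heads=1)
        with pytest.raises(ValueError):
            layer(Tensor(np.zeros((1, 5, 5, 4))), window=2)


class TestSwinBlock:
    def _block(self, index=0):
        rng = np.random.default_rng(7)
        return SwinBlock(
            rng, channels=4, num_heads=1, window=2, shift=1,
            mlp_ratio=2.0, block_index=index, name="b",
        )

    def test_zeroed_projections_make_identity(self):
        blk = self._block()
        blk.attn.proj.w.data[:] = 0.0
        blk.attn.proj.b.data[:] = 0.0
        blk.fc2.w.data[:] = 0.0
        blk.fc2.b.data[:] = 0.0
        x = np.random.default_rng(8).normal(size=(1, 4, 4, 4))
        np.testing.assert_allclose(blk(Tensor(x)).data, x, atol=1e-12)

    def test_shape_preserved(self):
        x = np.random.default_rng(9).normal(size=(2, 4, 4, 4))
        assert self._block()(Tensor(x)).shape == x.shape

    def test_alternation_rule(self):
        model = BoneAgeModel(ModelConfig.tiny())
        flags = [blk.shifted for blk in model.stages[0]]
        assert flags == [False, True]


class TestPatchMerge:
    def test_shape_halves_and_doubles(self):
        rng = np.random.default_rng(10)
        merge = PatchMerge(rng, channels=8, name="m")
        out = merge(Tensor(np.zeros((2, 8, 8, 8))))
        assert out.shape == (2, 4, 4, 16)

    def test_constant_input_constant_output(self):
        rng = np.random.default_rng(11)
        merge = PatchMerge(rng, channels=4, name="m")
        out = merge(Tensor(np.ones((1, 4, 4, 4)))).data
        for c in range(8):
            np.testing.assert_allclose(out[..., c], out[0, 0, 0, c], atol=1e-12)

    def test_four_stage_cascade_reaches_seven(self):
        rng = np.random.default_rng(12)
        side, channels = 56, 4
        x = Tensor(np.zeros((1, side, side, channels)))
        for _ in range(3):
            x = PatchMerge(rng, channels=x.shape[-1], name="m")(x)
        assert x.shape == (1, 7, 7, 32)

    def test_odd_side_rejected(self):
        rng = np.random.default_rng(13)
        merge = PatchMerge(rng, channels=4, name="m")
        with pytest.raises(ValueError):
            merge(Tensor(np.zeros((1, 5, 5, 4))))


@pytest.fixture(scope="module")
def model():
    return BoneAgeModel(micro_config())


@pytest.fixture(scope="module")
def stack():
    return np.random.default_rng(14).random((18, 58, 58))


class TestForward:
    def test_distribution_is_valid(self, model, stack):
        dist = model.forward(stack, "male")
        assert dist.probs.shape == (60,)
        assert dist.probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert dist.var_months2 >= 0

    def test_sex_changes_distribution(self, model, stack):
        male = model.forward(stack, "male")
        female = model.forward(stack, "female")
        assert not np.allclose(male.probs, female.probs)

    def test_frozen_gate_ignores_sex(self, stack):
        model = BoneAgeModel(micro_config())
        model.sex_gate_frozen = True
        np.testing.assert_array_equal(
            model.forward(stack, "male").probs, model.forward(stack, "female").probs
        )

    def test_batch_order_preserved(self, model):
        rng = np.random.default_rng(15)
        stacks = rng.random((3, 18, 58, 58))
        batch = model.forward_batch(stacks, ["male", "female", "male"])
        singles = [
            model.forward(stacks[i], s)
            for i, s in enumerate(["male", "female", "male"])
        ]
        for got, want in zip(batch, singles):
            np.testing.assert_allclose(got.probs, want.probs, atol=1e-12)

    def test_bit_stable_across_runs(self, model, stack):
        a = model.forward(stack, "female")
        b = model.forward(stack, "female")
        np.testing.assert_array_equal(a.probs, b.probs)

    def test_checkpoint_round_trip(self, model, stack, tmp_path):
        path = tmp_path / "ckpt.npz"
        model.save(path)
        loaded = BoneAgeModel.load(path)
        np.testing.assert_array_equal(
            model.forward(stack, "male").probs, loaded.forward(stack, "male").probs
        )


class TestPredictAge:
    def test_point_mass(self):
        p = np.zeros(240)
        p[119] = 1.0  # class 120
        assert predict_age(AgeDistribution.from_probs(p)) == pytest.approx(120.0)

    def test_uniform_three_classes(self):
        assert predict_age(
            AgeDistribution.from_probs(np.full(3, 1 / 3))
        ) == pytest.approx(2.0)

    def test_symmetric_distribution(self):
        p = np.array([0.2, 0.1, 0.4, 0.1, 0.2])
        assert predict_age(AgeDistribution.from_probs(p)) == pytest.approx(3.0)

    def test_invalid_probs_rejected(self):
        with pytest.raises(ValueError):
            AgeDistribution.from_probs(np.array([0.5, 0.4]))
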