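"""Sex-token fusion and the hierarchical windowed-attention age model.

The network consumes the (18, 58, 58) ROI stack and the biological-sex code
and produces a probability distribution over K discrete age classes
(class j = j months). Architecture, in execution order:

1. *Patch embedding* — non-overlapping p x p patches of the 18-channel stack
   are flattened and linearly mapped to ``embed_channels`` (the learned
   realisation of the 18 -> 144 channel expansion; the working map is
   centre-cropped to a side divisible by the window size).
2. *Sex-token fusion* — the sex code (male (0,1), female (1,0)) passes a
   linear layer and sigmoid, giving a per-channel gate in (0,1) that
   multiplies the feature map; it plays the role a position token plays in a
   standard vision transformer.
3. *Four-stage (configurable) backbone* — each stage is a run of pre-norm
   transformer blocks, x + Attn(LN(x)) then + MLP(LN(.)), where even blocks
   use window multihead self-attention (W-MSA: attention inside w x w tiles)
   and odd blocks use shifted-window attention (SW-MSA: tiles offset by half
   a window via cyclic shift, with masking so no attention crosses the
   original canvas boundary). Between stages a patch-merging layer halves
   the resolution and doubles the channels.
4. *Head* — global average pooling and a linear map to K logits; softmax
   gives the age distribution, whose mean is the predicted age in months.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autograd import Adam, Parameter, Tensor, layer_norm
from .detection_io import NUM_ROI_CLASSES, sex_code
from .loss import dist_mean, dist_var
from .patches import PATCH_SIZE, RoiStack


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``input_side`` is the ROI patch side (58); the working map is the centre
    crop to ``working_side`` so every stage side is divisible by
    ``window_size``. ``embed_patch`` is the patch-embedding stride (1 keeps
    58 -> 56 full resolution; 2 gives a 28 x 28 working map). Stage s runs at
    half the resolution and twice the channels of stage s-1.
    """

    num_classes: int = 240
    embed_channels: int = 144
    input_side: int = PATCH_SIZE
    working_side: int = 56
    embed_patch: int = 1
    stage_depths: tuple[int, ...] = (2, 2, 2, 2)
    head_counts: tuple[int, ...] = (3, 6, 12, 24)
    window_size: int = 7
    shift_size: int | None = None  # defaults to window_size // 2
    mlp_ratio: float = 2.0
    seed: int = 0

    @property
    def shift(self) -> int:
        return self.window_size // 2 if self.shift_size is None else self.shift_size

    def stage_side(self, s: int) -> int:
        return self.working_side // self.embed_patch // (2**s)

    def stage_channels(self, s: int) -> int:
        return self.embed_channels * (2**s)

    def validate(self) -> None:
        if self.working_side > self.input_side:
            raise ValueError("working_side cannot exceed input_side")
        if len(self.stage_depths) != len(self.head_counts):
            raise ValueError("stage_depths and head_counts must have equal length")
        for s in range(len(self.stage_depths)):
            side = self.stage_side(s)
            if side % self.window_size != 0:
                raise ValueError(
                    f"stage {s} side {side} not divisible by window {self.window_size}"
                )
            if self.stage_channels(s) % self.head_counts[s] != 0:
                raise ValueError(f"stage {s} channels not divisible by heads")
            if s + 1 < len(self.stage_depths) and side % 2 != 0:
                raise ValueError(f"stage {s} side {side} must be even to merge")

    @classmethod
    def tiny(cls, num_classes: int = 240, seed: int = 0) -> "ModelConfig":
        """Desk-scale preset: 28x28 working map, two stages, ~65k parameters."""
        return cls(
            num_classes=num_classes,
            embed_channels=24,
            embed_patch=2,
            stage_depths=(2, 2),
            head_counts=(2, 4),
            window_size=7,
            seed=seed,
        )


@dataclass(frozen=True)
class SexToken:
    """Sex code vector and the per-channel sigmoid gate derived from it."""

    code: np.ndarray
    gate: np.ndarray


@dataclass(frozen=True)
class AgeDistribution:
    """Probability vector over the K age classes with derived moments."""

    probs: np.ndarray
    mean_months: float
    var_months2: float

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "AgeDistribution":
        probs = np.asarray(probs, dtype=float)
        if np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("probs must be nonnegative and sum to 1")
        return cls(
            probs=probs,
            mean_months=float(dist_mean(probs)),
            var_months2=float(dist_var(probs)),
        )


def predict_age(dist: AgeDistribution) -> float:
    """Inference-time age estimate: the distribution mean, in months."""
    return dist.mean_months


def fuse_sex(features: np.ndarray, token: SexToken) -> np.ndarray:
    """Channel-wise multiplicative gating: out[c,h,w] = features[c,h,w] * gate[c]."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] != token.gate.shape[0]:
        raise ValueError(
            f"channel mismatch: features {features.shape[0]} vs gate {token.gate.shape[0]}"
        )
    return features * token.gate[:, None, None]


def _shifted_attention_mask(side: int, window: int, shift: int) -> np.ndarray:
    """Swin-style additive mask for SW-MSA, shape (nW, nW, T, T).

    Built in the cyclically shifted frame: row/column bands (0, -w), (-w, -s),
    (-s, end) receive distinct region ids; token pairs whose ids differ came
    from across the original canvas boundary and get -1e9.
    """
    img = np.zeros((side, side))
    bands = (slice(0, side - window), slice(side - window, side - shift),
             slice(side - shift, side))
    cnt = 0
    for hb in bands:
        for wb in bands:
            img[hb, wb] = cnt
            cnt += 1
    n = side // window
    wins = (
        img.reshape(n, window, n, window)
        .transpose(0, 2, 1, 3)
        .reshape(n, n, window * window)
    )
    diff = wins[:, :, :, None] - wins[:, :, None, :]
    return np.where(diff != 0, -1e9, 0.0)


class _Linear:
    """Affine map with Glorot-normal weight init and zero bias."""

    def __init__(self, rng, n_in: int, n_out: int, name: str):
        std = np.sqrt(2.0 / (n_in + n_out))
        self.w = Parameter(rng.normal(0.0, std, (n_in, n_out)), name=f"{name}.w")
        self.b = Parameter(np.zeros(n_out), name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self) -> list[Parameter]:
        return [self.w, self.b]


class WindowAttention:
    """Multihead self-attention inside (shifted) square windows.

    Operates on (B, H, W, C) tensors. With ``shifted`` the canvas is
    cyclically shifted by ``shift`` before partitioning and the boundary mask
    zeroes attention between tokens from opposite sides of the wrap-around.
    """

    def __init__(self, rng, channels: int, num_heads: int, name: str = "attn"):
        if channels % num_heads != 0:
            raise ValueError("channels must be divisible by num_heads")
        self.channels = channels
        self.num_heads = num_heads
        self.q = _Linear(rng, channels, channels, f"{name}.q")
        self.k = _Linear(rng, channels, channels, f"{name}.k")
        self.v = _Linear(rng, channels, channels, f"{name}.v")
        self.proj = _Linear(rng, channels, channels, f"{name}.proj")
        self.last_attn: np.ndarray | None = None

    def params(self) -> list[Parameter]:
        return self.q.params() + self.k.params() + self.v.params() + self.proj.params()

    def __call__(
        self,
        x: Tensor,
        window: int,
        shifted: bool = False,
        shift: int | None = None,
        keep_attn: bool = False,
    ) -> Tensor:
        b, h, w, c = x.shape
        if h % window or w % window:
            raise ValueError(f"map side ({h}, {w}) not divisible by window {window}")
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        shift = (window // 2) if shift is None else shift
        if shifted and (shift <= 0 or h <= window):
            shifted = False  # single-window maps cannot shift
        if shifted:
            x = x.roll((-shift, -shift), (1, 2))
        n = h // window
        t = window * window
        heads, hd = self.num_heads, c // self.num_heads
        # partition into windows: (B, n, n, T, C)
        xw = (
            x.reshape(b, n, window, n, window, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, n, n, t, c)
        )

        def split_heads(tns: Tensor) -> Tensor:
            return tns.reshape(b, n, n, t, heads, hd).transpose(0, 1, 2, 4, 3, 5)

        q = split_heads(self.q(xw)) * (1.0 / np.sqrt(hd))
        k = split_heads(self.k(xw))
        v = split_heads(self.v(xw))
        logits = q @ k.transpose(0, 1, 2, 3, 5, 4)  # (B, n, n, heads, T, T)
        if shifted:
            mask = _shifted_attention_mask(h, window, shift)
            logits = logits + Tensor(mask[None, :, :, None, :, :])
        attn = logits.softmax()
        if keep_attn:
            self.last_attn = attn.data.copy()
        out = attn @ v  # (B, n, n, heads, T, hd)
        out = out.transpose(0, 1, 2, 4, 3, 5).reshape(b, n, n, t, c)
        out = self.proj(out)
        # un-partition
        out = (
            out.reshape(b, n, n, window, window, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h, w, c)
        )
        if shifted:
            out = out.roll((shift, shift), (1, 2))
        return out


class SwinBlock:
    """Pre-norm residual block: x + Attn(LN(x)), then + MLP(LN(.)).

    Even ``block_index`` -> W-MSA, odd -> SW-MSA.
    """

    def __init__(self, rng, channels: int, num_heads: int, window: int,
                 shift: int, mlp_ratio: float, block_index: int, name: str):
        self.window = window
        self.shift = shift
        self.shifted = block_index % 2 == 1
        hidden = int(round(channels * mlp_ratio))
        self.ln1_g = Parameter(np.ones(channels), name=f"{name}.ln1.g")
        self.ln1_b = Parameter(np.zeros(channels), name=f"{name}.ln1.b")
        self.attn = WindowAttention(rng, channels, num_heads, name=f"{name}.attn")
        self.ln2_g = Parameter(np.ones(channels), name=f"{name}.ln2.g")
        self.ln2_b = Parameter(np.zeros(channels), name=f"{name}.ln2.b")
        self.fc1 = _Linear(rng, channels, hidden, f"{name}.fc1")
        self.fc2 = _Linear(rng, hidden, channels, f"{name}.fc2")

    def params(self) -> list[Parameter]:
        return (
            [self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b]
            + self.attn.params()
            + self.fc1.params()
            + self.fc2.params()
        )

    def __call__(self, x: Tensor) -> Tensor:
        y = layer_norm(x, self.ln1_g, self.ln1_b)
        x = x + self.attn(y, self.window, shifted=self.shifted, shift=self.shift)
        y = layer_norm(x, self.ln2_g, self.ln2_b)
        return x + self.fc2(self.fc1(y).gelu())


class PatchMerge:
    """Concatenate 2x2 neighbours (4C) and reduce linearly to 2C."""

    def __init__(self, rng, channels: int, name: str):
        self.reduce = _Linear(rng, 4 * channels, 2 * channels, name)

    def params(self) -> list[Parameter]:
        return self.reduce.params()

    def __call__(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"cannot merge odd-sized map ({h}, {w})")
        x = (
            x.reshape(b, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h // 2, w // 2, 4 * c)
        )
        return self.reduce(x)


class BoneAgeModel:
    """The full age-distribution network (embedding to softmax head)."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        config.validate()
        self.config = config
        #: when True the sex gate is bypassed (all-ones), for ablation runs
        self.sex_gate_frozen = False
        rng = np.random.default_rng(config.seed)
        c0 = config.embed_channels
        p = config.embed_patch
        self.embed = _Linear(rng, NUM_ROI_CLASSES * p * p, c0, "embed")
        self.sex_linear = _Linear(rng, 2, c0, "sex")
        # open-gate initialisation: bias +2 puts the sigmoid gate near 0.9 at
        # the start so gating does not attenuate features before it has
        # learned a sex-specific modulation
        self.sex_linear.b.data[:] = 2.0
        self.stages: list[list[SwinBlock]] = []
        self.merges: list[PatchMerge] = []
        for s, depth in enumerate(config.stage_depths):
            blocks = [
                SwinBlock(
                    rng,
                    config.stage_channels(s),
                    config.head_counts[s],
                    config.window_size,
                    config.shift,
                    config.mlp_ratio,
                    block_index=i,
                    name=f"stage{s}.block{i}",
                )
                for i in range(depth)
            ]
            self.stages.append(blocks)
            if s + 1 < len(config.stage_depths):
                self.merges.append(
                    PatchMerge(rng, config.stage_channels(s), f"merge{s}")
                )
        c_last = config.stage_channels(len(config.stage_depths) - 1)
        self.head = _Linear(rng, c_last, config.num_classes, "head")

    # ------------------------------------------------------------------ params
    def params(self) -> list[Parameter]:
        out = self.embed.params() + self.sex_linear.params()
        for blocks in self.stages:
            for blk in blocks:
                out += blk.params()
        for m in self.merges:
            out += m.params()
        return out + self.head.params()

    # -------------------------------------------------------------- sex token
    def encode_sex_token(self, sex: str) -> SexToken:
        """Linear map of the sex code followed by sigmoid: the channel gate."""
        code = sex_code(sex)
        logits = code @ self.sex_linear.w.data + self.sex_linear.b.data
        return SexToken(code=code, gate=1.0 / (1.0 + np.exp(-logits)))

    def _sex_gates(self, sexes: list[str]) -> Tensor:
        codes = Tensor(np.stack([sex_code(s) for s in sexes]))
        return self.sex_linear(codes).sigmoid()  # (B, C)

    # ---------------------------------------------------------------- forward
    def _prepare(self, stacks: np.ndarray) -> np.ndarray:
        """Centre-crop (N, 18, 58, 58) stacks to the working side."""
        cfg = self.config
        off = (cfg.input_side - cfg.working_side) // 2
        return stacks[:, :, off : off + cfg.working_side, off : off + cfg.working_side]

    def embed_rois(self, stacks: np.ndarray) -> Tensor:
        """Patch-embed (N, 18, S, S) stacks to (N, S', S', C) feature maps."""
        cfg = self.config
        x = np.asarray(stacks, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != NUM_ROI_CLASSES or x.shape[2] != cfg.input_side:
            raise ValueError(f"expected (N, 18, {cfg.input_side}, ...), got {x.shape}")
        x = self._prepare(x)
        n, c, s, _ = x.shape
        p = cfg.embed_patch
        sp = s // p
        t = Tensor(x)
        t = (
            t.reshape(n, c, sp, p, sp, p)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n, sp, sp, c * p * p)
        )
        return self.embed(t)

    def forward_logits(self, stacks: np.ndarray, sexes: list[str]) -> Tensor:
        """Run the full network; returns the (N, K) logits tensor."""
        x = self.embed_rois(stacks)  # (N, S', S', C)
        if not self.sex_gate_frozen:
            gates = self._sex_gates(sexes)  # (N, C)
            n, sp, _, c = x.shape
            x = x * gates.reshape(n, 1, 1, c)
        for s, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            if s < len(self.merges):
                x = self.merges[s](x)
        pooled = x.mean(axis=(1, 2))  # (N, C_last)
        return self.head(pooled)

    def forward(self, stack: RoiStack | np.ndarray, sex: str) -> AgeDistribution:
        """Predict the age distribution for one sample (evaluation mode)."""
        data = stack.data if isinstance(stack, RoiStack) else np.asarray(stack)
        logits = self.forward_logits(data[None], [sex]).data[0]
        shifted = logits - logits.max()
        e = np.exp(shifted)
        return AgeDistribution.from_probs(e / e.sum())

    def forward_batch(
        self, stacks: np.ndarray, sexes: list[str]
    ) -> list[AgeDistribution]:
        logits = self.forward_logits(stacks, sexes).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)
        return [AgeDistribution.from_probs(p) for p in probs]

    # ------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.params())}
        cfg = asdict(self.config)
        np.savez_compressed(path, config=np.array(json.dumps(cfg)), **arrays)

    @classmethod
    def load(cls, path) -> "BoneAgeModel":
        with np.load(path, allow_pickle=False) as archive:
            cfg_dict = json.loads(str(archive["config"]))
            for key in ("stage_depths", "head_counts"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = cls(ModelConfig(**cfg_dict))
            params = model.params()
            for i, p in enumerate(params):
                stored = archive[f"param_{i}"]
                if stored.shape != p.data.shape:
                    raise ValueError("checkpoint/config mismatch")
                p.data = stored.astype(np.float64)
        return model


__all__ = [
    "ModelConfig",
    "SexToken",
    "AgeDistribution",
    "BoneAgeModel",
    "WindowAttention",
    "SwinBlock",
    "PatchMerge",
    "predict_age",
    "fuse_sex",
]
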