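"""Dense convolutional backbone with parallel channel/spatial attention.

The classifier treats an encoded sequence (a 7x200 single-channel grey
image) as input to a modified densely connected convolutional network:

* no stem convolution - the raw feature grid enters dense block 1 directly;
* four dense blocks of three layers each; every layer is BN -> ReLU ->
  3x3 same-padded convolution producing ``growth_rate`` channels, and
  receives the channel-wise concatenation of the block input and all
  previous layer outputs;
* an extra batch-normalization layer between each dense block and the
  following transition layer;
* transition layers: 1x1 convolution compressing channels by a fixed
  fraction, then 2x2 stride-2 average pooling with ceiling division (so
  the height-7 axis survives all three transitions: 7 -> 4 -> 2 -> 1);
* an attention stage (layer-1 models only): channel attention (shared
  two-layer MLP over global avg- and max-pooled channel descriptors,
  sigmoid) and spatial attention (7x7 convolution over the concatenated
  channel-mean and channel-max maps, sigmoid) computed in parallel from
  the same input, their weighted maps multiplied position-wise;
* a head that adaptively average-pools to a 1x4 grid, flattens, applies
  dropout and fully connected layers, and outputs two softmax logits.

Everything runs on the package's NumPy autodiff engine.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

ATTENTION_VARIANTS = ("parallel", "serial", "channel", "spatial")
ATTENTION_COMBINE = ("weighted_product", "joint_mask")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters (all surfaced; defaults desk-scale).

    ``use_attention`` is True for layer-1 (enhancer recognition) models and
    False for layer-2 (strong/weak) models, which drop the attention stage
    to avoid overfitting the smaller dataset.
    """

    num_blocks: int = 4
    layers_per_block: int = 3
    growth_rate: int = 12
    conv_kernel: int = 3
    transition_compression: float = 0.5
    attention_reduction: int = 4
    spatial_kernel: int = 7
    use_attention: bool = True
    attention_variant: str = "parallel"
    attention_combine: str = "weighted_product"
    head_hidden_sizes: tuple = (64,)
    head_pool: tuple = (1, 4)
    n_classes: int = 2
    dropout_rate: float = 0.3
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.1
    dtype: str = "float32"
    seed: int = 0

    def __post_init__(self):
        if self.num_blocks < 1 or self.layers_per_block < 1 or self.growth_rate < 1:
            raise ValueError("num_blocks, layers_per_block, growth_rate must be >= 1")
        if not 0.0 < self.transition_compression <= 1.0:
            raise ValueError("transition_compression must be in (0, 1]")
        if self.bn_epsilon <= 0:
            raise ValueError("bn_epsilon must be positive")
        if self.attention_variant not in ATTENTION_VARIANTS:
            raise ValueError(f"attention_variant must be one of {ATTENTION_VARIANTS}")
        if self.attention_combine not in ATTENTION_COMBINE:
            raise ValueError(f"attention_combine must be one of {ATTENTION_COMBINE}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head_hidden_sizes"] = list(self.head_hidden_sizes)
        d["head_pool"] = list(self.head_pool)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for k in ("head_hidden_sizes", "head_pool"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def channel_trace(cfg: NetworkConfig, c_in: int = 1) -> list[dict]:
    """Symbolic per-block channel bookkeeping.

    Each entry records the channels entering a dense block, leaving it
    (c + L*k by concatenation), and leaving the following transition
    (floor(c * compression)); the last block has no transition.
    """
    trace = []
    c = c_in
    for b in range(cfg.num_blocks):
        entry = {"block": b, "in": c}
        c = c + cfg.layers_per_block * cfg.growth_rate
        entry["out"] = c
        if b < cfg.num_blocks - 1:
            c = int(np.floor(c * cfg.transition_compression))
            entry["after_transition"] = c
        trace.append(entry)
    return trace


# ---------------------------------------------------------------------------
# building blocks


class Module:
    def params(self) -> list[Tensor]:
        raise NotImplementedError

    def state_arrays(self) -> list[np.ndarray]:
        """Trainable parameter data plus persistent buffers, in fixed order."""
        return [p.data for p in self.params()]


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, rng, dtype):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        std = np.sqrt(2.0 / (c_in * kh * kw))
        self.w = ad.param(rng.normal(0.0, std, (c_out, c_in, kh, kw)).astype(dtype))
        self.b = ad.param(np.zeros(c_out, dtype=dtype))

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class Linear(Module):
    def __init__(self, d_in, d_out, rng, dtype):
        std = np.sqrt(2.0 / d_in)
        self.w = ad.param(rng.normal(0.0, std, (d_in, d_out)).astype(dtype))
        self.b = ad.param(np.zeros(d_out, dtype=dtype))

    def __call__(self, x):
        return ad.linear(x, self.w, self.b)

    def params(self):
        return [self.w, self.b]


class BatchNorm2d(Module):
    def __init__(self, channels, eps, momentum, dtype):
        self.gamma = ad.param(np.ones(channels, dtype=dtype))
        self.beta = ad.param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.eps, self.momentum = eps, momentum

    def __call__(self, x, train):
        return ad.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.eps, self.momentum, train,
        )

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.gamma.data, self.beta.data, self.running_mean, self.running_var]


class DenseLayer(Module):
    """The dense block's composite function H: BN -> ReLU -> 3x3 conv."""

    def __init__(self, c_in, growth_rate, kernel, cfg, rng):
        dtype = cfg.dtype
        self.bn = BatchNorm2d(c_in, cfg.bn_epsilon, cfg.bn_momentum, dtype)
        self.conv = Conv2d(c_in, growth_rate, kernel, rng, dtype)

    def __call__(self, x, train):
        return self.conv(ad.relu(self.bn(x, train)))

    def params(self):
        return self.bn.params() + self.conv.params()

    def state_arrays(self):
        return self.bn.state_arrays() + self.conv.state_arrays()


class DenseBlock(Module):
    """Each layer consumes the concatenation of the block input and all
    previous layer outputs; the block output concatenates everything
    (c_in + L * growth_rate channels)."""

    def __init__(self, c_in, n_layers, growth_rate, cfg, rng):
        self.layers = []
        c = c_in
        for _ in range(n_layers):
            self.layers.append(DenseLayer(c, growth_rate, cfg.conv_kernel, cfg, rng))
            c += growth_rate
        self.c_out = c

    def __call__(self, x, train):
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else ad.concat(feats, axis=1)
            feats.append(layer(inp, train))
        return ad.concat(feats, axis=1)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def state_arrays(self):
        return [a for l in self.layers for a in l.state_arrays()]


class Transition(Module):
    """1x1 convolution compressing channels, then ceil-mode 2x2 avg pooling."""

    def __init__(self, c_in, compression, cfg, rng):
        self.c_out = int(np.floor(c_in * compression))
        self.conv = Conv2d(c_in, self.c_out, 1, rng, cfg.dtype)

    def __call__(self, x, train):
        return ad.avgpool2x2_ceil(self.conv(x))

    def params(self):
        return self.conv.params()


class ChannelAttention(Module):
    """Per-channel sigmoid weights from a shared MLP over global avg/max
    channel descriptors; returns (weights, reweighted map)."""

    def __init__(self, channels, reduction, cfg, rng):
        hidden = channels // reduction
        if hidden < 1:
            raise ValueError(
                f"attention_reduction {reduction} too large for {channels} channels"
            )
        dtype = cfg.dtype
        self.fc1 = Linear(channels, hidden, rng, dtype)
        self.fc2 = Linear(hidden, channels, rng, dtype)

    def _mlp(self, v):
        return self.fc2(ad.relu(self.fc1(v)))

    def __call__(self, f):
        avg = self._mlp(ad.global_avgpool(f))
        mx = self._mlp(ad.global_maxpool(f))
        weights = ad.sigmoid(ad.add(avg, mx))  # (N, C)
        n, c = weights.data.shape
        w4 = ad.reshape(weights, (n, c, 1, 1))
        return weights, ad.mul(f, w4)

    def params(self):
        return self.fc1.params() + self.fc2.params()


class SpatialAttention(Module):
    """Per-position sigmoid weights from a 7x7 convolution over the
    concatenated channel-mean and channel-max maps."""

    def __init__(self, cfg, rng):
        self.conv = Conv2d(2, 1, cfg.spatial_kernel, rng, cfg.dtype)

    def __call__(self, f):
        avg = ad.mean_axis(f, axis=1, keepdims=True)
        mx = ad.max_axis(f, axis=1, keepdims=True)
        weights = ad.sigmoid(self.conv(ad.concat([avg, mx], axis=1)))  # (N,1,H,W)
        return weights, ad.mul(f, weights)

    def params(self):
        return self.conv.params()


class AttentionStage(Module):
    """Channel and spatial attention in one of four arrangements.

    parallel: both branches see the original map F; the combination is
    either (Mc*F) ⊙ (Ms*F) (``weighted_product``, the literal position-wise
    product of the two weighted maps) or F*Mc*Ms (``joint_mask``).
    serial: the classic arrangement, spatial applied to the
    channel-weighted map.  channel / spatial: a single branch.
    """

    def __init__(self, channels, cfg, rng):
        self.variant = cfg.attention_variant
        self.combine = cfg.attention_combine
        self.channel = (
            ChannelAttention(channels, cfg.attention_reduction, cfg, rng)
            if self.variant in ("parallel", "serial", "channel")
            else None
        )
        self.spatial = (
            SpatialAttention(cfg, rng)
            if self.variant in ("parallel", "serial", "spatial")
            else None
        )

    def __call__(self, f):
        if self.variant == "channel":
            return self.channel(f)[1]
        if self.variant == "spatial":
            return self.spatial(f)[1]
        if self.variant == "serial":
            fc = self.channel(f)[1]
            return self.spatial(fc)[1]
        # parallel
        cw, fc = self.channel(f)
        sw, fs = self.spatial(f)
        if self.combine == "weighted_product":
            return ad.mul(fc, fs)
        n, c = cw.data.shape
        cw4 = ad.reshape(cw, (n, c, 1, 1))
        return ad.mul(ad.mul(f, cw4), sw)

    def params(self):
        out = []
        if self.channel is not None:
            out += self.channel.params()
        if self.spatial is not None:
            out += self.spatial.params()
        return out


class ClassifierHead(Module):
    """Adaptive average pool -> flatten -> dropout -> FC stack -> logits."""

    def __init__(self, c_in, cfg, rng):
        self.pool_h, self.pool_w = cfg.head_pool
        self.dropout_rate = cfg.dropout_rate
        d = c_in * self.pool_h * self.pool_w
        self.fcs = []
        for h in cfg.head_hidden_sizes:
            self.fcs.append(Linear(d, h, rng, cfg.dtype))
            d = h
        self.out = Linear(d, cfg.n_classes, rng, cfg.dtype)

    def __call__(self, f, train, rng):
        x = ad.adaptive_avgpool2d(f, self.pool_h, self.pool_w)
        n = x.data.shape[0]
        x = ad.reshape(x, (n, -1))
        x = ad.dropout(x, self.dropout_rate, rng, train)
        for fc in self.fcs:
            x = ad.relu(fc(x))
        return self.out(x)

    def params(self):
        return [p for fc in self.fcs for p in fc.params()] + self.out.params()


# ---------------------------------------------------------------------------
# full models


class EnhancerDenseNet(Module):
    """The full pipeline: [dense block -> BN -> transition] x (B-1)
    -> dense block -> BN -> (attention) -> classifier head."""

    def __init__(self, cfg: NetworkConfig, c_in: int = 1):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        self.blocks, self.norms, self.transitions = [], [], []
        c = c_in
        for b in range(cfg.num_blocks):
            block = DenseBlock(c, cfg.layers_per_block, cfg.growth_rate, cfg, rng)
            self.blocks.append(block)
            c = block.c_out
            self.norms.append(BatchNorm2d(c, cfg.bn_epsilon, cfg.bn_momentum, cfg.dtype))
            if b < cfg.num_blocks - 1:
                tr = Transition(c, cfg.transition_compression, cfg, rng)
                self.transitions.append(tr)
                c = tr.c_out
        self.attention = AttentionStage(c, cfg, rng) if cfg.use_attention else None
        self.head = ClassifierHead(c, cfg, rng)
        self.final_channels = c

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        self._check_spatial(x.shape[2], x.shape[3])
        t = Tensor(np.asarray(x, dtype=self.cfg.dtype))
        for b in range(self.cfg.num_blocks):
            t = self.blocks[b](t, train)
            t = self.norms[b](t, train)
            if b < self.cfg.num_blocks - 1:
                t = self.transitions[b](t, train)
        if self.attention is not None:
            t = self.attention(t)
        return self.head(t, train, self._dropout_rng)

    def _check_spatial(self, h, w):
        for b in range(self.cfg.num_blocks - 1):
            if h < 1 or w < 1:
                raise ValueError(f"spatial dimensions exhausted before block {b}")
            h, w = -(-h // 2), -(-w // 2)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in eval mode (deterministic, no graph)."""
        outs = []
        with ad.no_grad():
            for i in range(0, len(x), batch_size):
                logits = self.forward(x[i : i + batch_size], train=False)
                outs.append(ad.softmax(logits.data))
        return np.concatenate(outs) if outs else np.zeros((0, self.cfg.n_classes))

    def params(self):
        out = []
        for b in range(self.cfg.num_blocks):
            out += self.blocks[b].params() + self.norms[b].params()
        for tr in self.transitions:
            out += tr.params()
        if self.attention is not None:
            out += self.attention.params()
        out += self.head.params()
        return out

    def state_arrays(self):
        out = []
        for b in range(self.cfg.num_blocks):
            out += self.blocks[b].state_arrays() + self.norms[b].state_arrays()
        for tr in self.transitions:
            out += tr.state_arrays()
        if self.attention is not None:
            out += [p.data for p in self.attention.params()]
        out += [p.data for p in self.head.params()]
        return out

    def get_state(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state: list[np.ndarray]) -> None:
        arrays = self.state_arrays()
        if len(arrays) != len(state):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            np.copyto(dst, src)


class ResNetBaseline(Module):
    """Minimal residual-network baseline for the architecture ablation:
    a stem conv and three residual stages with ceil-mode pooling between
    them, sharing the classifier head design."""

    def __init__(self, cfg: NetworkConfig, c_in: int = 1, widths=(16, 32, 64)):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        dtype = cfg.dtype
        self.stem = Conv2d(c_in, widths[0], cfg.conv_kernel, rng, dtype)
        self.stages = []
        c = widths[0]
        for w in widths:
            proj = Conv2d(c, w, 1, rng, dtype) if c != w else None
            stage = {
                "proj": proj,
                "bn1": BatchNorm2d(w, cfg.bn_epsilon, cfg.bn_momentum, dtype),
                "conv1": Conv2d(w, w, cfg.conv_kernel, rng, dtype),
                "bn2": BatchNorm2d(w, cfg.bn_epsilon, cfg.bn_momentum, dtype),
                "conv2": Conv2d(w, w, cfg.conv_kernel, rng, dtype),
            }
            self.stages.append(stage)
            c = w
        self.head = ClassifierHead(c, cfg, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> Tensor:
        t = Tensor(np.asarray(x, dtype=self.cfg.dtype))
        t = self.stem(t)
        for i, st in enumerate(self.stages):
            if st["proj"] is not None:
                t = st["proj"](t)
            h = st["conv1"](ad.relu(st["bn1"](t, train)))
            h = st["conv2"](ad.relu(st["bn2"](h, train)))
            t = ad.add(t, h)
            if i < len(self.stages) - 1:
                t = ad.avgpool2x2_ceil(t)
        return self.head(t, train, self._dropout_rng)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = []
        with ad.no_grad():
            for i in range(0, len(x), batch_size):
                logits = self.forward(x[i : i + batch_size], train=False)
                outs.append(ad.softmax(logits.data))
        return np.concatenate(outs) if outs else np.zeros((0, self.cfg.n_classes))

    def params(self):
        out = self.stem.params()
        for st in self.stages:
            if st["proj"] is not None:
                out += st["proj"].params()
            out += st["bn1"].params() + st["conv1"].params()
            out += st["bn2"].params() + st["conv2"].params()
        return out + self.head.params()

    def state_arrays(self):
        out = self.stem.state_arrays()
        for st in self.stages:
            if st["proj"] is not None:
                out += st["proj"].state_arrays()
            out += st["bn1"].state_arrays() + st["conv1"].state_arrays()
            out += st["bn2"].state_arrays() + st["conv2"].state_arrays()
        return out + [p.data for p in self.head.params()]

    def get_state(self):
        return [a.copy() for a in self.state_arrays()]

    def set_state(self, state):
        for dst, src in zip(self.state_arrays(), state):
            np.copyto(dst, src)


def build_model(cfg: NetworkConfig, c_in: int = 1, backbone: str = "densenet"):
    """Instantiate an untrained model from a config.

    ``backbone`` is "densenet" (the main architecture) or "resnet" (the
    ablation baseline).  Attention is controlled by cfg.use_attention /
    cfg.attention_variant.
    """
    if backbone == "densenet":
        return EnhancerDenseNet(cfg, c_in=c_in)
    if backbone == "resnet":
        return ResNetBaseline(cfg, c_in=c_in)
    raise ValueError(f"unknown backbone {backbone!r}")
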