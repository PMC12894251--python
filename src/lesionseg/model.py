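"""Dual-attention ASPP U-Net for binary lesion segmentation.

Architecture: a VGG-16-topology encoder (five blocks, 13 convolutional
layers, ReLU + 2x2 max pooling), an atrous-spatial-pyramid-pooling (ASPP)
bottleneck (parallel branches at dilation rates 1/6/12/18 plus a
global-average-pooling branch, channel-concatenated and fused by a 1x1
convolution with ReLU), and a decoder whose skip connections pass through a
dual-headed attention (DHA) gate: a spatial gate (per-pixel sigmoid from the
channel mean/max descriptors through a 7x7 convolution) followed by a channel
gate (per-channel sigmoid from spatially pooled descriptors through a
two-layer dense network).  The refined skip is concatenated with the
upsampled decoder feature and convolved; a final 1x1 convolution + sigmoid
yields the per-pixel lesion probability.

Feature maps are NHWC.  The public helper functions at the bottom operate on
plain (H, W, C) NumPy arrays for direct comparison against brute-force
oracles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .core import Prediction

__all__ = [
    "EncoderConfig", "AsppConfig", "DhaConfig", "DecoderConfig", "ModelConfig",
    "EncoderFeatures", "Encoder", "AsppModule", "SpatialAttention",
    "ChannelAttention", "DhaBlock", "DecoderLevel", "DualAttentionASPPUNet",
    "conv_layer", "max_pool2", "spatial_attention", "channel_attention", "dha",
]


# ---------------------------------------------------------------- configs

@dataclass
class EncoderConfig:
    block_widths: tuple[int, ...] = (64, 128, 256, 512, 512)
    convs_per_block: tuple[int, ...] = (2, 2, 3, 3, 3)
    pretrained_init: bool = False
    pretrained_weights_path: str | None = None
    frozen: bool = False
    replicate_grayscale: bool = True

    def __post_init__(self):
        if sum(self.convs_per_block) != 13:
            raise ValueError(
                f"encoder must total 13 convolutional layers, got {sum(self.convs_per_block)}"
            )
        if len(self.block_widths) != 5 or len(self.convs_per_block) != 5:
            raise ValueError("encoder needs exactly 5 blocks")


@dataclass
class AsppConfig:
    dilation_rates: tuple[int, ...] = (1, 6, 12, 18)
    include_gap_branch: bool = True
    branch_channels: int = 256
    out_channels: int = 256

    def __post_init__(self):
        if list(self.dilation_rates) != sorted(set(self.dilation_rates)):
            raise ValueError("dilation rates must be strictly increasing")


@dataclass
class DhaConfig:
    spatial_kernel: int = 7
    channel_mlp_ratio: int = 8   # hidden width = max(C // ratio, 1)

    def __post_init__(self):
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")


@dataclass
class DecoderConfig:
    level_widths: tuple[int, ...] = (16, 32, 64, 128, 256)  # shallow -> deep
    dropout_rate: float = 0.2
    attention_site: str = "skip"   # skip | upsampled

    def __post_init__(self):
        if len(self.level_widths) != 5:
            raise ValueError("decoder needs 5 widths (4 skip levels + bottleneck stage)")
        if self.attention_site not in ("skip", "upsampled"):
            raise ValueError("attention_site must be 'skip' or 'upsampled'")


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    aspp: AsppConfig = field(default_factory=AsppConfig)
    dha: DhaConfig = field(default_factory=DhaConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    seed: int = 0

    @classmethod
    def reference(cls, seed: int = 0) -> "ModelConfig":
        """Full-size profile: VGG-16 encoder widths, 256-channel ASPP."""
        return cls(seed=seed)

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "ModelConfig":
        """Small profile with the same topology (13 convs, 5 blocks, same
        attention and ASPP structure) that trains in minutes on one CPU."""
        return cls(
            encoder=EncoderConfig(block_widths=(8, 16, 32, 64, 64)),
            aspp=AsppConfig(branch_channels=32, out_channels=32),
            # 16 channels at the two shallowest levels: with fewer, all
            # channels of the last level can go ReLU-dead on the (rare)
            # foreground pixels, which stalls training unrecoverably
            decoder=DecoderConfig(level_widths=(16, 16, 32, 64, 64)),
            seed=seed,
        )

    def to_dict(self) -> dict:
        import dataclasses as dc
        return dc.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def tup(dd):
            return {k: tuple(v) if isinstance(v, list) else v for k, v in dd.items()}
        return cls(encoder=EncoderConfig(**tup(d["encoder"])),
                   aspp=AsppConfig(**tup(d["aspp"])),
                   dha=DhaConfig(**tup(d["dha"])),
                   decoder=DecoderConfig(**tup(d["decoder"])),
                   seed=d.get("seed", 0))


@dataclass
class EncoderFeatures:
    """E1..E4: last pre-pool activations of blocks 1-4 (strides 1,2,4,8);
    bottleneck_in: block-5 post-pool output (stride 32)."""

    E1: nn.Tensor
    E2: nn.Tensor
    E3: nn.Tensor
    E4: nn.Tensor
    bottleneck_in: nn.Tensor


# ---------------------------------------------------------------- modules

class Encoder(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        c_in = 3 if cfg.replicate_grayscale else 1
        convs = []
        for width, n in zip(cfg.block_widths, cfg.convs_per_block):
            block = []
            for _ in range(n):
                block.append(nn.Conv2d(c_in, width, 3, rng=rng))
                c_in = width
            convs.append(block)
        # register flat so parameter paths are stable
        self.convs = [c for block in convs for c in block]
        self._block_sizes = cfg.convs_per_block
        self.out_channels = cfg.block_widths[-1]
        if cfg.pretrained_init:
            self._load_pretrained(cfg.pretrained_weights_path)
        if cfg.frozen:
            self.set_requires_grad(False)

    def _load_pretrained(self, path):
        if path is None:
            raise ValueError(
                "pretrained_init requires pretrained_weights_path (an .npz with "
                "arrays conv{i}_weight/conv{i}_bias in HWIO layout)"
            )
        data = np.load(path)
        for i, conv in enumerate(self.convs):
            conv.weight.data = np.asarray(data[f"conv{i}_weight"], dtype=np.float64)
            conv.bias.data = np.asarray(data[f"conv{i}_bias"], dtype=np.float64)

    def __call__(self, x: nn.Tensor) -> EncoderFeatures:
        N, H, W, C = x.shape
        if H % 32 or W % 32:
            raise ValueError(
                f"input spatial size {(H, W)} must be divisible by 32 "
                "(five 2x2 pooling stages)"
            )
        taps = []
        i = 0
        for b, n in enumerate(self._block_sizes):
            for _ in range(n):
                x = nn.relu(self.convs[i](x))
                i += 1
            taps.append(x)           # last pre-pool activation of block b
            x = nn.max_pool2(x)
        return EncoderFeatures(E1=taps[0], E2=taps[1], E3=taps[2], E4=taps[3],
                               bottleneck_in=x)


class AsppModule(nn.Module):
    """Parallel dilated branches + GAP branch, concatenated and fused."""

    def __init__(self, c_in: int, cfg: AsppConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.branches = [
            nn.Conv2d(c_in, cfg.branch_channels, 1 if r == 1 else 3,
                      dilation=1 if r == 1 else r, rng=rng)
            for r in cfg.dilation_rates
        ]
        self.gap_conv = nn.Conv2d(c_in, cfg.branch_channels, 1, rng=rng) \
            if cfg.include_gap_branch else None
        n_branches = len(self.branches) + (1 if cfg.include_gap_branch else 0)
        self.fuse = nn.Conv2d(cfg.branch_channels * n_branches, cfg.out_channels, 1,
                              rng=rng)

    def branch_outputs(self, x: nn.Tensor) -> list[nn.Tensor]:
        outs = [conv(x) for conv in self.branches]
        if self.gap_conv is not None:
            gap = nn.mean(x, axis=(1, 2), keepdims=True)
            gap = self.gap_conv(gap)
            outs.append(nn.broadcast_hw(gap, x.shape[1], x.shape[2]))
        return outs

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.relu(self.fuse(nn.concat(self.branch_outputs(x), axis=-1)))


class SpatialAttention(nn.Module):
    """Per-pixel gate from channel-mean and channel-max descriptors."""

    def __init__(self, cfg: DhaConfig, rng: np.random.Generator):
        self.conv = nn.Conv2d(2, 1, cfg.spatial_kernel, rng=rng)
        # open-gate init: start near identity so the decoder sees full-scale
        # skip features before the gate has learned anything
        self.conv.bias.data[:] = 2.0

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        f_avg = nn.mean(x, axis=3, keepdims=True)
        f_max = nn.amax(x, axis=3, keepdims=True)
        a_s = nn.sigmoid(self.conv(nn.concat([f_avg, f_max], axis=-1)))
        return a_s, nn.mul(a_s, x)


class ChannelAttention(nn.Module):
    """Per-channel gate from spatial mean/max descriptors through a
    two-layer dense network (first layer bias-free)."""

    def __init__(self, channels: int, cfg: DhaConfig, rng: np.random.Generator):
        hidden = max(channels // cfg.channel_mlp_ratio, 1)
        self.fc1 = nn.Dense(2 * channels, hidden, rng=rng, bias=False)
        self.fc2 = nn.Dense(hidden, channels, rng=rng, bias=True)
        self.fc2.bias.data[:] = 2.0   # open-gate init, as in SpatialAttention
        self.channels = channels

    def __call__(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        N, H, W, C = x.shape
        f_avg = nn.mean(x, axis=(1, 2), keepdims=False)      # (N, C)
        f_max = nn.amax(x, axis=(1, 2), keepdims=False)      # (N, C)
        desc = nn.concat([f_avg, f_max], axis=-1)            # (N, 2C)
        a_c = nn.sigmoid(self.fc2(nn.relu(self.fc1(desc))))  # (N, C)
        a_c4 = _reshape(a_c, (N, 1, 1, C))
        return a_c4, nn.mul(a_c4, x)


def _reshape(t: nn.Tensor, shape) -> nn.Tensor:
    out = nn.Tensor(t.data.reshape(shape), parents=(t,))

    def bw(g):
        t.accumulate(g.reshape(t.data.shape))

    out._backward = bw
    return out


class DhaBlock(nn.Module):
    """Sequential spatial-then-channel attention; last maps kept for
    inspection/export."""

    def __init__(self, channels: int, cfg: DhaConfig, rng: np.random.Generator):
        self.spatial = SpatialAttention(cfg, rng)
        self.channel = ChannelAttention(channels, cfg, rng)
        self.last_spatial_map: np.ndarray | None = None
        self.last_channel_gates: np.ndarray | None = None

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        a_s, x_s = self.spatial(x)
        a_c, x_c = self.channel(x_s)
        self.last_spatial_map = a_s.data[..., 0].copy()
        self.last_channel_gates = a_c.data[:, 0, 0, :].copy()
        return x_c


class DecoderLevel(nn.Module):
    """Upsample x2 + 3x3 conv, attention-gated skip fusion, two 3x3 convs."""

    def __init__(self, c_deeper: int, c_skip: int, width: int,
                 dha_cfg: DhaConfig, attention_site: str, rng: np.random.Generator):
        self.up_conv = nn.Conv2d(c_deeper, width, 3, rng=rng)
        gated_channels = c_skip if attention_site == "skip" else width
        self.dha = DhaBlock(gated_channels, dha_cfg, rng)
        self.conv1 = nn.Conv2d(width + c_skip, width, 3, rng=rng)
        self.conv2 = nn.Conv2d(width, width, 3, rng=rng)
        self.attention_site = attention_site

    def __call__(self, deeper: nn.Tensor, skip: nn.Tensor, dropout_rate: float,
                 rng: np.random.Generator, training: bool) -> nn.Tensor:
        if (skip.shape[1], skip.shape[2]) != (2 * deeper.shape[1], 2 * deeper.shape[2]):
            raise ValueError(
                f"skip spatial size {skip.shape[1:3]} must be twice the deeper "
                f"feature size {deeper.shape[1:3]}"
            )
        up = nn.relu(self.up_conv(
            nn.resize_bilinear(deeper, 2 * deeper.shape[1], 2 * deeper.shape[2])))
        if self.attention_site == "skip":
            merged = nn.concat([up, self.dha(skip)], axis=-1)
        else:
            merged = nn.concat([self.dha(up), skip], axis=-1)
        y = nn.relu(self.conv1(merged))
        y = nn.relu(self.conv2(y))
        return nn.dropout(y, dropout_rate, rng, training)


class DualAttentionASPPUNet(nn.Module):
    """The assembled segmentation network."""

    def __init__(self, cfg: ModelConfig | None = None):
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg.encoder, rng)
        self.aspp = AsppModule(cfg.encoder.block_widths[-1], cfg.aspp, rng)
        widths = cfg.decoder.level_widths
        # skip-free bottleneck stage (stride 32 -> 16) at the deepest width
        self.stage0 = nn.Conv2d(cfg.aspp.out_channels, widths[4], 3, rng=rng)
        skips = list(cfg.encoder.block_widths[:4])          # E1..E4 channels
        deeper = [widths[4], widths[3], widths[2], widths[1]]
        self.levels = [
            DecoderLevel(deeper[i], skips[3 - i], widths[3 - i], cfg.dha,
                         cfg.decoder.attention_site, rng)
            for i in range(4)
        ]
        self.head = nn.Conv2d(widths[0], 1, 1, rng=rng)
        # prior-aware init: lesions are rare, so start the sigmoid output
        # near a low foreground probability instead of 0.5
        self.head.bias.data[:] = -2.0
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        self.training = False
        self.captured: dict[str, nn.Tensor] = {}

    # -- plumbing -------------------------------------------------------
    def set_training(self, flag: bool):
        object.__setattr__(self, "training", bool(flag))

    def _prepare(self, image) -> nn.Tensor:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None, :, :, None]
        elif arr.ndim == 3:
            arr = arr[..., None]
        x = nn.Tensor(arr)
        if self.cfg.encoder.replicate_grayscale and arr.shape[-1] == 1:
            x = nn.concat([x, x, x], axis=-1)
        return x

    # -- forward --------------------------------------------------------
    def forward(self, image, training: bool | None = None, capture: bool = False
                ) -> nn.Tensor:
        """Return the sigmoid probability Tensor of shape (N, H, W, 1)."""
        training = self.training if training is None else training
        x = self._prepare(image)
        feats = self.encoder(x)
        aspp_out = self.aspp(feats.bottleneck_in)
        aspp_out = nn.dropout(aspp_out, self.cfg.decoder.dropout_rate,
                              self._dropout_rng, training)
        d = nn.relu(self.stage0(nn.resize_bilinear(
            aspp_out, 2 * aspp_out.shape[1], 2 * aspp_out.shape[2])))
        skip_order = [feats.E4, feats.E3, feats.E2, feats.E1]
        decs = []
        for level, skip in zip(self.levels, skip_order):
            d = level(d, skip, self.cfg.decoder.dropout_rate,
                      self._dropout_rng, training)
            decs.append(d)
        logits = self.head(d)
        prob = nn.sigmoid(logits)
        if not np.all(np.isfinite(prob.data)):
            raise FloatingPointError("non-finite activations in forward pass")
        if capture:
            self.captured = {
                "E1": feats.E1, "E2": feats.E2, "E3": feats.E3, "E4": feats.E4,
                "bottleneck_in": feats.bottleneck_in, "aspp_out": aspp_out,
                "dec4": decs[0], "dec3": decs[1], "dec2": decs[2], "dec1": decs[3],
                "logits": logits, "probabilities": prob,
            }
        return prob

    def predict(self, image: np.ndarray, threshold: float = 0.5) -> Prediction:
        prob = self.forward(image, training=False)
        return Prediction(probabilities=prob.data[0, :, :, 0], threshold=threshold)

    # -- reporting ------------------------------------------------------
    def architecture_summary(self) -> dict:
        layers = [{"name": name, "shape": list(p.data.shape), "params": int(p.size)}
                  for name, p in self.named_parameters()]
        return {"layers": layers, "total_params": self.parameter_count(),
                "config": self.cfg.to_dict()}

    def summary_json(self) -> str:
        return json.dumps(self.architecture_summary(), indent=2)


# ------------------------------------------------- oracle-facing helpers

def _hwc_tensor(arr) -> nn.Tensor:
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        a = a[..., None]
    return nn.Tensor(a[None])


def conv_layer(f_prev: np.ndarray, weights: np.ndarray, bias: np.ndarray,
               dilation: int = 1) -> np.ndarray:
    """Single conv layer with ReLU on an (H, W, C) array; ``weights`` is
    (k, k, C_in, C_out), same zero padding, cross-correlation convention."""
    out = nn.relu(nn.conv2d(_hwc_tensor(f_prev), nn.Tensor(weights),
                            nn.Tensor(np.asarray(bias, dtype=np.float64)),
                            dilation=dilation))
    return out.data[0]


def max_pool2(f: np.ndarray) -> np.ndarray:
    """2x2/stride-2 max pooling on an (H, W, C) array."""
    return nn.max_pool2(_hwc_tensor(f)).data[0]


def spatial_attention(x: np.ndarray, module: SpatialAttention
                      ) -> tuple[np.ndarray, np.ndarray]:
    a_s, x_s = module(_hwc_tensor(x))
    return a_s.data[0, :, :, 0], x_s.data[0]


def channel_attention(x_s: np.ndarray, module: ChannelAttention
                      ) -> tuple[np.ndarray, np.ndarray]:
    a_c, x_c = module(_hwc_tensor(x_s))
    return a_c.data[0, 0, 0, :], x_c.data[0]


def dha(x: np.ndarray, block: DhaBlock) -> np.ndarray:
    return block(_hwc_tensor(x)).data[0]
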