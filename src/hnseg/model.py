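"""HN-Net: a lightweight residual encoder-decoder for organ-at-risk
segmentation on CT slices, with CBAM attention gating the skip paths.

The backbone is a U-shaped fully convolutional network.  Each stage is a
residual block of two depthwise-separable 3x3 convolutions (DS-conv ->
batch norm -> ReLU, twice) with an identity shortcut (1x1 projection
when the channel count changes).  The encoder halves resolution with
2x2 max pooling and doubles channels per stage; the decoder mirrors it
with learned 2x upsampling.  Instead of plain skip connections, each
encoder feature map passes through a Convolutional Block Attention
Module (channel attention then spatial attention, both multiplicative
sigmoid gates) before being concatenated into the decoder.  A final
1x1 convolution with a sigmoid head emits a per-pixel foreground
probability, so one model instance segments one organ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "ProbabilityMap",
    "CBAM",
    "ResidualBlock",
    "HNNet",
    "build_model",
    "predict_probability",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    input_size must be divisible by 2**depth so that every pooling and
    upsampling stage is exact.  ``cbam_scope`` is "all" (attention on
    every skip) or "deepest" (attention only on the lowest-resolution
    skip, emphasising globally receptive features); ``use_cbam=False``
    reduces the skips to plain identity connections.
    """

    input_size: int = 512
    depth: int = 4
    base_channels: int = 16
    cbam_reduction: int = 8
    cbam_spatial_kernel: int = 7
    use_cbam: bool = True
    cbam_scope: str = "all"  # "all" | "deepest"
    separable: bool = True   # depthwise-separable vs full 3x3 convolutions
    seed: int = 0

    def __post_init__(self):
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^depth = {2 ** self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.cbam_spatial_kernel % 2 != 1:
            raise ValueError("cbam_spatial_kernel must be odd")
        if self.cbam_scope not in ("all", "deepest"):
            raise ValueError("cbam_scope must be 'all' or 'deepest'")


@dataclass
class ProbabilityMap:
    """Per-pixel foreground probability for one slice."""

    values: np.ndarray
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")


class CBAM(nn.Module):
    """Convolutional Block Attention Module.

    Channel attention: a shared two-layer bottleneck MLP applied to the
    global average- and max-pooled channel descriptors, summed, passed
    through a sigmoid.  Spatial attention: a k x k convolution over the
    stacked channel-wise mean and max maps, sigmoid.  Both gates
    multiply the input, so attention never amplifies a feature.
    """

    def __init__(self, ch: int, rng: np.random.Generator,
                 reduction: int = 8, spatial_kernel: int = 7):
        super().__init__()
        hidden = max(1, ch // reduction)
        self.fc1 = nn.Linear(ch, hidden, rng, bias=False)
        self.fc2 = nn.Linear(hidden, ch, rng, bias=False)
        # replicate padding keeps the spatial gate translation-symmetric:
        # a spatially uniform input yields a constant attention map
        self.spatial = nn.Conv2d(2, 1, spatial_kernel, rng,
                                 pad_mode="replicate")

    def __call__(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))                       # (N, C)
        mx = nn.amax(nn.amax(x, axis=3), axis=2)        # (N, C)
        att = self.fc2(nn.relu(self.fc1(avg))) + \
            self.fc2(nn.relu(self.fc1(mx)))
        ca = nn.sigmoid(att).reshape(n, c, 1, 1)
        x = x * ca
        s_avg = x.mean(axis=1, keepdims=True)           # (N, 1, H, W)
        s_max = nn.amax(x, axis=1, keepdims=True)
        sa = nn.sigmoid(self.spatial(nn.concat([s_avg, s_max], axis=1)))
        return x * sa


class ResidualBlock(nn.Module):
    """(conv -> BN -> ReLU) x2 plus an identity shortcut.

    The convolutions are depthwise separable by default ("lightweight");
    ``separable=False`` swaps in full 3x3 convolutions with identical
    topology, which is the comparison point for the parameter-count
    claim.  A 1x1 projection aligns the shortcut when channels change.
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 separable: bool = True):
        super().__init__()
        conv = (lambda i, o: nn.DepthwiseSeparableConv2d(i, o, rng)) \
            if separable else (lambda i, o: nn.Conv2d(i, o, 3, rng))
        self.conv1 = conv(in_ch, out_ch)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = conv(out_ch, out_ch)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.proj = nn.Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def __call__(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        shortcut = self.proj(x) if self.proj is not None else x
        return nn.relu(y + shortcut)


class HNNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = [config.base_channels * 2 ** i for i in range(config.depth + 1)]

        self.encoders = []
        in_ch = 1
        for i in range(config.depth):
            block = ResidualBlock(in_ch, ch[i], rng, config.separable)
            setattr(self, f"enc{i}", block)
            self.encoders.append(block)
            in_ch = ch[i]
        self.bottleneck = ResidualBlock(in_ch, ch[config.depth], rng,
                                        config.separable)

        self.attentions: list[CBAM | None] = []
        for i in range(config.depth):
            gated = config.use_cbam and (
                config.cbam_scope == "all" or i == config.depth - 1)
            att = CBAM(ch[i], rng, config.cbam_reduction,
                       config.cbam_spatial_kernel) if gated else None
            if att is not None:
                setattr(self, f"cbam{i}", att)
            self.attentions.append(att)

        self.upsamples, self.decoders = [], []
        for i in reversed(range(config.depth)):
            up = nn.ConvTranspose2x2(ch[i + 1], ch[i], rng)
            dec = ResidualBlock(2 * ch[i], ch[i], rng, config.separable)
            setattr(self, f"up{i}", up)
            setattr(self, f"dec{i}", dec)
            self.upsamples.append(up)
            self.decoders.append(dec)

        self.head = nn.Conv2d(ch[0], 1, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = nn.maxpool2x2(x)
        x = self.bottleneck(x)
        for up, dec, i in zip(self.upsamples, self.decoders,
                              reversed(range(self.config.depth))):
            skip = skips[i]
            if self.attentions[i] is not None:
                skip = self.attentions[i](skip)
            x = dec(nn.concat([up(x), skip], axis=1))
        return nn.sigmoid(self.head(x))

    def forward_array(self, batch: np.ndarray) -> np.ndarray:
        """Forward pass on a (N, H, W) array, returning probabilities."""
        out = self(Tensor(batch[:, None, :, :]))
        return out.data[:, 0]


def build_model(config: ModelConfig) -> HNNet:
    """Construct an HN-Net with seeded parameter initialization."""
    return HNNet(config)


def count_parameters(model: nn.Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


def cbam_attention(features: np.ndarray, seed: int = 0,
                   reduction: int = 8, spatial_kernel: int = 7) -> np.ndarray:
    """Apply a freshly initialized CBAM gate to an (N, C, H, W) array.

    Convenience wrapper used for inspecting attention behaviour in
    isolation; inside the network the gates are trained end-to-end.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 4 or features.shape[1] < 1:
        raise ValueError("features must be (N, C, H, W) with C >= 1")
    att = CBAM(features.shape[1], np.random.default_rng(seed),
               reduction, spatial_kernel)
    att.eval()
    return att(Tensor(features)).data


def predict_probability(model: HNNet, preprocessed_slice: np.ndarray,
                        case_id: str = "", slice_index: int = 0) -> ProbabilityMap:
    """Run inference on a single preprocessed slice (values in [0, 1])."""
    sl = np.asarray(preprocessed_slice, dtype=np.float64)
    size = model.config.input_size
    if sl.shape != (size, size):
        raise ValueError(
            f"slice shape {sl.shape} does not match model input "
            f"({size}, {size})")
    model.eval()
    probs = model.forward_array(sl[None])[0]
    return ProbabilityMap(values=probs, case_id=case_id,
                          slice_index=slice_index)


def save_checkpoint(model: HNNet, directory: str | Path) -> Path:
    """Save weights (npz) plus a YAML copy of the config next to them."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.state_dict())
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(model.config), fh)
    return directory


def load_checkpoint(directory: str | Path) -> HNNet:
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        config = ModelConfig(**yaml.safe_load(fh))
    model = HNNet(config)
    with np.load(directory / "weights.npz") as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
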