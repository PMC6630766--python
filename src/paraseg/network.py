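"""The segmentation architecture: residual encoder, FPA bottleneck, U-decoder.

The model is a U-shaped encoder–decoder. The encoder follows the ResNet-18
layout (a stem plus four stages of two residual blocks each) with every
channel width reduced to a quarter of the classical U-Net widths, so the
default stage widths are (16, 32, 64, 128). Each stage downsamples 2x and
the stem keeps full resolution, so the deepest feature map is 1/16 of the
input side. Between encoder and decoder sits a feature-pyramid-attention
(FPA) bottleneck: a three-level convolutional pyramid (7x7, 5x5, 3x3
kernels at 1/2, 1/4, 1/8 of the bottleneck resolution) fused bottom-up by
upsample-and-add, multiplied pixel-by-pixel into a 1x1-convolved main
branch, plus an additive global-average-pooling branch. The decoder
upsamples in four steps, concatenating the same-resolution encoder map at
each step, and ends in a 1x1 convolution with a sigmoid, producing one
probability map per output channel.

Three named variants cover the ablation line-up:

==============  ============  =======
variant         use_residual  use_fpa
==============  ============  =======
U-Net baseline  False         False
ResU-Net        True          False
full model      True          True
==============  ============  =======
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, autodiff as ad


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters defining a model variant.

    ``base_channels`` is the stem width; ``stage_channels`` the four encoder
    stage widths. ``input_side`` must be divisible by 16 (four 2x
    downsamplings); the FPA bottleneck additionally needs a deepest map of
    at least 8 px, i.e. ``input_side >= 128`` when ``use_fpa`` is on.
    """

    in_channels: int = 1
    out_channels: int = 1
    base_channels: int = 16
    stage_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    use_residual: bool = True
    use_fpa: bool = True
    input_side: int = 512
    norm: str = "batch"  # "batch" or "none"

    def __post_init__(self) -> None:
        if self.input_side < 16 or self.input_side % 16 != 0:
            raise ValueError(
                f"input_side must be a positive multiple of 16 (four 2x "
                f"downsamplings), got {self.input_side}")
        if len(self.stage_channels) != 4:
            raise ValueError("stage_channels must have exactly 4 entries")
        if self.use_fpa and self.input_side // 16 < 8:
            raise ValueError(
                "FPA needs a bottleneck side >= 8 px (three pyramid levels); "
                f"input_side {self.input_side} gives {self.input_side // 16}")
        if self.norm not in ("batch", "none"):
            raise ValueError("norm must be 'batch' or 'none'")

    # -- named variants --------------------------------------------------
    @classmethod
    def ours(cls, **kw) -> "NetworkConfig":
        """Quarter-width residual encoder with the FPA bottleneck."""
        return cls(**kw)

    @classmethod
    def resunet(cls, **kw) -> "NetworkConfig":
        kw.setdefault("use_residual", True)
        return cls(use_fpa=False, **kw)

    @classmethod
    def unet(cls, **kw) -> "NetworkConfig":
        return cls(use_residual=False, use_fpa=False, **kw)

    @classmethod
    def unet_full_width(cls, **kw) -> "NetworkConfig":
        """Classical full-width U-Net baseline (64..512 channels)."""
        return cls(use_residual=False, use_fpa=False, base_channels=64,
                   stage_channels=(64, 128, 256, 512), **kw)

    @property
    def bottleneck_side(self) -> int:
        return self.input_side // 16

    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "base_channels": self.base_channels,
            "stage_channels": list(self.stage_channels),
            "use_residual": self.use_residual,
            "use_fpa": self.use_fpa,
            "input_side": self.input_side,
            "norm": self.norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        d["stage_channels"] = tuple(d["stage_channels"])
        return cls(**d)


def _norm_layer(channels: int, norm: str) -> nn.Module:
    return nn.BatchNorm2d(channels) if norm == "batch" else nn.Identity()


class ConvNormAct(nn.Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, norm: str,
                 rng: np.random.Generator, act: bool = True) -> None:
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride,
                              bias=(norm == "none"), rng=rng)
        self.norm = _norm_layer(cout, norm)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return ad.relu(y) if self.act else y


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with a shortcut: ``y = relu(F(x) + shortcut(x))``.

    The shortcut is the identity when shape is preserved, otherwise a
    stride-matched 1x1 projection. With ``norm='none'`` this is exactly the
    plain residual unit (conv -> relu -> conv, added to x, outer relu).
    """

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 norm: str = "none", rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, bias=(norm == "none"), rng=rng)
        self.norm1 = _norm_layer(cout, norm)
        self.conv2 = nn.Conv2d(cout, cout, 3, stride=1, bias=(norm == "none"), rng=rng)
        self.norm2 = _norm_layer(cout, norm)
        if cin != cout or stride != 1:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=(norm == "none"), rng=rng)
            self.proj_norm = _norm_layer(cout, norm)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        f = self.norm2(self.conv2(ad.relu(self.norm1(self.conv1(x)))))
        s = x if self.proj is None else self.proj_norm(self.proj(x))
        return ad.relu(ad.add(f, s))


class PlainBlock(nn.Module):
    """U-Net style double conv: (conv-norm-relu) x 2, first conv may stride."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 norm: str = "batch", rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c1 = ConvNormAct(cin, cout, 3, stride, norm, rng)
        self.c2 = ConvNormAct(cout, cout, 3, 1, norm, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.c2(self.c1(x))


class Encoder(nn.Module):
    """Stem at full resolution plus four downsampling stages of two blocks."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        block = ResidualBlock if cfg.use_residual else PlainBlock
        self.stem = ConvNormAct(cfg.in_channels, cfg.base_channels, 3, 1, cfg.norm, rng)
        prev = cfg.base_channels
        for i, ch in enumerate(cfg.stage_channels, start=1):
            setattr(self, f"stage{i}_a", block(prev, ch, stride=2, norm=cfg.norm, rng=rng))
            setattr(self, f"stage{i}_b", block(ch, ch, stride=1, norm=cfg.norm, rng=rng))
            prev = ch

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the five feature maps: stem plus one per stage."""
        feats = [self.stem(x)]
        h = feats[0]
        for i in range(1, 5):
            h = getattr(self, f"stage{i}_b")(getattr(self, f"stage{i}_a")(h))
            feats.append(h)
        return feats


def fpa_pyramid_sides(input_side: int) -> tuple[int, int, int]:
    """Spatial sides of the three FPA pyramid levels below ``input_side``."""
    if input_side < 8:
        raise ValueError("FPA needs an input side of at least 8 px")
    return input_side // 2, input_side // 4, input_side // 8


class FPA(nn.Module):
    """Feature pyramid attention bottleneck.

    Five parts: (i) a 1x1-convolved main branch; (ii-iv) a pyramid of
    7x7 / 5x5 / 3x3 convolution levels at 1/2, 1/4 and 1/8 resolution
    (two convolutions per level: a strided one entering the level and one
    before fusion), merged bottom-up by upsample-and-add and finally
    upsampled to the input size to gate the main branch multiplicatively;
    (v) a global-average-pooling branch (1x1 conv, broadcast back) added
    to the gated product. Output spatial size equals input spatial size.
    """

    def __init__(self, channels: int, input_side: int, norm: str,
                 rng: np.random.Generator) -> None:
        super().__init__()
        fpa_pyramid_sides(input_side)  # validates the side
        self.input_side = input_side
        c = channels
        self.main = ConvNormAct(c, c, 1, 1, norm, rng, act=False)
        self.down1 = ConvNormAct(c, c, 7, 2, norm, rng)
        self.lat1 = ConvNormAct(c, c, 7, 1, norm, rng)
        self.down2 = ConvNormAct(c, c, 5, 2, norm, rng)
        self.lat2 = ConvNormAct(c, c, 5, 1, norm, rng)
        self.down3 = ConvNormAct(c, c, 3, 2, norm, rng)
        self.lat3 = ConvNormAct(c, c, 3, 1, norm, rng)
        self.global_conv = nn.Conv2d(c, c, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        s = x.shape[2]
        s1, s2, s3 = fpa_pyramid_sides(s)
        d1 = self.down1(x)          # side/2
        d2 = self.down2(d1)         # side/4
        d3 = self.down3(d2)         # side/8
        u3 = ad.bilinear_resize(self.lat3(d3), s2, s2)
        m2 = ad.add(u3, self.lat2(d2))
        u2 = ad.bilinear_resize(m2, s1, s1)
        m1 = ad.add(u2, self.lat1(d1))
        gate = ad.bilinear_resize(m1, s, s)
        gated = ad.mul(self.main(x), gate)
        glob = self.global_conv(ad.global_avg_pool(x))  # (N, C, 1, 1)
        return ad.add(gated, glob)   # broadcast over the spatial axes


class DecoderStage(nn.Module):
    """Upsample 2x, concatenate the skip feature map, apply a double conv."""

    def __init__(self, cin: int, skip_ch: int, cfg: NetworkConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        block = ResidualBlock if cfg.use_residual else PlainBlock
        self.block = block(cin + skip_ch, skip_ch, stride=1, norm=cfg.norm, rng=rng)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        up = ad.bilinear_resize(x, skip.shape[2], skip.shape[3])
        return self.block(ad.concat([up, skip], axis=1))


class SegmentationNetwork(nn.Module):
    """Full encoder–FPA–decoder model producing per-pixel probabilities."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(cfg, rng)
        if cfg.use_fpa:
            self.bottleneck = FPA(cfg.stage_channels[-1], cfg.bottleneck_side,
                                  cfg.norm, rng)
        else:
            self.bottleneck = nn.Identity()
        chans = (cfg.base_channels,) + tuple(cfg.stage_channels)
        # decoder runs deepest-first: stage i consumes chans[i+1], emits chans[i]
        for i in range(4, 0, -1):
            setattr(self, f"dec{i}", DecoderStage(chans[i], chans[i - 1], cfg, rng))
        self.head = nn.Conv2d(cfg.base_channels, cfg.out_channels, 1, bias=True, rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=nn.DTYPE))
        if x.ndim == 2:
            x = Tensor(x.data[None, None])
        elif x.ndim == 3:
            x = Tensor(x.data[:, None])
        feats = self.encoder(x)
        h = self.bottleneck(feats[4])
        for i in range(4, 0, -1):
            h = getattr(self, f"dec{i}")(h, feats[i - 1])
        return ad.sigmoid(self.head(h))


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    return SegmentationNetwork(cfg, seed=seed)


def build_encoder(cfg: NetworkConfig, seed: int = 0) -> Encoder:
    return Encoder(cfg, np.random.default_rng(seed))


def build_fpa(channels: int, input_side: int, norm: str = "batch",
              seed: int = 0) -> FPA:
    return FPA(channels, input_side, norm, np.random.default_rng(seed))


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalars (running BN stats excluded)."""
    return int(sum(p.data.size for p in model.parameters()))


def conv_param_count(k: int, cin: int, cout: int, bias: bool = True) -> int:
    """Closed-form parameter count of one convolution layer."""
    return k * k * cin * cout + (cout if bias else 0)


def predict_proba(model: SegmentationNetwork, images: np.ndarray,
                  batch_size: int = 4) -> np.ndarray:
    """Run inference in eval mode without building the autodiff graph.

    ``images`` is (N, H, W) or (H, W); returns probabilities of the same
    leading shape with a channel axis: (N, C, H, W).
    """
    arr = np.asarray(images, dtype=nn.DTYPE)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    model.eval()
    outs = []
    with ad.no_grad():
        for i in range(0, arr.shape[0], batch_size):
            outs.append(model(arr[i:i + batch_size]).data)
    out = np.concatenate(outs, axis=0)
    return out[0] if squeeze else out
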