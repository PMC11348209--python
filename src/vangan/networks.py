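"""Generator and discriminator architectures.

Generators are 3-D deep residual U-Nets: an encoder/bridge/decoder of
residual units (instance norm -> ReLU -> 3x3x3 conv, twice, plus identity
shortcut) with skip connections, reflection padding throughout, He-normal
init and a tanh output that matches the [-1, 1] data range.

Discriminators are five-layer 3-D PatchGANs (4x4x4 kernels, strides
2,2,2,1,1, instance norm, leaky ReLU 0.2, 20% spatial dropout on the
middle layers) that emit a spatial grid of real/fake logits.  Annealed
Gaussian noise can be injected at the input and before every subsequent
convolution block for training stabilisation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .nn import (Conv3d, InstanceNorm3d, Module, SpatialDropout3d, Tensor,
                 concat)
from .nn import functional as F

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "ResidualUnit",
           "ResUNetGenerator", "PatchGANDiscriminator",
           "build_generator", "build_discriminator"]


@dataclass
class GeneratorConfig:
    levels: int = 4
    base_filters: int = 16
    kernel_size: int = 3
    in_channels: int = 1
    out_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")


@dataclass
class DiscriminatorConfig:
    layers: int = 5
    base_filters: int = 64
    kernel_size: int = 4
    strides: Tuple[int, ...] = (2, 2, 2, 1, 1)
    dropout_rate: float = 0.2
    leaky_slope: float = 0.2
    instance_norm: bool = True
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.layers != 5:
            raise ValueError("the PatchGAN used here has exactly 5 layers")
        if len(self.strides) != self.layers:
            raise ValueError("need one stride per layer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")


class ResidualUnit(Module):
    """Two pre-activation conv blocks plus an identity/1x1 shortcut."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.norm1 = InstanceNorm3d(in_ch)
        self.conv1 = Conv3d(in_ch, out_ch, kernel, rng=rng)
        self.norm2 = InstanceNorm3d(out_ch)
        self.conv2 = Conv3d(out_ch, out_ch, kernel, rng=rng)
        if in_ch != out_ch:
            self.shortcut = Conv3d(in_ch, out_ch, 1, bias=False, rng=rng)
        else:
            self.shortcut = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).relu())
        h = self.conv2(self.norm2(h).relu())
        s = x if self.shortcut is None else self.shortcut(x)
        return h + s


class ResUNetGenerator(Module):
    """Volume-to-volume residual U-Net with tanh output in [-1, 1]."""

    def __init__(self, cfg: GeneratorConfig | None = None):
        super().__init__()
        cfg = cfg or GeneratorConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        k = cfg.kernel_size
        self.stem = Conv3d(cfg.in_channels, f, k, rng=rng)
        enc_ch = [f * 2 ** i for i in range(cfg.levels)]
        self._enc_names: List[str] = []
        self._down_names: List[str] = []
        for i, ch in enumerate(enc_ch):
            setattr(self, f"enc{i}", ResidualUnit(ch, ch, k, rng))
            setattr(self, f"down{i}", Conv3d(ch, ch * 2, k, stride=2, rng=rng))
            self._enc_names.append(f"enc{i}")
            self._down_names.append(f"down{i}")
        bridge_ch = f * 2 ** cfg.levels
        self.bridge = ResidualUnit(bridge_ch, bridge_ch, k, rng)
        self._up_names: List[str] = []
        self._dec_names: List[str] = []
        for i in reversed(range(cfg.levels)):
            ch = enc_ch[i]
            setattr(self, f"up{i}", Conv3d(ch * 2, ch, k, rng=rng))
            setattr(self, f"dec{i}", ResidualUnit(ch * 2, ch, k, rng))
            self._up_names.append(f"up{i}")
            self._dec_names.append(f"dec{i}")
        self.head = Conv3d(f, cfg.out_channels, k, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        div = 2 ** self.cfg.levels
        for extent in x.shape[1:4]:
            if extent % div:
                raise ValueError(
                    f"spatial extent {extent} not divisible by 2^levels={div}")
        h = self.stem(x)
        skips = []
        for enc, down in zip(self._enc_names, self._down_names):
            h = getattr(self, enc)(h)
            skips.append(h)
            h = getattr(self, down)(h)
        h = self.bridge(h)
        for up, dec, skip in zip(self._up_names, self._dec_names,
                                 reversed(skips)):
            h = getattr(self, up)(F.upsample_nearest3d(h, 2))
            h = concat([h, skip], axis=-1)
            h = getattr(self, dec)(h)
        return self.head(h).tanh()


class PatchGANDiscriminator(Module):
    """Five-layer PatchGAN emitting a spatial logit grid.

    ``forward(x, noise_sigma, rng)`` adds N(0, sigma^2) noise to the input
    and before each subsequent convolution when ``noise_sigma > 0``; with
    sigma = 0 and dropout disabled the forward pass is deterministic.
    """

    def __init__(self, cfg: DiscriminatorConfig | None = None):
        super().__init__()
        cfg = cfg or DiscriminatorConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        chans = [f, f * 2, f * 4, f * 8, 1]
        in_ch = cfg.in_channels
        self._conv_names: List[str] = []
        self._norm_names: List[str | None] = []
        self._drop_names: List[str | None] = []
        for i, (out_ch, s) in enumerate(zip(chans, cfg.strides)):
            setattr(self, f"conv{i}", Conv3d(in_ch, out_ch, cfg.kernel_size,
                                             stride=s, rng=rng))
            self._conv_names.append(f"conv{i}")
            is_last = i == len(chans) - 1
            if i > 0 and not is_last and cfg.instance_norm:
                setattr(self, f"norm{i}", InstanceNorm3d(out_ch))
                self._norm_names.append(f"norm{i}")
            else:
                self._norm_names.append(None)
            if 0 < i < len(chans) - 1 and cfg.dropout_rate > 0:
                setattr(self, f"drop{i}", SpatialDropout3d(cfg.dropout_rate))
                self._drop_names.append(f"drop{i}")
            else:
                self._drop_names.append(None)
            in_ch = out_ch

    def forward(self, x: Tensor, noise_sigma: float = 0.0,
                rng: np.random.Generator | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if noise_sigma > 0 and rng is None:
            rng = np.random.default_rng(0)
        n_layers = len(self._conv_names)
        for i in range(n_layers):
            if noise_sigma > 0:
                eps = rng.normal(0.0, noise_sigma,
                                 size=x.shape).astype(np.float32)
                x = x + Tensor(eps)
            x = getattr(self, self._conv_names[i])(x)
            if i == n_layers - 1:
                break
            if self._norm_names[i] is not None:
                x = getattr(self, self._norm_names[i])(x)
            x = x.leaky_relu(self.cfg.leaky_slope)
            if self._drop_names[i] is not None:
                x = getattr(self, self._drop_names[i])(x, rng)
        return x


def build_generator(cfg: GeneratorConfig | None = None) -> ResUNetGenerator:
    return ResUNetGenerator(cfg)


def build_discriminator(cfg: DiscriminatorConfig | None = None
                        ) -> PatchGANDiscriminator:
    return PatchGANDiscriminator(cfg)
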