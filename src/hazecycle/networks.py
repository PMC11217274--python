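"""Network architectures for the cycle-consistent dehazing system.

Four archetypes:

* **Dehazing generator** — a U-net-style encoder with a residual trunk and
  *two* decoders: an image head producing the haze-free estimate J in
  [0, 1] (sigmoid) and a transmission head producing t in [T_MIN, 1]
  (rescaled sigmoid).  Both outputs are functions of the same hazy input,
  matching the scattering model I = J t + A (1 - t) they must recompose.
* **Translation generator** — identical trunk, single 3-channel image head;
  used for the clear -> hazy direction where no physics branch applies.
* **Detail discriminator** — a shallow 4-stage Conv-BatchNorm-LeakyReLU
  critic emitting a spatial patch map of real/fake scores; its small
  receptive field sensitises training to texture.
* **Structure discriminator** — a deeper critic downsampling the whole
  image to a fixed 4x4 sigmoid score block, judging global layout.

Channel widths follow a 64-128-256-[512 residual]-256-128-64 progression
scaled by ``width_multiplier``; the multiplier exists so that desk-scale
experiments train in minutes while ``1.0`` reproduces the full-width model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, crop2d, pad2d
from ._nn import (BatchNorm2d, Conv2d, ConvTranspose2d, InstanceNorm2d,
                  Module)
from .haze_physics import T_MIN

logger = logging.getLogger(__name__)

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "build_dehaze_generator",
           "build_translation_generator", "build_detail_discriminator",
           "build_structure_discriminator", "image_to_tensor",
           "tensor_to_image"]


@dataclass
class GeneratorConfig:
    base_channels: int = 64
    width_multiplier: float = 1.0
    n_residual_blocks: int = 5
    emit_transmission: bool = True
    normalization: str = "instance"

    def __post_init__(self):
        if self.base_channels * self.width_multiplier < 4:
            raise ValueError("base_channels * width_multiplier must be >= 4")
        if self.n_residual_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.normalization not in ("instance", "batch"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def widths(self) -> tuple:
        """(c1, c2, c3, c_res) channel widths after the multiplier."""
        m = self.width_multiplier
        c1 = max(4, int(round(self.base_channels * m)))
        return c1, 2 * c1, 4 * c1, 8 * c1


@dataclass
class DiscriminatorConfig:
    kind: str = "detail"
    base_channels: int = 64
    width_multiplier: float = 1.0
    input_size: int = 256  # structure discriminator only

    def __post_init__(self):
        if self.kind not in ("detail", "structure"):
            raise ValueError(f"unknown discriminator kind {self.kind!r}")
        if self.base_channels * self.width_multiplier < 4:
            raise ValueError("base_channels * width_multiplier must be >= 4")


# ---------------------------------------------------------------------------
# Image <-> tensor conversion
# ---------------------------------------------------------------------------

def image_to_tensor(img: np.ndarray) -> Tensor:
    """HxWx3 [0,1] float image -> 1x3xHxW Tensor."""
    arr = np.asarray(img, dtype=np.float32).transpose(2, 0, 1)[None]
    return Tensor(arr)


def tensor_to_image(t: Tensor) -> np.ndarray:
    """1xCxHxW Tensor -> HxWxC (squeezed to HxW if C == 1) float64 array."""
    arr = np.asarray(t.data, dtype=np.float64)[0].transpose(1, 2, 0)
    return arr[..., 0] if arr.shape[2] == 1 else arr


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _make_norm(kind: str, c: int) -> Module:
    return InstanceNorm2d(c) if kind == "instance" else BatchNorm2d(c)


class _ConvBlock(Module):
    def __init__(self, cin, cout, k, stride, norm, rng,
                 pad_mode="zero"):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, pad=k // 2,
                           pad_mode=pad_mode, rng=rng)
        self.norm = _make_norm(norm, cout)

    def __call__(self, x):
        return self.norm(self.conv(x)).relu()


class _ResidualBlock(Module):
    def __init__(self, c, norm, rng):
        super().__init__()
        self.conv1 = Conv2d(c, c, 3, pad=1, rng=rng)
        self.norm1 = _make_norm(norm, c)
        self.conv2 = Conv2d(c, c, 3, pad=1, rng=rng)
        self.norm2 = _make_norm(norm, c)

    def __call__(self, x):
        h = self.norm1(self.conv1(x)).relu()
        return self.norm2(self.conv2(h)) + x


class _Decoder(Module):
    """Deconv mirror with U-net skip concatenation; one output head."""

    def __init__(self, cfg: GeneratorConfig, out_channels: int, rng):
        super().__init__()
        c1, c2, c3, _ = cfg.widths()
        self.up1 = ConvTranspose2d(2 * c3, c2, rng=rng)   # H/4 -> H/2
        self.norm1 = _make_norm(cfg.normalization, c2)
        self.up2 = ConvTranspose2d(2 * c2, c1, rng=rng)   # H/2 -> H
        self.norm2 = _make_norm(cfg.normalization, c1)
        self.head = Conv2d(2 * c1, out_channels, 7, pad=3,
                           pad_mode="reflect", rng=rng)

    def __call__(self, trunk, e1, e2, e3):
        h = self.norm1(self.up1(concat([trunk, e3]))).relu()
        h = self.norm2(self.up2(concat([h, e2]))).relu()
        return self.head(concat([h, e1]))


class _GeneratorBase(Module):
    """Shared encoder + residual trunk; subclasses attach decoders.

    Total stride is 4; inputs whose sides are not multiples of 4 are
    reflection-padded up and the outputs cropped back, never rejected.
    """

    def __init__(self, cfg: GeneratorConfig, rng):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3, cr = cfg.widths()
        norm = cfg.normalization
        self.stem = _ConvBlock(3, c1, 7, 1, norm, rng, pad_mode="reflect")
        self.down1 = _ConvBlock(c1, c2, 3, 2, norm, rng)
        self.down2 = _ConvBlock(c2, c3, 3, 2, norm, rng)
        self.enter = _ConvBlock(c3, cr, 3, 1, norm, rng)
        self.blocks = _Sequential(
            [_ResidualBlock(cr, norm, rng)
             for _ in range(cfg.n_residual_blocks)])
        self.exit = _ConvBlock(cr, c3, 3, 1, norm, rng)

    def _encode(self, x: Tensor):
        n, c, h, w = x.shape
        ph = (-h) % 4
        pw = (-w) % 4
        if ph or pw:
            x = pad2d(x, (0, ph, 0, pw), mode="reflect")
        e1 = self.stem(x)
        e2 = self.down1(e1)
        e3 = self.down2(e2)
        trunk = self.exit(self.blocks(self.enter(e3)))
        return trunk, e1, e2, e3, (h, w)


class _Sequential(Module):
    def __init__(self, mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, f"m{i}", m)
        self._seq = mods

    def __call__(self, x):
        for m in self._seq:
            x = m(x)
        return x


class DehazeGenerator(_GeneratorBase):
    """Hazy image -> (haze-free estimate J in [0,1], transmission t in
    [T_MIN, 1])."""

    def __init__(self, cfg: GeneratorConfig, rng):
        super().__init__(cfg, rng)
        self.image_decoder = _Decoder(cfg, 3, rng)
        self.t_decoder = _Decoder(cfg, 1, rng)

    def __call__(self, x: Tensor):
        trunk, e1, e2, e3, (h, w) = self._encode(x)
        j = self.image_decoder(trunk, e1, e2, e3).sigmoid()
        t_raw = self.t_decoder(trunk, e1, e2, e3).sigmoid()
        t = T_MIN + (1.0 - T_MIN) * t_raw
        if j.shape[2] != h or j.shape[3] != w:
            j = crop2d(j, 0, h, 0, w)
            t = crop2d(t, 0, h, 0, w)
        return j, t


class TranslationGenerator(_GeneratorBase):
    """Plain domain-translation generator (clear -> hazy direction)."""

    def __init__(self, cfg: GeneratorConfig, rng):
        super().__init__(cfg, rng)
        self.image_decoder = _Decoder(cfg, 3, rng)

    def __call__(self, x: Tensor):
        trunk, e1, e2, e3, (h, w) = self._encode(x)
        j = self.image_decoder(trunk, e1, e2, e3).sigmoid()
        if j.shape[2] != h or j.shape[3] != w:
            j = crop2d(j, 0, h, 0, w)
        return j


class DetailDiscriminator(Module):
    """Patch critic: 4 Conv-BN-LeakyReLU stages (strides 2,2,2,1), then a
    1x1 convolution and sigmoid, giving an h' x w' map of patch scores."""

    def __init__(self, cfg: DiscriminatorConfig, rng):
        super().__init__()
        m = cfg.width_multiplier
        chans = [max(4, int(round(c * m)))
                 for c in (cfg.base_channels, cfg.base_channels * 2,
                           cfg.base_channels * 4, cfg.base_channels * 8)]
        strides = [2, 2, 2, 1]
        cin = 3
        stages = []
        for c, s in zip(chans, strides):
            stages.append(_DiscStage(cin, c, 4, s, rng))
            cin = c
        self.stages = _Sequential(stages)
        self.score = Conv2d(cin, 1, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h < 16 or w < 16:
            raise ValueError(
                f"detail discriminator needs >= 16x16 input, got {h}x{w}")
        return self.score(self.stages(x)).sigmoid()


class _DiscStage(Module):
    def __init__(self, cin, cout, k, stride, rng):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, pad=1, rng=rng)
        self.norm = BatchNorm2d(cout)

    def __call__(self, x):
        return self.norm(self.conv(x)).leaky_relu(0.2)


class StructureDiscriminator(Module):
    """Whole-image critic reducing the input to a fixed 4x4 score block.

    At the 256x256 default this is 7 convolution stages, the first six with
    stride-2 downsampling (256 -> 4).  For other power-of-two sizes the
    number of downsampling stages adapts so the output stays 4x4 (logged).
    """

    OUT = 4

    def __init__(self, cfg: DiscriminatorConfig, rng):
        super().__init__()
        size = cfg.input_size
        n_down = int(np.log2(size / self.OUT))
        if 2 ** n_down * self.OUT != size or n_down < 1:
            raise ValueError(
                f"structure discriminator needs a power-of-two input size "
                f">= 8 (got {size}); e.g. 256 for the 7-stage default")
        self.input_size = size
        m = cfg.width_multiplier
        b = cfg.base_channels
        full = [b, 2 * b, 4 * b, 8 * b, 8 * b, 8 * b, 8 * b]
        chans = [max(4, int(round(c * m))) for c in full[:n_down + 1]]
        if n_down != 6:
            logger.info("structure discriminator depth adjusted to %d "
                        "downsampling stages for input size %d", n_down, size)
        stages = []
        cin = 3
        for i, c in enumerate(chans):
            stride = 2 if i < n_down else 1
            k = 4 if stride == 2 else 3
            stages.append(_DiscStage(cin, c, k, stride, rng))
            cin = c
        self.stages = _Sequential(stages)
        self.score = Conv2d(cin, 1, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h != self.input_size or w != self.input_size:
            raise ValueError(
                f"structure discriminator configured for "
                f"{self.input_size}x{self.input_size} input, got {h}x{w}")
        return self.score(self.stages(x)).sigmoid()


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _rng(seed):
    return np.random.default_rng(seed)


def build_dehaze_generator(cfg: GeneratorConfig, seed: int = 0
                           ) -> DehazeGenerator:
    if not cfg.emit_transmission:
        raise ValueError("dehaze generator requires emit_transmission=True; "
                         "use build_translation_generator otherwise")
    return DehazeGenerator(cfg, _rng(seed))


def build_translation_generator(cfg: GeneratorConfig, seed: int = 0
                                ) -> TranslationGenerator:
    if cfg.emit_transmission:
        raise ValueError("translation generator has no transmission head; "
                         "set emit_transmission=False")
    return TranslationGenerator(cfg, _rng(seed))


def build_detail_discriminator(cfg: DiscriminatorConfig, seed: int = 0
                               ) -> DetailDiscriminator:
    return DetailDiscriminator(cfg, _rng(seed))


def build_structure_discriminator(cfg: DiscriminatorConfig, seed: int = 0
                                  ) -> StructureDiscriminator:
    return StructureDiscriminator(cfg, _rng(seed))
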