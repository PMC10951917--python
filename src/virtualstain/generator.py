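"""Dual-path encoder–decoder generator.

A shared 5-level residual encoder turns an S-slice bright-field stack
into a bottleneck representation; two decoders with encoder skip
connections then produce (i) a 2-channel fluorescent translation
(channel 0 = healthy nuclei, channel 1 = apoptotic nuclei, Tanh-bounded
to [−1, 1]) and (ii) a 3-class per-pixel probability map (healthy,
apoptotic, background — one more channel than the image head) via
SoftMax. The final translation gates each image channel by its class
probability: ``translation[c] = image[c] · mask[c]``, so pixels the mask
path calls background are suppressed in the rendered fluorescence.

Between the five up-sampling layers of the two decoders lie four
intervals; a 4-digit binary placement code selects which intervals carry
cross-attention modules (digit 1 = the interval between the two deepest
up-sampling layers). Single-path ablation variants replace the dual
decoders with one decoder and plain self-attention, with one or two
output channels and no mask gating.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .attention import CrossAttention2d, SelfAttention2d
from .autograd import Tensor, concat, upsample_nearest2x
from .nn import Conv2d, ConvTranspose2d, Module

VARIANTS = ("dual", "single_1ch", "single_2ch")

__all__ = [
    "GeneratorConfig",
    "Generator",
    "GeneratorOutput",
    "DownBlock",
    "UpBlock",
    "build_generator",
    "generate",
    "validate_placement_code",
]


def validate_placement_code(code: str) -> str:
    if not isinstance(code, str) or len(code) != 4 or any(c not in "01" for c in code):
        raise ValueError(
            f"placement code must be a 4-digit binary string, got {code!r}"
        )
    return code


@dataclass
class GeneratorConfig:
    """Architecture hyper-parameters.

    placement: 4-digit binary string; digit i marks decoder interval i
        (interval 1 = between the two deepest up-sampling layers).
    input_slices: number of bright-field z-slices S (conditioning channels).
    base_channels: channels after the first down-sampling; doubled per
        level, so the bottleneck holds 16× this many.
    levels: 5 down- and 5 up-sampling layers (fixed), hence 4 intervals.
    variant: "dual" (image + mask decoders, cross-attention) or the
        single-path ablations "single_1ch"/"single_2ch" (self-attention,
        no mask path, no gating).
    """

    placement: str = "0011"
    input_slices: int = 13
    base_channels: int = 32
    levels: int = 5
    variant: str = "dual"
    reduction_factor: int = 8
    spectral_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        validate_placement_code(self.placement)
        if self.levels != 5:
            raise ValueError("the architecture is fixed at 5 levels (4 attention intervals)")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.input_slices < 1:
            raise ValueError("input_slices must be >= 1")

    @property
    def n_attention_intervals(self) -> int:
        return self.levels - 1

    @property
    def out_channels(self) -> int:
        return 1 if self.variant == "single_1ch" else 2


class DownBlock(Module):
    """Residual down-sampling sub-module: 3×3 shape-invariant conv →
    4×4 stride-2 sampling conv, plus a strided 1×1 shortcut."""

    def __init__(self, in_channels: int, out_channels: int, rng,
                 spectral_norm: bool = True, slope: float = 0.2):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 3, 1, 1, rng, spectral_norm)
        self.down = Conv2d(out_channels, out_channels, 4, 2, 1, rng, spectral_norm)
        self.shortcut = Conv2d(in_channels, out_channels, 1, 2, 0, rng, spectral_norm)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        if h % 2 or w % 2:
            raise ValueError(f"down-sampling needs even spatial dims, got {h}x{w}")
        y = self.conv(x).leaky_relu(self.slope)
        y = self.down(y)
        return (y + self.shortcut(x)).leaky_relu(self.slope)


class Bottleneck(Module):
    def __init__(self, channels: int, rng, spectral_norm: bool = True):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, 1, 1, rng, spectral_norm)
        self.conv2 = Conv2d(channels, channels, 3, 1, 1, rng, spectral_norm)
        self.shortcut = Conv2d(channels, channels, 1, 1, 0, rng, spectral_norm)

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv1(x).leaky_relu(0.2)
        y = self.conv2(y)
        return (y + self.shortcut(x)).leaky_relu(0.2)


class UpBlock(Module):
    """Residual up-sampling sub-module: transposed 4×4 stride-2 conv,
    encoder skip concatenated before the 3×3 shape-invariant conv, and a
    nearest-upsample + 1×1 shortcut."""

    def __init__(self, in_channels: int, skip_channels: int, out_channels: int,
                 rng, spectral_norm: bool = True):
        super().__init__()
        self.up = ConvTranspose2d(in_channels, out_channels, 4, 2, 1, rng, spectral_norm)
        self.conv = Conv2d(out_channels + skip_channels, out_channels, 3, 1, 1,
                           rng, spectral_norm)
        self.shortcut = Conv2d(in_channels, out_channels, 1, 1, 0, rng, spectral_norm)
        self.skip_channels = skip_channels

    def forward(self, x: Tensor, skip: Tensor | None = None) -> Tensor:
        y = self.up(x).relu()
        if self.skip_channels:
            if skip is None:
                raise ValueError("block configured with a skip connection but none given")
            if (skip.shape[2], skip.shape[3]) != (2 * x.shape[2], 2 * x.shape[3]):
                raise ValueError(
                    f"skip spatial dims must be 2x the input: {skip.shape[2:]} vs {x.shape[2:]}"
                )
            if skip.shape[1] != self.skip_channels:
                raise ValueError(
                    f"skip has {skip.shape[1]} channels, block expects {self.skip_channels}"
                )
            y = concat([y, skip], axis=1)
        elif skip is not None:
            raise ValueError("block configured without a skip connection")
        y = self.conv(y)
        return (y + self.shortcut(upsample_nearest2x(x))).relu()


class GeneratorOutput(NamedTuple):
    image: np.ndarray | Tensor
    mask: np.ndarray | Tensor | None
    translation: np.ndarray | Tensor


class Generator(Module):
    """See module docstring; construct with :func:`build_generator`."""

    def __init__(self, config: GeneratorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        b, sn = config.base_channels, config.spectral_norm
        enc_ch = [b * 2**i for i in range(5)]  # b … 16b
        # shared encoder
        self.enc1 = DownBlock(config.input_slices, enc_ch[0], rng, sn)
        self.enc2 = DownBlock(enc_ch[0], enc_ch[1], rng, sn)
        self.enc3 = DownBlock(enc_ch[1], enc_ch[2], rng, sn)
        self.enc4 = DownBlock(enc_ch[2], enc_ch[3], rng, sn)
        self.enc5 = DownBlock(enc_ch[3], enc_ch[4], rng, sn)
        self.bottleneck = Bottleneck(enc_ch[4], rng, sn)
        # decoder channel plan: up_i input → output, with encoder skips at
        # levels 1–4 and a skipless final up-sampling
        dec_in = [enc_ch[4], enc_ch[3], enc_ch[2], enc_ch[1], enc_ch[0]]
        dec_skip = [enc_ch[3], enc_ch[2], enc_ch[1], enc_ch[0], 0]
        dec_out = [enc_ch[3], enc_ch[2], enc_ch[1], enc_ch[0], enc_ch[0]]
        self._dec_out = dec_out

        def make_decoder(prefix):
            for i in range(5):
                setattr(self, f"{prefix}{i + 1}",
                        UpBlock(dec_in[i], dec_skip[i], dec_out[i], rng, sn))

        make_decoder("img_up")
        if config.variant == "dual":
            make_decoder("mask_up")
            self.mask_head = Conv2d(enc_ch[0], 3, 1, 1, 0, rng, sn)
        self.image_head = Conv2d(enc_ch[0], config.out_channels, 1, 1, 0, rng, sn)
        # attention modules at flagged intervals; interval i sits after up_i,
        # acting on feature maps with dec_out[i-1] channels
        self._attention: dict[int, Module] = {}
        for i, digit in enumerate(config.placement, start=1):
            if digit != "1":
                continue
            ch = dec_out[i - 1]
            if config.variant == "dual":
                mod = CrossAttention2d(ch, config.reduction_factor, rng, sn)
            else:
                mod = SelfAttention2d(ch, config.reduction_factor, rng, sn)
            setattr(self, f"attn{i}", mod)
            self._attention[i] = mod

    # ------------------------------------------------------------------ info
    @property
    def n_attention_modules(self) -> int:
        return len(self._attention)

    @property
    def attention_intervals(self) -> tuple[int, ...]:
        return tuple(sorted(self._attention))

    def set_attention_gamma(self, value: float):
        """Set every attention γ (all branches) to ``value``."""
        for name, p in self.named_parameters():
            if name.endswith("gamma") or name.endswith("gamma_cross"):
                p.data[...] = value

    # --------------------------------------------------------------- forward
    def _check_input(self, x: Tensor):
        n, s, h, w = x.shape
        if s != self.config.input_slices:
            raise ValueError(
                f"generator configured for {self.config.input_slices} slices, got {s}"
            )
        if h % 32 or w % 32:
            raise ValueError(
                f"spatial dims must be divisible by 32 (5 down-samplings); "
                f"got {h}x{w} — pad to {-(-h // 32) * 32}x{-(-w // 32) * 32}"
            )

    def forward(self, x: Tensor) -> GeneratorOutput:
        self._check_input(x)
        e1 = self.enc1(x)
        e2 = self.enc2(e1)
        e3 = self.enc3(e2)
        e4 = self.enc4(e3)
        e5 = self.enc5(e4)
        bott = self.bottleneck(e5)
        skips = [e4, e3, e2, e1, None]
        if self.config.variant == "dual":
            fi, fm = bott, bott
            for i in range(1, 6):
                fi = getattr(self, f"img_up{i}")(fi, skips[i - 1])
                fm = getattr(self, f"mask_up{i}")(fm, skips[i - 1])
                if i in self._attention:
                    fi, fm = self._attention[i](fi, fm)
            image = self.image_head(fi).tanh()
            mask = self.mask_head(fm).softmax(axis=1)
            translation = image * mask[:, :2]
            return GeneratorOutput(image, mask, translation)
        f = bott
        for i in range(1, 6):
            f = getattr(self, f"img_up{i}")(f, skips[i - 1])
            if i in self._attention:
                f = self._attention[i](f)
        image = self.image_head(f).tanh()
        return GeneratorOutput(image, None, image)


def build_generator(config: GeneratorConfig) -> Generator:
    """Instantiate a generator from its configuration."""
    return Generator(config)


def generate(g: Generator, x: np.ndarray) -> GeneratorOutput:
    """Run a bright-field stack through the generator (inference).

    ``x`` is (S,H,W) or (N,S,H,W) with values in [0, 1]; returns NumPy
    arrays, squeezing the batch axis when the input had none.
    """
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("bright-field stack must be min–max normalized to [0, 1]")
    was_training = g.training
    g.eval()
    out = g(Tensor(x))
    if was_training:
        g.train()
    image = out.image.data
    mask = None if out.mask is None else out.mask.data
    trans = out.translation.data
    if squeeze:
        image, trans = image[0], trans[0]
        mask = None if mask is None else mask[0]
    return GeneratorOutput(image, mask, trans)
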