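"""Conditional PatchGAN discriminator with spectral normalization.

The discriminator scores bright-field/fluorescence pairs patchwise: the
S-slice conditioning stack and the 2-channel fluorescent image are
concatenated along channels, passed through residual down-sampling
sub-modules (the same structure as the generator's encoder), and mapped
by a final 1-channel convolution to an N×N grid of real/fake logits.
Each logit sees only a bounded sub-window of the input, so patches are
penalized independently; self-attention modules can be inserted after
the deeper down-sampling levels (identity at initialization, γ = 0).
Spectral normalization on every convolution bounds the layer Lipschitz
constants, stabilizing adversarial training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import SelfAttention2d
from .autograd import Tensor, concat
from .generator import DownBlock
from .nn import Conv2d, Module
from .nn import spectral_normalize  # re-exported: part of this module's surface

__all__ = ["DiscriminatorConfig", "PatchDiscriminator", "discriminate", "spectral_normalize"]


@dataclass
class DiscriminatorConfig:
    input_slices: int = 13
    image_channels: int = 2
    base_channels: int = 32
    n_down: int = 4
    #: 1-based down-sampling levels followed by self-attention ("higher levels")
    attention_levels: tuple[int, ...] = (3, 4)
    reduction_factor: int = 8
    spectral_norm: bool = True
    seed: int = 0

    @property
    def in_channels(self) -> int:
        return self.input_slices + self.image_channels

    def __post_init__(self):
        if any(l < 1 or l > self.n_down for l in self.attention_levels):
            raise ValueError("attention_levels must lie in 1..n_down")


class PatchDiscriminator(Module):
    def __init__(self, config: DiscriminatorConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        b, sn = config.base_channels, config.spectral_norm
        ch_in = config.in_channels
        self.blocks: list[Module] = []
        for lvl in range(1, config.n_down + 1):
            ch_out = b * 2 ** (lvl - 1)
            blk = DownBlock(ch_in, ch_out, rng, sn)
            setattr(self, f"down{lvl}", blk)
            self.blocks.append(blk)
            if lvl in config.attention_levels:
                attn = SelfAttention2d(ch_out, config.reduction_factor, rng, sn)
                setattr(self, f"attn{lvl}", attn)
                self.blocks.append(attn)
            ch_in = ch_out
        self.head = Conv2d(ch_in, 1, 3, 1, 1, rng, sn)

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        if x.shape[2:] != y.shape[2:]:
            raise ValueError(
                f"stack and image spatial dims differ: {x.shape[2:]} vs {y.shape[2:]}"
            )
        h = concat([x, y], axis=1)
        for blk in self.blocks:
            h = blk(h)
        return self.head(h)  # (N, 1, H/2^n_down, W/2^n_down) logits


def discriminate(d: PatchDiscriminator, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Score a (S,H,W) stack against a (2,H,W) image; returns the patch
    logit grid as a 2-D array."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x, y = x[None], y[None]
    was_training = d.training
    d.eval()
    out = d(Tensor(x), Tensor(y)).data[:, 0]
    if was_training:
        d.train()
    return out[0] if squeeze else out
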