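"""Self-attention and cross-attention operators for feature maps.

Both operators compute position-wise long-range dependencies over the
H·W spatial positions of a feature map: 1×1 convolutions project the
input into query/key/value sequences, attention logits are the
query–key inner products, a row-wise SoftMax turns them into weights,
and the weighted sum of values is projected back to the input channel
count. The attended map enters through a residual ``x + γ·o(x)`` with a
learnable scale γ initialized to zero, so every attention module is an
exact identity at initialization.

The cross-attention operator couples the image-generation and
mask-generation decoders: each path keeps its own self-attention, and an
additional cross term draws its query from the image path and its
key/value from the mask path. The cross branch (with its own γ-residual
on the image features) is channel-concatenated with the image
self-attention output and reduced by a 1×1 projection so downstream
shapes do not depend on attention placement. The mask path receives no
cross information — a single plain decoder is enough for semantic
segmentation, so only the image path is enriched.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .nn import Conv2d, Module


def _as_batched(x) -> tuple[Tensor, bool]:
    """Accept (C,H,W) or (N,C,H,W); return (N,C,H,W) tensor."""
    t = x if isinstance(x, Tensor) else Tensor(x)
    if t.ndim == 3:
        return t.reshape(1, *t.shape), True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"expected a (C,H,W) or (N,C,H,W) feature map, got {t.shape}")


class SelfAttention2d(Module):
    """SAGAN-style self-attention over the spatial positions of (N,C,H,W).

    Parameters
    ----------
    channels : input/output channel count C.
    reduction_factor : query/key projections use max(1, C // reduction_factor)
        channels (the usual C/8 convention).
    rng : seeded generator for projection weights.
    spectral_norm : apply spectral normalization to the 1×1 projections.
    """

    def __init__(self, channels: int, reduction_factor: int = 8,
                 rng: np.random.Generator | None = None, spectral_norm: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if channels < 1:
            raise ValueError("attention needs at least one channel")
        self.channels = channels
        self.reduction_factor = reduction_factor
        inner = max(1, channels // reduction_factor)
        self.query = Conv2d(channels, inner, 1, rng=rng, spectral_norm=spectral_norm)
        self.key = Conv2d(channels, inner, 1, rng=rng, spectral_norm=spectral_norm)
        self.value = Conv2d(channels, channels, 1, rng=rng, spectral_norm=spectral_norm)
        self.out_proj = Conv2d(channels, channels, 1, rng=rng, spectral_norm=spectral_norm)
        self.register_parameter("gamma", np.zeros(()))

    # -- attended map o(x), without the residual -------------------------------
    def attended(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h * w < 1:
            raise ValueError("empty spatial grid")
        q = self.query(x).reshape(n, -1, h * w).transpose(0, 2, 1)  # (N, P, Ci)
        k = self.key(x).reshape(n, -1, h * w)                       # (N, Ci, P)
        v = self.value(x).reshape(n, c, h * w).transpose(0, 2, 1)   # (N, P, C)
        weights = (q @ k).softmax(axis=-1)                          # (N, P, P)
        o = (weights @ v).transpose(0, 2, 1).reshape(n, c, h, w)
        return self.out_proj(o)

    def attention_weights(self, x) -> np.ndarray:
        """Row-stochastic (N, P, P) attention matrix, for inspection."""
        xb, _ = _as_batched(x)
        n, c, h, w = xb.shape
        q = self.query(xb).reshape(n, -1, h * w).transpose(0, 2, 1)
        k = self.key(xb).reshape(n, -1, h * w)
        return (q @ k).softmax(axis=-1).data

    def forward(self, x):
        xb, squeeze = _as_batched(x)
        if xb.shape[1] != self.channels:
            raise ValueError(
                f"attention configured for {self.channels} channels, got {xb.shape[1]}"
            )
        y = xb + self.gamma * self.attended(xb)
        return y.reshape(y.shape[1:]) if squeeze else y


class CrossAttention2d(Module):
    """Dual-path attention coupling the image and mask decoders.

    ``forward(x_img, x_mask)`` returns ``(y_img, y_mask)`` where

    * ``y_mask = x_mask + γ_m · o_self(x_mask)`` — the mask path is plain
      self-attention;
    * the image path concatenates its self-attention branch
      ``x_img + γ_i · o_self(x_img)`` with a cross branch
      ``x_img + γ_c · o_cross`` whose query comes from ``x_img`` and whose
      key/value come from ``x_mask``, then restores the channel count with
      a 1×1 projection.

    The post-concatenation projection is initialized to average the two
    halves, so with all three γ at zero the module passes ``x_img``
    through unchanged.
    """

    def __init__(self, channels: int, reduction_factor: int = 8,
                 rng: np.random.Generator | None = None, spectral_norm: bool = True):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.image_attn = SelfAttention2d(channels, reduction_factor, rng, spectral_norm)
        self.mask_attn = SelfAttention2d(channels, reduction_factor, rng, spectral_norm)
        inner = max(1, channels // reduction_factor)
        self.cross_query = Conv2d(channels, inner, 1, rng=rng, spectral_norm=spectral_norm)
        self.cross_key = Conv2d(channels, inner, 1, rng=rng, spectral_norm=spectral_norm)
        self.cross_value = Conv2d(channels, channels, 1, rng=rng, spectral_norm=spectral_norm)
        self.cross_out = Conv2d(channels, channels, 1, rng=rng, spectral_norm=spectral_norm)
        self.register_parameter("gamma_cross", np.zeros(()))
        # merge 2C→C, initialized to the mean of the two halves (identity at γ=0);
        # no spectral norm here so that the exact averaging survives inspection
        merge = Conv2d(2 * channels, channels, 1, rng=rng, spectral_norm=False)
        eye = np.zeros((channels, 2 * channels, 1, 1))
        for c in range(channels):
            eye[c, c, 0, 0] = 0.5
            eye[c, channels + c, 0, 0] = 0.5
        merge.weight.data = eye
        merge.bias.data[:] = 0.0
        self.merge = merge

    def cross_attended(self, x_img: Tensor, x_mask: Tensor) -> Tensor:
        """The raw cross term: SoftMax(Q_img·K_maskᵀ)·V_mask, projected."""
        n, c, h, w = x_img.shape
        q = self.cross_query(x_img).reshape(n, -1, h * w).transpose(0, 2, 1)
        k = self.cross_key(x_mask).reshape(n, -1, h * w)
        v = self.cross_value(x_mask).reshape(n, c, h * w).transpose(0, 2, 1)
        weights = (q @ k).softmax(axis=-1)
        o = (weights @ v).transpose(0, 2, 1).reshape(n, c, h, w)
        return self.cross_out(o)

    def forward(self, x_img, x_mask):
        xi, squeeze = _as_batched(x_img)
        xm, _ = _as_batched(x_mask)
        if xi.shape[2:] != xm.shape[2:]:
            raise ValueError(
                f"image and mask features must share spatial dims, got "
                f"{xi.shape[2:]} vs {xm.shape[2:]}"
            )
        y_mask = xm + self.mask_attn.gamma * self.mask_attn.attended(xm)
        self_branch = xi + self.image_attn.gamma * self.image_attn.attended(xi)
        cross_branch = xi + self.gamma_cross * self.cross_attended(xi, xm)
        y_img = self.merge(concat([self_branch, cross_branch], axis=1))
        if squeeze:
            return y_img.reshape(y_img.shape[1:]), y_mask.reshape(y_mask.shape[1:])
        return y_img, y_mask
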