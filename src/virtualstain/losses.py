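"""Training objectives and image-quality metrics.

The generator objective is a weighted sum of three terms: the
non-saturating adversarial loss from the patch discriminator, a
"conventional" reconstruction loss α·L1 + (1−α)·(1−SSIM) weighted by
λ (two orders of magnitude above the adversarial term, the pix2pix
precedent), and the per-pixel cross-entropy of the 3-class mask. The
mask weight is dynamic: it starts high (250) so the segmentation path
converges first and feeds credible spatial information to the
cross-attention modules, then decays 10% every 1,500 epochs down to a
floor of 2.5.

Every function accepts either NumPy arrays (returning floats, for
evaluation) or autograd :class:`~virtualstain.autograd.Tensor` inputs
(returning Tensors, for training) — the evaluation metrics and the loss
share one implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, conv2d

__all__ = [
    "MaskWeightSchedule",
    "LossConfig",
    "adversarial_losses",
    "ssim",
    "conventional_loss",
    "mask_loss",
    "mask_weight",
    "total_generator_loss",
    "metrics",
]


@dataclass
class MaskWeightSchedule:
    """Stepwise-decaying weight for the mask cross-entropy term."""

    initial: float = 250.0
    decay: float = 0.9
    period_epochs: int = 1500
    floor: float = 2.5

    def __post_init__(self):
        if not (self.initial > self.floor > 0):
            raise ValueError("schedule requires initial > floor > 0")
        if not (0 < self.decay < 1):
            raise ValueError("decay must lie in (0, 1)")


@dataclass
class LossConfig:
    """Weights and constants of the generator objective.

    lambda_conv : weight of the reconstruction loss vs the adversarial loss.
    alpha : balance between L1 and SSIM distance within the reconstruction
        loss (1 → pure L1).
    schedule : dynamic mask-loss weight (see :class:`MaskWeightSchedule`).
    data_range : dynamic range L of the images entering the loss; Tanh
        outputs span [−1, 1], hence 2.
    k1, k2 : SSIM stabilization constants; c1 = (k1·L)², c2 = (k2·L)².
    """

    lambda_conv: float = 100.0
    alpha: float = 0.5
    schedule: MaskWeightSchedule = field(default_factory=MaskWeightSchedule)
    data_range: float = 2.0
    k1: float = 0.01
    k2: float = 0.03
    ssim_window: int | None = 11
    ssim_sigma: float = 1.5

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_conv <= 0:
            raise ValueError("lambda_conv must be positive")

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def adversarial_losses(real_scores, fake_scores):
    """Patchwise binary cross-entropy of the minimax game.

    loss_D = mean −[log σ(real) + log(1 − σ(fake))] (sum of the two patch
    means); loss_G_adv = mean −log σ(fake), the non-saturating generator
    form. Raw logits in, scalars out.
    """
    real, tr = _wrap(real_scores)
    fake, tf = _wrap(fake_scores)
    loss_d = (-real).softplus().mean() + fake.softplus().mean()
    loss_g = (-fake).softplus().mean()
    if tr or tf:
        return loss_d, loss_g
    return float(loss_d.data), float(loss_g.data)


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _flatten_images(x: Tensor) -> Tensor:
    """(H,W) | (C,H,W) | (N,C,H,W) → (B,1,H,W) treating channels as batch."""
    if x.ndim == 2:
        return x.reshape(1, 1, *x.shape)
    if x.ndim == 3:
        return x.reshape(x.shape[0], 1, *x.shape[1:])
    if x.ndim == 4:
        n, c, h, w = x.shape
        return x.reshape(n * c, 1, h, w)
    raise ValueError(f"expected 2-4 dimensional image, got shape {x.shape}")


def ssim(x, y, config: LossConfig | None = None, *, data_range: float | None = None):
    """Mean structural similarity of two images of equal shape.

    Local statistics use an 11×11 Gaussian window (σ = 1.5); with
    ``config.ssim_window = None``, or when the image is smaller than the
    window, statistics are global (uniform window over the whole image).
    Symmetric in its arguments; 1 exactly when ``x is y`` elementwise.
    """
    xt, tx = _wrap(x)
    yt, ty = _wrap(y)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    cfg = config or LossConfig(data_range=1.0)
    if data_range is not None:
        c1 = (cfg.k1 * data_range) ** 2
        c2 = (cfg.k2 * data_range) ** 2
    else:
        c1, c2 = cfg.c1, cfg.c2
    xf, yf = _flatten_images(xt), _flatten_images(yt)
    h, w = xf.shape[2], xf.shape[3]
    win = cfg.ssim_window
    if win is None or min(h, w) < (win or 0):
        kernel = np.full((1, 1, h, w), 1.0 / (h * w))
        k = Tensor(kernel)

        def smooth(t):
            return conv2d(t, k)
    else:
        # separable Gaussian window: two 1-D passes
        r = np.arange(win) - (win - 1) / 2.0
        g1 = np.exp(-(r**2) / (2 * cfg.ssim_sigma**2))
        g1 = g1 / g1.sum()
        kv = Tensor(g1.reshape(1, 1, win, 1))
        kh = Tensor(g1.reshape(1, 1, 1, win))

        def smooth(t):
            return conv2d(conv2d(t, kv), kh)

    mu_x, mu_y = smooth(xf), smooth(yf)
    sxx = smooth(xf * xf) - mu_x * mu_x
    syy = smooth(yf * yf) - mu_y * mu_y
    sxy = smooth(xf * yf) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x * mu_x + mu_y * mu_y + c1) * (sxx + syy + c2)
    val = (num / den).mean()
    return val if (tx or ty) else float(val.data)


def conventional_loss(image, target, config: LossConfig | None = None):
    """α·L1 + (1−α)·(1 − SSIM); zero iff the images are identical."""
    cfg = config or LossConfig()
    xt, tx = _wrap(image)
    yt, ty = _wrap(target)
    if xt.shape != yt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {yt.shape}")
    l1 = (xt - yt).abs().mean()
    if cfg.alpha == 1.0:
        out = l1
    else:
        d_ssim = 1.0 - ssim(xt, yt, cfg)
        out = cfg.alpha * l1 + (1.0 - cfg.alpha) * d_ssim
    return out if (tx or ty) else float(out.data)


def mask_loss(mask, labels):
    """Mean per-pixel cross-entropy of the 3-class probability map.

    ``mask`` is (3,H,W) or (N,3,H,W) with per-pixel channel sums of 1;
    ``labels`` holds classes {0: healthy, 1: apoptotic, 2: background}.
    """
    mt, tm = _wrap(mask)
    labels = np.asarray(labels)
    if mt.ndim == 3:
        mt = mt.reshape(1, *mt.shape)
        labels = labels[None]
    n_classes = mt.shape[1]
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    onehot = np.zeros(mt.shape)
    for c in range(n_classes):
        onehot[:, c] = labels == c
    p_true = (mt * Tensor(onehot)).sum(axis=1)
    out = -((p_true + 1e-12).log()).mean()
    return out if tm else float(out.data)


def mask_weight(epoch: int, config: LossConfig | None = None) -> float:
    """Dynamic weight of the mask loss: max(floor, initial·decay^⌊e/period⌋)."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    s = (config or LossConfig()).schedule
    return max(s.floor, s.initial * s.decay ** (epoch // s.period_epochs))


def total_generator_loss(loss_G_adv, conv, mask, epoch: int,
                         config: LossConfig | None = None):
    """loss_G_adv + λ·conventional + w(epoch)·mask."""
    cfg = config or LossConfig()
    return loss_G_adv + cfg.lambda_conv * conv + mask_weight(epoch, cfg) * mask


def metrics(pred, target, *, data_range: float = 1.0) -> dict[str, float]:
    """MAE, SSIM and PSNR between two images of equal shape.

    PSNR = 10·log10(L²/MSE) in dB, +inf for identical images.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    mae = float(np.abs(p - t).mean())
    mse = float(((p - t) ** 2).mean())
    psnr = float("inf") if mse == 0 else 10.0 * np.log10(data_range**2 / mse)
    s = ssim(p, t, LossConfig(data_range=data_range), data_range=data_range)
    return {"mae": mae, "ssim": s, "psnr": psnr}
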