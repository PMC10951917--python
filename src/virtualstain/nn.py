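"""Layers, spectral normalization and the Adam optimizer.

Conventions follow the image-to-image translation literature: convolution
weights are He-initialized, spectral normalization divides each kernel
(reshaped to 2-D) by its leading singular value estimated with persistent
power-iteration vectors, and the optimizer is Adam with β₁=0.5, β₂=0.999.
"""

from __future__ import annotations

import logging

import numpy as np

from .autograd import Tensor, conv2d, conv_transpose2d

logger = logging.getLogger(__name__)

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Adam",
    "spectral_normalize",
]


def spectral_normalize(weight: np.ndarray, n_iterations: int = 20,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Divide ``weight`` by its largest singular value (power iteration).

    Conv kernels are reshaped to 2-D (out_channels × rest) first. An
    all-zero weight has no defined leading singular direction; it is
    returned unchanged with a warning.
    """
    w = np.asarray(weight, dtype=np.float64)
    mat = w.reshape(w.shape[0], -1)
    if not np.any(mat):
        logger.warning("spectral_normalize: all-zero weight left unchanged")
        return w.copy()
    rng = rng or np.random.default_rng(0)
    u = rng.standard_normal(mat.shape[0])
    u /= np.linalg.norm(u)
    v = None
    for _ in range(max(1, n_iterations)):
        v = mat.T @ u
        v /= np.linalg.norm(v) + 1e-12
        u = mat @ v
        u /= np.linalg.norm(u) + 1e-12
    sigma = float(u @ mat @ v)
    return w / sigma


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        p = Tensor(value, requires_grad=True)
        self._params[name] = p
        object.__setattr__(self, name, p)
        return p

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for n, m in self._modules.items():
            yield from m.named_modules(prefix + n + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, _ConvBase):  # persistent power-iteration state
                out[name + "__sn_u"] = m._u.copy()
                out[name + "__sn_v"] = m._v.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()
        for name, m in self.named_modules():
            if isinstance(m, _ConvBase) and name + "__sn_u" in state:
                m._u = np.asarray(state[name + "__sn_u"]).copy()
                m._v = np.asarray(state[name + "__sn_v"]).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class _ConvBase(Module):
    """Shared machinery for (transposed) convolutions with spectral norm."""

    #: power-iteration steps per forward pass while training; many more in
    #: eval mode so σ₁ estimates are tight when the network is inspected
    #: (the matrices are small, so the extra iterations are cheap).
    train_power_iterations = 1
    eval_power_iterations = 100

    def __init__(self, weight_shape, bias_channels, rng: np.random.Generator,
                 spectral_norm: bool = True, fan_in: int | None = None):
        super().__init__()
        scale = np.sqrt(2.0 / max(1, fan_in))
        self.register_parameter("weight", rng.standard_normal(weight_shape) * scale)
        self.register_parameter("bias", np.zeros(bias_channels))
        self.spectral_norm = spectral_norm
        mat_rows = weight_shape[0]
        mat_cols = int(np.prod(weight_shape[1:]))
        u = rng.standard_normal(mat_rows)
        self._u = u / np.linalg.norm(u)
        self._v = np.zeros(mat_cols)

    def _power_iterate(self, n_iter: int, persist: bool):
        mat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        if not np.any(mat):
            return None
        u = self._u
        for _ in range(n_iter):
            v = mat.T @ u
            v /= np.linalg.norm(v) + 1e-12
            u = mat @ v
            u /= np.linalg.norm(u) + 1e-12
        if persist:  # only training steps advance the persistent vectors,
            self._u, self._v = u, v  # keeping inference passes deterministic
        return u, v

    def effective_weight(self) -> Tensor:
        """Weight after spectral normalization (grad flows through σ)."""
        w = self.weight
        if not self.spectral_norm:
            return w
        n_iter = self.train_power_iterations if self.training else self.eval_power_iterations
        uv = self._power_iterate(n_iter, persist=self.training)
        if uv is None:
            logger.warning("all-zero conv weight: spectral norm skipped")
            return w
        u, v = uv
        wm = w.reshape(w.data.shape[0], -1)
        # σ = uᵀ W v with u, v held constant; dividing by the Tensor σ keeps
        # the gradient of the normalization itself (as in the cited scheme)
        sigma = (Tensor(u[None, :]) @ wm @ Tensor(v[:, None])).reshape(())
        return w / sigma

    def top_singular_value(self) -> float:
        mat = self.effective_weight().data.reshape(self.weight.data.shape[0], -1)
        return float(np.linalg.svd(mat, compute_uv=False)[0])


class Conv2d(_ConvBase):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, rng=None, spectral_norm=True):
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        super().__init__((out_channels, in_channels, k, k), out_channels, rng,
                         spectral_norm, fan_in=in_channels * k * k)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_weight(), self.bias,
                      stride=self.stride, padding=self.padding)


class ConvTranspose2d(_ConvBase):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 2, padding: int = 1, rng=None, spectral_norm=True):
        rng = rng if rng is not None else np.random.default_rng(0)
        k = kernel_size
        super().__init__((in_channels, out_channels, k, k), out_channels, rng,
                         spectral_norm, fan_in=in_channels * k * k)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.effective_weight(), self.bias,
                                stride=self.stride, padding=self.padding)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
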