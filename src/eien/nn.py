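"""Layers, parameter containers, resampling matrices and Adam.

Everything here is shared by the decomposition and illumination-correction
networks.  Parameters are float32; the layer forward functions operate on
``autodiff.Tensor`` objects in (N, C, H, W) layout.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv2d, scale_axis

__all__ = [
    "Module",
    "Conv2d",
    "Adam",
    "bilinear_matrix",
    "adaptive_avg_matrix",
    "resize_bilinear",
    "adaptive_avg_pool",
    "gradient_map_t",
]


class Module:
    """Parameter container with recursive discovery, like small DL kits."""

    def parameters(self) -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                for sub, p in value.parameters():
                    yield f"{name}.{sub}", p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters():
                            yield f"{name}.{i}.{sub}", p

    def parameter_count(self) -> int:
        return sum(p.data.size for _, p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state does not match architecture: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for _, p in self.parameters():
            p.grad = None


class Conv2d(Module):
    """Stride-1, shape-preserving 2-D convolution with bias.

    Kaiming fan-in initialisation (gain for ReLU); pass ``rng`` to make
    initial weights reproducible.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 dilation: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w.astype(np.float32), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Adam:
    """Adam with the conventional moment/epsilon defaults."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def bilinear_matrix(n_in: int, n_out: int, dtype=np.float32) -> np.ndarray:
    """(n_out, n_in) bilinear interpolation weights, half-pixel convention."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def adaptive_avg_matrix(n_in: int, n_bins: int, dtype=np.float32) -> np.ndarray:
    """(n_bins, n_in) averaging weights with near-equal contiguous bins."""
    m = np.zeros((n_bins, n_in), dtype=dtype)
    for i in range(n_bins):
        lo = (i * n_in) // n_bins
        hi = -(-((i + 1) * n_in) // n_bins)  # ceil division
        m[i, lo:hi] = 1.0 / (hi - lo)
    return m


def resize_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (N, C, H, W) to (N, C, *size*)."""
    h, w = x.shape[-2:]
    ht, wt = size
    if h != ht:
        x = scale_axis(x, bilinear_matrix(h, ht), axis=2)
    if w != wt:
        x = scale_axis(x, bilinear_matrix(w, wt), axis=3)
    return x


def adaptive_avg_pool(x: Tensor, bins: int) -> Tensor:
    """Adaptive average pooling of (N, C, H, W) down to (bins, bins)."""
    h, w = x.shape[-2:]
    x = scale_axis(x, adaptive_avg_matrix(h, bins), axis=2)
    x = scale_axis(x, adaptive_avg_matrix(w, bins), axis=3)
    return x


def gradient_map_t(x: Tensor) -> Tensor:
    """|forward diff along H| + |forward diff along W| with replicate padding.

    Replicate padding makes the difference at the last row/column zero,
    matching the numpy implementation in ``imaging``.  Input (N, C, H, W).
    """
    from .autodiff import pad2d

    dh = (x[:, :, 1:, :] - x[:, :, :-1, :]).abs()
    dw = (x[:, :, :, 1:] - x[:, :, :, :-1]).abs()
    return pad2d(dh, (0, 1, 0, 0)) + pad2d(dw, (0, 0, 0, 1))
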