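"""Neural building blocks: linear layers, 3D convolution (im2col), small MLPs."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Linear", "Conv3d", "MLP"]


class Linear:
    """Affine layer y = x W + b with He-style seeded init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self):
        return [self.W, self.b]


def _im2col_indices(shape: tuple[int, ...], k: int, stride: int) -> tuple:
    """Flat gather indices turning (N,C,D,H,W) into (N, P, C*k^3) columns."""
    N, C, D, H, W = shape
    Do = (D - k) // stride + 1
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    d0, h0, w0 = np.meshgrid(
        np.arange(Do) * stride, np.arange(Ho) * stride, np.arange(Wo) * stride,
        indexing="ij",
    )
    base = ((d0 * H + h0) * W + w0).reshape(-1)  # (P,)
    base = base[None, :] + (np.arange(N) * C * D * H * W)[:, None]  # (N, P)
    c, kd, kh, kw = np.meshgrid(
        np.arange(C), np.arange(k), np.arange(k), np.arange(k), indexing="ij"
    )
    win = ((c * D + kd) * H + kh) * W + kw  # offsets within one sample
    idx = base[:, :, None] + win.reshape(-1)[None, None, :]
    return idx, (Do, Ho, Wo)


class Conv3d:
    """Valid 3D convolution with cubic kernel, expressed as gather + matmul."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator):
        fan_in = c_in * k**3
        self.W = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.k = k
        self.stride = stride
        self.c_out = c_out
        self._idx_cache: dict[tuple, tuple] = {}

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        key = shape
        if key not in self._idx_cache:
            self._idx_cache[key] = _im2col_indices(shape, self.k, self.stride)
        idx, (Do, Ho, Wo) = self._idx_cache[key]
        cols = x.take_flat(idx)                      # (N, P, C*k^3)
        out = cols @ self.W + self.b                 # (N, P, c_out)
        N = shape[0]
        return out.reshape(N, Do, Ho, Wo, self.c_out).transpose(0, 4, 1, 2, 3)

    @property
    def params(self):
        return [self.W, self.b]


class MLP:
    """Fully connected stack with a configurable activation on hidden layers.

    ``zero_last`` zero-initializes the output layer, which makes an affine
    coupling layer start as the identity map.
    """

    def __init__(self, sizes: list[int], rng: np.random.Generator,
                 activation: str = "relu", zero_last: bool = False):
        self.layers = []
        for i in range(len(sizes) - 1):
            last = i == len(sizes) - 2
            self.layers.append(
                Linear(sizes[i], sizes[i + 1], rng, zero_init=zero_last and last)
            )
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu() if self.activation == "relu" else x.tanh()
        return x

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]
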