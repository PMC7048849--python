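"""Layer modules over the autograd core: parameter containers with
DCGAN-style initialization (weights ~ N(0, 0.02)) and checkpoint support."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: tracks parameters and sub-modules for optimizers and I/O."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                state[key] = v.data
            elif isinstance(v, np.ndarray):
                state[key] = v
            elif isinstance(v, Module):
                state.update(v.state_dict(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor):
                v.data = np.asarray(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_dict(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{key}.{i}.")


def _init_weight(shape, rng: np.random.Generator, init: str, fan_in: int) -> np.ndarray:
    if init == "dcgan":
        return rng.normal(0.0, 0.02, size=shape)
    if init == "he":
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
    if init == "zero":
        return np.zeros(shape)
    raise ValueError(f"unknown init {init!r}")


def bilinear_kernel(cin: int, cout: int, k: int) -> np.ndarray:
    """Bilinear-interpolation kernel for transposed-convolution upsampling
    (identity across channels), the classic fully-convolutional init."""
    f = int(np.ceil(k / 2.0))
    c = (2 * f - 1 - f % 2) / (2.0 * f)
    og = np.ogrid[:k, :k]
    filt = (1 - abs(og[0] / f - c)) * (1 - abs(og[1] / f - c))
    w = np.zeros((cin, cout, k, k))
    for i in range(min(cin, cout)):
        w[i, i] = filt
    return w


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng,
                 init: str = "dcgan"):
        self.stride, self.pad = stride, pad
        self.w = Tensor(_init_weight((cout, cin, k, k), rng, init, cin * k * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, pad: int, rng,
                 init: str = "dcgan"):
        self.stride, self.pad = stride, pad
        if init == "bilinear":
            w = bilinear_kernel(cin, cout, k)
        else:
            w = _init_weight((cin, cout, k, k), rng, init, cin * k * k)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.w, self.b, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, rng, momentum: float = 0.1):
        self.gamma = Tensor(rng.normal(1.0, 0.02, size=c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        return ag.batch_norm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            train, self.momentum,
        )
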