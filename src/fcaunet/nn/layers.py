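"""Layer/module abstractions over the autodiff engine."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import engine as E
from .engine import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
            elif isinstance(v, Module):
                yield from v.parameters()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # flat state dict of parameter + buffer arrays, for checkpointing
    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v.data
            elif isinstance(v, np.ndarray):
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.state_arrays(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{key}.{i}."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.array(state[key], dtype=np.float64)
            elif isinstance(v, np.ndarray):
                v[...] = state[key]
            elif isinstance(v, Module):
                v.load_state_arrays(state, f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: Optional[int] = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad  # default 'same' for stride 1
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return E.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: Optional[int] = None, bias: bool = True):
        super().__init__()
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.weight = Tensor(_he_init(rng, (c, k, k), k * k), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return E.depthwise_conv2d(x, self.weight, self.bias,
                                  stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x: Tensor) -> Tensor:
        return E.batch_norm(x, self.gamma, self.beta,
                            self.running_mean, self.running_var,
                            training=self.training,
                            momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_he_init(rng, (nin, nout), nin), requires_grad=True)
        self.bias = Tensor(np.zeros(nout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return E.add(E.matmul(x, self.weight), self.bias)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return E.dropout(x, self.rate, self.rng, self.training)


class Adam:
    """Adam optimizer with bias-corrected moments."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
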