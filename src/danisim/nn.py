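"""Small neural-network layer zoo and ADAM optimizer on top of autograd.

Layers hold their parameters as :class:`~danisim.autograd.Tensor` objects
with ``requires_grad=True``; ``state_dict``/``load_state_dict`` move raw
numpy arrays in and out for checkpointing.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Dense", "Conv2d", "Conv3d", "Sequential", "Activation",
           "AvgPool2", "Upsample2", "Flatten", "Adam"]


class Module:
    """Base class: parameter discovery by attribute walk, in definition order."""

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data[...] = arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 1.0):
        scale = gain * np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class _ConvNd(Module):
    nd: int

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, gain: float = 1.0):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd (same-padding convolution)")
        fan_in = c_in * kernel ** self.nd
        scale = gain * np.sqrt(2.0 / fan_in)
        shape = (c_out, c_in) + (kernel,) * self.nd
        self.weight = Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv(self.weight, self.bias)


class Conv2d(_ConvNd):
    nd = 2


class Conv3d(_ConvNd):
    nd = 3


class Activation(Module):
    def __init__(self, kind: str):
        if kind not in ("lrelu", "sigmoid", "tanh"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x: Tensor) -> Tensor:
        if self.kind == "lrelu":
            return x.leaky_relu(0.2)
        if self.kind == "sigmoid":
            return x.sigmoid()
        return x.tanh()


class AvgPool2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.avg_pool2()


class Upsample2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.upsample2()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """ADAM with the adversarial-training defaults alpha=2e-4, beta1=0.5."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 10.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                grads = [g * (self.clip_norm / total) for g in grads]
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
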