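"""Minimal neural-network layer and optimizer primitives over :mod:`smartpet.grad`.

Layers hold :class:`Parameter` tensors; :meth:`Module.parameters` recurses
through attributes and lists so optimizers see every weight.  Initialisation
is He-style and fully determined by the ``rng`` handed to each constructor,
which makes whole networks bit-reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np

from .grad import Tensor, conv3d


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match module parameters")
        for p, arr in zip(params, state):
            p.data = np.asarray(arr, dtype=p.data.dtype).reshape(p.data.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    """3D convolution layer, NCDHW, 'same'-style padding by default."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int | tuple = 3, stride: int = 1,
                 padding: int | tuple | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True, gain: float = 2.0):
        rng = rng or np.random.default_rng(0)
        k = kernel if isinstance(kernel, tuple) else (kernel,) * 3
        if padding is None:
            padding = tuple(ki // 2 for ki in k)
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * int(np.prod(k))
        std = math.sqrt(gain / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, *k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """Transposed 3D convolution layer (stride-2 upsampling by default)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, rng: np.random.Generator | None = None,
                 bias: bool = True, gain: float = 2.0):
        rng = rng or np.random.default_rng(0)
        k = (kernel,) * 3
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * int(np.prod(k))
        std = math.sqrt(gain / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_ch, out_ch, *k)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        from .grad import conv_transpose3d
        return conv_transpose3d(x, self.weight, self.bias,
                                stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_f, out_f)))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)) in the overflow-safe split form."""
    return x.relu() + ((-x.abs()).exp() + 1.0).log()


def bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy against a constant 0/1 target."""
    if target == 1:
        return softplus(-logits).mean()
    if target == 0:
        return softplus(logits).mean()
    raise ValueError("target must be 0 or 1")


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
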