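"""Layer modules built on the autodiff ops: convolutions, batch norm,
residual blocks, and the Adam optimizer.

Convolutions immediately followed by batch normalization carry no bias
term — the normalization would cancel it and its gradient is identically
zero.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .autodiff import (
    BatchNormState,
    Parameter,
    Tensor,
    add,
    batch_norm,
    conv1x1,
    conv3x3,
    get_dtype,
    relu,
)


class Module:
    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv3x3(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True):
        std = np.sqrt(2.0 / (c_in * 9))
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, 3, 3)))
        self.bias: Optional[Parameter] = Parameter(np.zeros(c_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return conv3x3(x, self.weight, self.bias)


class Conv1x1(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        stride: int = 1,
        bias: bool = True,
    ):
        std = np.sqrt(2.0 / c_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in)))
        self.bias: Optional[Parameter] = Parameter(np.zeros(c_out)) if bias else None
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv1x1(x, self.weight, self.bias, stride=self.stride)


class BatchNorm(Module):
    def __init__(self, channels: int):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.state = BatchNormState(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.state, training)


class ResidualBlock(Module):
    """Two 3x3 conv + batch-norm + ReLU stages with an identity shortcut.

    When the channel count changes, the shortcut is a 1x1 projection.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv3x3(c_in, c_out, rng, bias=False)
        self.bn1 = BatchNorm(c_out)
        self.conv2 = Conv3x3(c_out, c_out, rng, bias=False)
        self.bn2 = BatchNorm(c_out)
        self.project = Conv1x1(c_in, c_out, rng) if c_in != c_out else None

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = relu(self.bn1(self.conv1(x), training))
        h = self.bn2(self.conv2(h), training)
        shortcut = self.project(x) if self.project is not None else x
        return relu(add(h, shortcut))


class ConvBlock(Module):
    """3x3 conv + batch norm + ReLU (decoder stages)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv = Conv3x3(c_in, c_out, rng, bias=False)
        self.bn = BatchNorm(c_out)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return relu(self.bn(self.conv(x), training))


def batchnorm_states(module: Module) -> List[BatchNormState]:
    """All batch-norm states reachable from a module (for recalibration)."""
    states: List[BatchNormState] = []
    for v in module.__dict__.values():
        if isinstance(v, BatchNorm):
            states.append(v.state)
        elif isinstance(v, Module):
            states.extend(batchnorm_states(v))
    return states


class Adam:
    """Adam optimizer with the usual bias-corrected moment estimates."""

    def __init__(self, params: List[Parameter], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
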