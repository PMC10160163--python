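"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the flow network needs: 3x3 and strided 1x1
convolutions, batch normalization, ReLU, 2x2 max pooling, nearest-neighbour
upsampling, channel concatenation, addition, and the masked end-point-error
loss. Convolutions are lowered to single large matrix products (im2col) so
the heavy lifting stays inside BLAS.

Arrays are ``[N, C, H, W]``. The working precision is module-wide
(:func:`set_dtype`): float32 for training throughput, float64 when verifying
gradients against finite differences.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

_DTYPE = np.float32


def set_dtype(dtype) -> None:
    """Set the working floating-point precision for subsequently created tensors."""
    global _DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be float32 or float64")
    _DTYPE = dtype


def get_dtype():
    return _DTYPE


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "grad_fn", "requires_grad")

    def __init__(
        self,
        data: np.ndarray,
        parents: Tuple["Tensor", ...] = (),
        grad_fn: Optional[Callable[[np.ndarray], Sequence[Optional[np.ndarray]]]] = None,
        requires_grad: bool = False,
    ):
        arr = np.asarray(data, dtype=_DTYPE)
        if arr.ndim and not arr.flags["C_CONTIGUOUS"]:
            arr = np.ascontiguousarray(arr)
        self.data = arr
        self.grad: Optional[np.ndarray] = None
        self.parents = parents
        self.grad_fn = grad_fn
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        order: List[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.grad_fn is None or node.grad is None:
                continue
            parent_grads = node.grad_fn(node.grad)
            for p, g in zip(node.parents, parent_grads):
                if g is None or not p.requires_grad:
                    continue
                if p.grad is None:
                    p.grad = g
                else:
                    p.grad += g


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data: np.ndarray):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def grad_fn(dy):
        return dy, dy

    return Tensor(a.data + b.data, (a, b), grad_fn)


def relu(x: Tensor) -> Tensor:
    pos = x.data > 0

    def grad_fn(dy):
        return (dy * pos,)

    return Tensor(np.where(pos, x.data, 0.0), (x,), grad_fn)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def grad_fn(dy):
        return np.ascontiguousarray(dy[:, :ca]), np.ascontiguousarray(dy[:, ca:])

    return Tensor(np.concatenate([a.data, b.data], axis=1), (a, b), grad_fn)


# ---------------------------------------------------------------------------
# convolutions (im2col; one GEMM per call)
# ---------------------------------------------------------------------------

def _im2col3x3(xp: np.ndarray, H: int, W: int) -> np.ndarray:
    """From padded [N,C,H+2,W+2] to [C*9, N*H*W] column matrix."""
    N, C = xp.shape[0], xp.shape[1]
    cols = np.empty((C, 9, N, H, W), dtype=xp.dtype)
    for i in range(3):
        for j in range(3):
            cols[:, 3 * i + j] = xp[:, :, i : i + H, j : j + W].transpose(1, 0, 2, 3)
    return cols.reshape(C * 9, N * H * W)


def _col2im3x3(dcols: np.ndarray, N: int, C: int, H: int, W: int) -> np.ndarray:
    """Adjoint of :func:`_im2col3x3`: fold [C*9, N*H*W] back into [N,C,H+2,W+2]."""
    d = dcols.reshape(C, 9, N, H, W)
    dxp = np.zeros((N, C, H + 2, W + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + H, j : j + W] += d[:, 3 * i + j].transpose(1, 0, 2, 3)
    return dxp


def conv3x3(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """3x3 convolution, stride 1, zero padding 1. weight [F,C,3,3], bias [F] or None."""
    N, C, H, W = x.data.shape
    F = weight.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = _im2col3x3(xp, H, W)
    w2 = weight.data.reshape(F, C * 9)
    y = (w2 @ cols).reshape(F, N, H, W).transpose(1, 0, 2, 3)
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    def grad_fn(dy):
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(F, N * H * W)
        dw = (dyf @ cols.T).reshape(F, C, 3, 3)
        dcols = w2.T @ dyf
        dx = _col2im3x3(dcols, N, C, H, W)[:, :, 1 : H + 1, 1 : W + 1]
        if bias is None:
            return dx, dw
        return dx, dw, dy.sum(axis=(0, 2, 3))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(y, parents, grad_fn)


def conv1x1(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None, stride: int = 1) -> Tensor:
    """1x1 convolution with optional stride. weight [F,C], bias [F] or None."""
    N, C, H, W = x.data.shape
    F = weight.data.shape[0]
    xs = x.data[:, :, ::stride, ::stride]
    Hs, Ws = xs.shape[2], xs.shape[3]
    xf = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(C, N * Hs * Ws)
    y = (weight.data @ xf).reshape(F, N, Hs, Ws).transpose(1, 0, 2, 3)
    if bias is not None:
        y = y + bias.data[None, :, None, None]

    def grad_fn(dy):
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(F, N * Hs * Ws)
        dw = dyf @ xf.T
        dxs = (weight.data.T @ dyf).reshape(C, N, Hs, Ws).transpose(1, 0, 2, 3)
        if stride == 1:
            dx = dxs
        else:
            dx = np.zeros_like(x.data)
            dx[:, :, ::stride, ::stride] = dxs
        if bias is None:
            return dx, dw
        return dx, dw, dy.sum(axis=(0, 2, 3))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(y, parents, grad_fn)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.data.shape
    xb = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xb = np.ascontiguousarray(xb).reshape(N, C, H // 2, W // 2, 4)
    idx = xb.argmax(axis=4)
    y = np.take_along_axis(xb, idx[..., None], axis=4)[..., 0]

    def grad_fn(dy):
        onehot = idx[..., None] == np.arange(4)
        db = onehot * dy[..., None]
        db = db.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (np.ascontiguousarray(db).reshape(N, C, H, W),)

    return Tensor(y, (x,), grad_fn)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    N, C, H, W = x.data.shape
    y = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def grad_fn(dy):
        d = dy.reshape(N, C, H, factor, W, factor).sum(axis=(3, 5))
        return (d,)

    return Tensor(y, (x,), grad_fn)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

class BatchNormState:
    """Running statistics for inference.

    Besides the exponential update during training, a collection mode allows
    re-estimating the statistics exactly (precise-BN recalibration): batch
    moments are accumulated and averaged, giving inference statistics
    consistent with the final weights.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.collecting = False
        self._acc_mean = np.zeros(channels)
        self._acc_var = np.zeros(channels)
        self._acc_n = 0

    def start_collect(self) -> None:
        self.collecting = True
        self._acc_mean = np.zeros_like(self.running_mean)
        self._acc_var = np.zeros_like(self.running_var)
        self._acc_n = 0

    def finalize_collect(self) -> None:
        if self._acc_n > 0:
            self.running_mean = self._acc_mean / self._acc_n
            self.running_var = self._acc_var / self._acc_n
        self.collecting = False


def batch_norm(
    x: Tensor, gamma: Tensor, beta: Tensor, state: BatchNormState, training: bool
) -> Tensor:
    eps = state.eps
    if training:
        mean = x.data.mean(axis=(0, 2, 3), dtype=np.float64)
        var = x.data.var(axis=(0, 2, 3), dtype=np.float64)
        if state.collecting:
            state._acc_mean += mean
            state._acc_var += var
            state._acc_n += 1
        else:
            state.running_mean = (1 - state.momentum) * state.running_mean + state.momentum * mean
            state.running_var = (1 - state.momentum) * state.running_var + state.momentum * var
    else:
        mean, var = state.running_mean, state.running_var
    istd = (1.0 / np.sqrt(var + eps)).astype(x.data.dtype)
    mean = mean.astype(x.data.dtype)
    xhat = (x.data - mean[None, :, None, None]) * istd[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def grad_fn(dy):
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        dxhat = dy * gamma.data[None, :, None, None]
        if training:
            m_dxhat = dxhat.mean(axis=(0, 2, 3))
            m_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))
            dx = (
                dxhat
                - m_dxhat[None, :, None, None]
                - xhat * m_dxhat_xhat[None, :, None, None]
            ) * istd[None, :, None, None]
        else:
            dx = dxhat * istd[None, :, None, None]
        return dx, dgamma, dbeta

    return Tensor(y, (x, gamma, beta), grad_fn)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def masked_epe(pred: Tensor, gt: np.ndarray, mask: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean end-point error over masked pixels, averaged over the batch.

    ``pred`` is [N,2,H,W]; ``gt`` likewise; ``mask`` is [N,H,W] boolean. The
    small ``eps`` regularizes the square root at exact zero error.
    """
    dtype = pred.data.dtype
    m = mask.astype(dtype)
    gt = np.asarray(gt, dtype=dtype)
    counts = m.sum(axis=(1, 2))
    if np.any(counts == 0):
        raise ValueError("empty mask in masked_epe")
    diff = pred.data - gt
    r = np.sqrt(diff[:, 0] ** 2 + diff[:, 1] ** 2 + dtype.type(eps))
    per_sample = (r * m).sum(axis=(1, 2)) / counts
    N = pred.data.shape[0]
    loss = per_sample.mean()

    def grad_fn(dy):
        scale = dy * m / (counts[:, None, None] * N)
        dr = scale / r
        dpred = np.stack([diff[:, 0] * dr, diff[:, 1] * dr], axis=1)
        return (dpred,)

    return Tensor(np.asarray(loss), (pred,), grad_fn)


def weighted_sum(terms: Sequence[Tensor], weights: Sequence[float]) -> Tensor:
    ws = [float(w) for w in weights]
    value = sum(w * t.data for w, t in zip(ws, terms))

    def grad_fn(dy):
        return [dy * np.asarray(w, dtype=get_dtype()) for w in ws]

    return Tensor(np.asarray(value), tuple(terms), grad_fn)
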