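"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the network needs are implemented: broadcasting
arithmetic, matrix products, sigmoid/tanh/ReLU, reductions (sum, mean,
max), valid 1D/2D convolution via unfold + matmul, spatial zero-padding,
concatenation, reshape, time-step indexing, and numerically stable
MSE / binary-cross-entropy-with-logits losses.

Gradient correctness is enforced by finite-difference checks in the test
suite; every backward rule here is exercised through them.
"""

from __future__ import annotations

import numpy as np

#: Float dtype for all graph arrays.  float32 by default (training is
#: memory-bandwidth bound); finite-difference gradient checks switch to
#: float64 via :func:`set_dtype`.
DTYPE = np.float32


def set_dtype(dtype):
    """Set the global graph dtype (np.float32 or np.float64)."""
    global DTYPE
    DTYPE = np.dtype(dtype).type


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- graph construction helpers -----------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g, b.data.shape)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            if a.requires_grad:
                a.grad += -g

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a.grad += _unbroadcast(g * b.data, a.data.shape)
            if b.requires_grad:
                b.grad += _unbroadcast(g * a.data, b.data.shape)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g, a=self, b=other):
            if a.requires_grad:
                a.grad += g @ b.data.T
            if b.requires_grad:
                b.grad += a.data.T @ g

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- activations ---------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g, a=self, s=s):
            if a.requires_grad:
                a.grad += g * s * (1.0 - s)

        return Tensor._make(s, (self,), bw)

    def tanh(self):
        t = np.tanh(self.data)

        def bw(g, a=self, t=t):
            if a.requires_grad:
                a.grad += g * (1.0 - t * t)

        return Tensor._make(t, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g, a=self, mask=mask):
            if a.requires_grad:
                a.grad += g * mask

        return Tensor._make(self.data * mask, (self,), bw)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g, a=self, old=old):
            if a.requires_grad:
                a.grad += g.reshape(old)

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def _ensure_grad_array(self):
        """Materialise .grad as a writable zero array (for sliced
        accumulation in conv/pad/index backward rules)."""
        if not isinstance(self.grad, np.ndarray):
            self.grad = np.zeros_like(self.data)

    def index_step(self, t: int):
        """Select time-step *t* along axis 1: (B, T, C) -> (B, C)."""

        def bw(g, a=self, t=t):
            if a.requires_grad:
                a._ensure_grad_array()
                a.grad[:, t, :] += g

        return Tensor._make(self.data[:, t, :], (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a.grad += np.broadcast_to(gg, a.data.shape)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )

        def bw(g, a=self, axis=axis, keepdims=keepdims, n=n):
            if not a.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a.grad += np.broadcast_to(gg, a.data.shape) / n

        return Tensor._make(
            self.data.mean(axis=axis, keepdims=keepdims), (self,), bw
        )

    def amax(self, axis, keepdims=False):
        """Max over *axis*; ties share the gradient equally."""
        mx = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == mx).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        out = mx if keepdims else np.squeeze(mx, axis=axis)

        def bw(g, a=self, axis=axis, keepdims=keepdims, mask=mask):
            if not a.requires_grad:
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a.grad += mask * gg

        return Tensor._make(out, (self,), bw)

    # -- autodiff driver ----------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        # grads start as scalar 0.0; the first accumulation `grad += g`
        # then allocates a fresh array (never aliasing g), and ops that
        # accumulate into slices materialise zeros on demand
        for node in topo:
            node.grad = 0.0
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------

def concat(tensors, axis: int) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tuple(tensors), axis=axis, offsets=offsets):
        sl = [slice(None)] * g.ndim
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl[axis] = slice(lo, hi)
                t.grad += g[tuple(sl)]

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1D convolution. x: (B, L, C), w: (F, m, C), b: (F,) -> (B, L-m+1, F).

    Accumulates over kernel offsets (no im2col buffer), which is fast
    for the small kernels used here.
    """
    B, L, C = x.data.shape
    F, m, _ = w.data.shape
    if m > L:
        raise ValueError(f"kernel size {m} exceeds input length {L}")
    Lo = L - m + 1
    y = np.broadcast_to(b.data, (B, Lo, F)).copy()
    for j in range(m):
        y += x.data[:, j : j + Lo, :] @ w.data[:, j, :].T

    def bw(g, x=x, w=w, b=b, Lo=Lo, m=m):
        if w.requires_grad:
            dw = np.stack(
                [np.einsum("blf,blc->fc", g, x.data[:, j : j + Lo, :])
                 for j in range(m)], axis=1)
            w.grad += dw
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 1))
        if x.requires_grad:
            x._ensure_grad_array()
            for j in range(m):
                x.grad[:, j : j + Lo, :] += g @ w.data[:, j, :]

    return Tensor._make(y, (x, w, b), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 2D convolution. x: (B, C, H, W), w: (F, C, K, L), b: (F,).

    Accumulates over kernel offsets with einsum; avoids materialising
    the (B, Ho, Wo, C, K, L) unfolded tensor.
    """
    B, C, H, W = x.data.shape
    F, _, K, L = w.data.shape
    if K > H or L > W:
        raise ValueError(f"kernel {K}x{L} exceeds input {H}x{W}")
    Ho, Wo = H - K + 1, W - L + 1
    y = np.broadcast_to(b.data[:, None, None], (B, F, Ho, Wo)).copy()
    for k in range(K):
        for l in range(L):
            y += np.einsum("bchw,fc->bfhw",
                           x.data[:, :, k : k + Ho, l : l + Wo],
                           w.data[:, :, k, l])

    def bw(g, x=x, w=w, b=b, dims=(K, L, Ho, Wo)):
        K, L, Ho, Wo = dims
        if b.requires_grad:
            b.grad += g.sum(axis=(0, 2, 3))
        if w.requires_grad:
            w._ensure_grad_array()
            for k in range(K):
                for l in range(L):
                    w.grad[:, :, k, l] += np.einsum(
                        "bfhw,bchw->fc", g,
                        x.data[:, :, k : k + Ho, l : l + Wo])
        if x.requires_grad:
            x._ensure_grad_array()
            for k in range(K):
                for l in range(L):
                    x.grad[:, :, k : k + Ho, l : l + Wo] += np.einsum(
                        "bfhw,fc->bchw", g, w.data[:, :, k, l])

    return Tensor._make(y, (x, w, b), bw)


def slice2d(x: Tensor, h: int, w: int) -> Tensor:
    """Crop the last two axes to ``[:h, :w]``."""
    if x.data.shape[-2:] == (h, w):
        return x

    def bw(g, x=x, h=h, w=w):
        if x.requires_grad:
            x._ensure_grad_array()
            x.grad[..., :h, :w] += g

    return Tensor._make(x.data[..., :h, :w], (x,), bw)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; odd trailing rows/cols are cropped."""
    B, C, H, W = x.data.shape
    Hp, Wp = H // 2, W // 2
    t = slice2d(x, 2 * Hp, 2 * Wp)
    t = t.reshape(B, C, Hp, 2, Wp, 2)
    t = t.amax(axis=5)
    return t.amax(axis=3)


def pad2d(x: Tensor, pad: int) -> Tensor:
    """Zero-pad the last two axes of (B, C, H, W) by *pad* on each side."""
    width = [(0, 0)] * (x.data.ndim - 2) + [(pad, pad), (pad, pad)]

    def bw(g, x=x, pad=pad):
        if x.requires_grad:
            x.grad += g[..., pad:-pad, pad:-pad]

    return Tensor._make(np.pad(x.data, width), (x,), bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = pred.data - np.asarray(target, dtype=DTYPE)
    n = diff.size

    def bw(g, pred=pred, diff=diff, n=n):
        if pred.requires_grad:
            pred.grad += g * 2.0 * diff / n

    return Tensor._make(np.mean(diff * diff), (pred,), bw)


def bce_with_logits(logits: Tensor, target: np.ndarray, weight=None) -> Tensor:
    """Weighted binary cross-entropy on logits, numerically stable.

    loss = mean_i w_i * [ max(z,0) - z*t + log(1 + exp(-|z|)) ]
    """
    z = logits.data
    t = np.asarray(target, dtype=DTYPE)
    w = np.ones_like(z) if weight is None else np.asarray(weight, dtype=DTYPE)
    per = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def bw(g, logits=logits, z=z, t=t, w=w, n=n):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits.grad += g * w * (s - t) / n

    return Tensor._make(np.mean(w * per), (logits,), bw)
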