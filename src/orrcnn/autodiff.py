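"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations that produced
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients. Only the primitives required by the encoder and the
classification heads are provided: affine maps, element-wise arithmetic,
sigmoid/tanh/leaky-ReLU, windowed max, mean, concatenation, sequence
reversal, gather, a fused GRU recurrence, and the two losses (softmax
cross-entropy, squared error).

Broadcasting is supported for ``+`` and ``*``; gradients are summed back
over broadcast axes.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping -------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs from long GRU loops get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, Tensor(-1.0)))

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled:
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` back down to ``shape`` after broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Matrix product; ``a`` may be (..., n, k) against a 2-D ``b`` (k, m)."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        ga = np.tensordot(a.data, g, axes=(range(a.data.ndim - 1),) * 2)
        b._accumulate(ga)

    return _make(out_data, (a, b), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    t = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    mask = np.where(a.data > 0, 1.0, slope)

    def backward(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def flip(a, axis: int) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(np.flip(g, axis=axis))

    return _make(np.flip(a.data, axis=axis), (a,), backward)


def index(a, idx) -> Tensor:
    """Gather along the first axis (rows may repeat)."""
    a = as_tensor(a)
    idx = np.asarray(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


def index_axis1(a, idx) -> Tensor:
    """Gather along axis 1 of a 3-D tensor: returns a[:, idx, :]."""
    a = as_tensor(a)
    idx = np.asarray(idx)

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, (slice(None), idx), g)
        a._accumulate(full)

    return _make(a.data[:, idx, :], (a,), backward)


def max_pool_blocks(a, n: int, axis: int = 1) -> Tensor:
    """Per-dimension max over consecutive disjoint blocks of ``n`` along
    ``axis``; a partial final block is pooled over its available entries.
    """
    a = as_tensor(a)
    if n < 1:
        raise ValueError(f"pool width must be >= 1, got {n}")
    L = a.data.shape[axis]
    starts = list(range(0, L, n))
    moved = np.moveaxis(a.data, axis, 0)
    pieces, argmaxes = [], []
    for s in starts:
        block = moved[s : s + n]
        am = block.argmax(axis=0)
        argmaxes.append((s, am))
        pieces.append(np.take_along_axis(block, am[None], axis=0)[0])
    out = np.moveaxis(np.stack(pieces, axis=0), 0, axis)

    def backward(g):
        gm = np.moveaxis(g, axis, 0)
        full = np.zeros_like(moved)
        for i, (s, am) in enumerate(argmaxes):
            np.put_along_axis(full[s : s + n], am[None], gm[i][None], axis=0)
        a._accumulate(np.moveaxis(full, 0, axis))

    return _make(out, (a,), backward)


def mean(a, axis: int | None = None) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.mean(axis=axis)
    count = a.data.size if axis is None else a.data.shape[axis]

    def backward(g):
        if axis is None:
            a._accumulate(np.full_like(a.data, g / count))
        else:
            a._accumulate(np.broadcast_to(np.expand_dims(g, axis) / count, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(a.data.reshape(shape), (a,), backward)


def gru_recurrence(xz, xr, xs, N_z, N_r, N_s, h0: np.ndarray) -> Tensor:
    """Fused GRU recurrence with hand-derived backpropagation through time.

    ``xz``, ``xr``, ``xs`` are the precomputed input projections (B, L, H)
    (input weights and biases already applied); ``N_*`` are the
    hidden-to-hidden matrices. Returns all hidden states (B, L, H). Forward:

        z_t = sigmoid(xz_t + h_{t-1} N_z)
        r_t = sigmoid(xr_t + h_{t-1} N_r)
        c_t = tanh(xs_t + r_t * (h_{t-1} N_s))
        h_t = z_t * c_t + (1 - z_t) * h_{t-1}

    Fusing the time loop into one graph node keeps the per-step work in plain
    NumPy instead of building ~10 graph nodes per position.
    """
    xz, xr, xs = as_tensor(xz), as_tensor(xr), as_tensor(xs)
    N_z, N_r, N_s = as_tensor(N_z), as_tensor(N_r), as_tensor(N_s)
    B, L, H = xz.data.shape
    h = np.broadcast_to(h0, (B, H)).astype(np.float64)
    hs = np.empty((L, B, H))
    zs = np.empty((L, B, H))
    rs = np.empty((L, B, H))
    cs = np.empty((L, B, H))
    hNs = np.empty((L, B, H))
    h_prev = np.empty((L, B, H))
    for t in range(L):
        h_prev[t] = h
        z = 1.0 / (1.0 + np.exp(-(xz.data[:, t] + h @ N_z.data)))
        r = 1.0 / (1.0 + np.exp(-(xr.data[:, t] + h @ N_r.data)))
        hn = h @ N_s.data
        c = np.tanh(xs.data[:, t] + r * hn)
        h = z * c + (1.0 - z) * h
        zs[t], rs[t], cs[t], hNs[t], hs[t] = z, r, c, hn, h

    out_data = np.moveaxis(hs, 0, 1)  # (B, L, H)

    def backward(g):
        dxz = np.empty_like(xz.data)
        dxr = np.empty_like(xr.data)
        dxs = np.empty_like(xs.data)
        dNz = np.zeros_like(N_z.data)
        dNr = np.zeros_like(N_r.data)
        dNs = np.zeros_like(N_s.data)
        carry = np.zeros((B, H))
        for t in range(L - 1, -1, -1):
            dh = g[:, t] + carry
            z, r, c, hn, hp = zs[t], rs[t], cs[t], hNs[t], h_prev[t]
            dz = dh * (c - hp)
            da_z = dz * z * (1.0 - z)
            dc = dh * z
            da_c = dc * (1.0 - c * c)
            dr = da_c * hn
            da_r = dr * r * (1.0 - r)
            dhn = da_c * r
            dxz[:, t] = da_z
            dxr[:, t] = da_r
            dxs[:, t] = da_c
            dNz += hp.T @ da_z
            dNr += hp.T @ da_r
            dNs += hp.T @ dhn
            carry = (
                dh * (1.0 - z)
                + da_z @ N_z.data.T
                + da_r @ N_r.data.T
                + dhn @ N_s.data.T
            )
        xz._accumulate(dxz)
        xr._accumulate(dxr)
        xs._accumulate(dxs)
        N_z._accumulate(dNz)
        N_r._accumulate(dNr)
        N_s._accumulate(dNs)

    return _make(out_data, (xz, xr, xs, N_z, N_r, N_s), backward)


def softmax_cross_entropy(logits, class_index) -> Tensor:
    """Mean cross-entropy of row-softmax probabilities against integer labels.

    ``logits`` is (B, C); ``class_index`` is (B,) with values in 0..C-1.
    Log-sum-exp stabilised.
    """
    logits = as_tensor(logits)
    y = np.asarray(class_index, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    B = z.shape[0]
    loss = -logp[np.arange(B), y].mean()

    def backward(g):
        p = np.exp(logp)
        p[np.arange(B), y] -= 1.0
        logits._accumulate(g * p / B)

    return _make(loss, (logits,), backward)


def squared_error(pred, target) -> Tensor:
    """Mean squared error of a prediction vector against fixed targets."""
    pred = as_tensor(pred)
    t = np.asarray(target, dtype=np.float64)
    diff = pred.data - t

    def backward(g):
        pred._accumulate(g * 2.0 * diff / diff.size)

    return _make(np.mean(diff**2), (pred,), backward)
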