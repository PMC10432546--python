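"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the dual-path separator network needs:
broadcasting arithmetic, (batched) matrix products, element-wise
nonlinearities, fused softmax and layer normalisation, shape manipulation
and reductions. Arrays are float32 throughout; gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward` via a topological sweep.

Batched matrix products route through an explicit loop of BLAS GEMM calls
when the batch is small and each slice is large (numpy's stacked ``matmul``
is an order of magnitude slower there), and through ``einsum`` when the
batch is huge and slices are tiny.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

_DTYPE = np.float32

_NO_GRAD = False


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _NO_GRAD
        self._prev = _NO_GRAD
        _NO_GRAD = True

    def __exit__(self, *exc):
        global _NO_GRAD
        _NO_GRAD = self._prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_owns_grad")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self._owns_grad = False
        if _NO_GRAD:
            requires_grad, _parents = False, ()
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        # First store borrows the array (no copy); a second accumulation
        # allocates, so borrowed arrays are never written into (they may be
        # shared with another tensor's gradient, e.g. through residual adds).
        if self.grad is None:
            self.grad = g if g.dtype == _DTYPE else g.astype(_DTYPE)
            self._owns_grad = False
        elif not self._owns_grad:
            self.grad = self.grad + g
            self._owns_grad = True
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        self._owns_grad = True
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __sub__(self, other: "Tensor") -> "Tensor":
        out_data = self.data - other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(-_unbroadcast(g, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def __mul__(self, other: "Tensor") -> "Tensor":
        out_data = self.data * other.data

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, _parents=(self, other), _backward=bw)

    def scale(self, c: float) -> "Tensor":
        c = float(c)

        def bw(g: np.ndarray) -> None:
            self._accum(g * c)

        return Tensor(self.data * c, _parents=(self,), _backward=bw)

    # -- shape --------------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        orig = self.shape

        def bw(g: np.ndarray) -> None:
            self._accum(g.reshape(orig))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, *axes: int) -> "Tensor":
        inv = np.argsort(axes)

        def bw(g: np.ndarray) -> None:
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor(
            np.ascontiguousarray(self.data.transpose(axes)),
            _parents=(self,),
            _backward=bw,
        )

    def first_rows(self, k: int) -> "Tensor":
        """Rows 0..k-1 along the leading axis."""
        n = self.shape[0]

        def bw(g: np.ndarray) -> None:
            full = np.zeros(self.shape, dtype=_DTYPE)
            full[:k] = g
            self._accum(full)

        if k > n:
            raise ValueError(f"cannot take {k} rows from {n}")
        return Tensor(self.data[:k].copy(), _parents=(self,), _backward=bw)

    # -- nonlinearities -----------------------------------------------------

    def relu(self) -> "Tensor":
        out_data = np.maximum(self.data, 0.0)

        def bw(g: np.ndarray) -> None:
            self._accum(g * (self.data > 0))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def sigmoid(self) -> "Tensor":
        with np.errstate(over="ignore"):  # exp overflow saturates to 0/1
            out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g: np.ndarray) -> None:
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g: np.ndarray) -> None:
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).astype(_DTYPE))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def mean(self) -> "Tensor":
        n = self.data.size
        out_data = self.data.mean(dtype=np.float64)

        def bw(g: np.ndarray) -> None:
            self._accum(np.full(self.shape, float(g) / n, dtype=_DTYPE))

        return Tensor(np.float32(out_data), _parents=(self,), _backward=bw)


# -- free functions ----------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D matrix product ``a @ b``."""
    out_data = a.data @ b.data

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def affine(x: Tensor, W: Tensor, b: Tensor, relu: bool = False) -> Tensor:
    """Fused ``x @ W + b`` over the last axis, with optional ReLU.

    Avoids materialising the pre-bias product and the separate
    activation pass — these run over multi-megabyte activations in the
    feed-forward sublayers.
    """
    shape = x.shape
    x2 = x.data.reshape(-1, shape[-1])
    out = x2 @ W.data
    out += b.data
    if relu:
        np.maximum(out, 0.0, out=out)

    def bw(g: np.ndarray) -> None:
        g2 = np.ascontiguousarray(g).reshape(out.shape)
        if relu:
            g2 = g2 * (out > 0)
        if b.requires_grad:
            b._accum(g2.sum(axis=0))
        if W.requires_grad:
            W._accum(x2.T @ g2)
        if x.requires_grad:
            x._accum((g2 @ W.data.T).reshape(shape))

    return Tensor(
        out.reshape(*shape[:-1], W.shape[-1]), _parents=(x, W, b), _backward=bw
    )


def _bmm_raw(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched (B, n, k) @ (B, k, m) choosing the faster backend."""
    B = a.shape[0]
    if B <= 1024:
        out = np.empty((B, a.shape[1], b.shape[2]), dtype=_DTYPE)
        for i in range(B):
            np.matmul(a[i], b[i], out=out[i])
        return out
    return np.ascontiguousarray(np.einsum("bnk,bkm->bnm", a, b, optimize=True))


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product over the leading axis."""
    out_data = _bmm_raw(a.data, b.data)
    B = a.shape[0]

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            if B <= 1024:
                ga = np.empty_like(a.data)
                for i in range(B):
                    np.matmul(g[i], b.data[i].T, out=ga[i])
            else:
                ga = np.einsum("bnm,bkm->bnk", g, b.data, optimize=True)
            a._accum(ga)
        if b.requires_grad:
            if B <= 1024:
                gb = np.empty_like(b.data)
                for i in range(B):
                    np.matmul(a.data[i].T, g[i], out=gb[i])
            else:
                gb = np.einsum("bnk,bnm->bkm", a.data, g, optimize=True)
            b._accum(gb)

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def bmm_nt(a: Tensor, b: Tensor) -> Tensor:
    """Batched ``a @ b.T`` over the leading axis (no transpose copies)."""
    B, n, k = a.shape
    m = b.shape[1]
    out_data = np.empty((B, n, m), dtype=_DTYPE)
    if B <= 1024:
        for i in range(B):
            np.matmul(a.data[i], b.data[i].T, out=out_data[i])
    else:
        out_data = np.ascontiguousarray(
            np.einsum("bnk,bmk->bnm", a.data, b.data, optimize=True)
        )

    def bw(g: np.ndarray) -> None:
        if a.requires_grad:
            a._accum(_bmm_raw(g, b.data))
        if b.requires_grad:
            if B <= 1024:
                gb = np.empty_like(b.data)
                for i in range(B):
                    np.matmul(g[i].T, a.data[i], out=gb[i])
            else:
                gb = np.einsum("bnm,bnk->bmk", g, a.data, optimize=True)
            b._accum(gb)

    return Tensor(out_data, _parents=(a, b), _backward=bw)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis (fused single-pass kernel)."""
    from . import kernels

    out_data = kernels.softmax_forward(x.data)

    def bw(g: np.ndarray) -> None:
        x._accum(kernels.softmax_backward(out_data, g))

    return Tensor(out_data, _parents=(x,), _backward=bw)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with affine parameters."""
    from . import kernels

    out_data, xhat, inv_std = kernels.layernorm_forward(
        x.data, gamma.data, beta.data, eps
    )

    def bw(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            x._accum(kernels.layernorm_backward_x(xhat, inv_std, gamma.data, g))

    return Tensor(out_data, _parents=(x, gamma, beta), _backward=bw)


def constant(data) -> Tensor:
    """A non-differentiable tensor."""
    return Tensor(data)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    """A differentiable leaf tensor."""
    return Tensor(data, requires_grad=True)


def zero_grads(params: Iterable[Tensor]) -> None:
    for p in params:
        p.grad = None
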