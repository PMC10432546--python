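"""Fused numerical kernels for the hot autodiff operations.

Softmax and layer normalisation are memory-bandwidth bound as sequences
of numpy ufuncs (each pass re-reads multi-megabyte activations); the
numba-compiled versions here fuse them into single passes over each row.
Pure-numpy fallbacks keep the package functional if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit, prange

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco

    prange = range


@njit(cache=False, fastmath=True, parallel=False, error_model="numpy")
def _softmax_fwd(x2: np.ndarray, out: np.ndarray) -> None:
    R, L = x2.shape
    for r in range(R):
        m = x2[r, 0]
        for j in range(1, L):
            if x2[r, j] > m:
                m = x2[r, j]
        s = np.float32(0.0)
        for j in range(L):
            v = np.exp(x2[r, j] - m)
            out[r, j] = v
            s += v
        inv = np.float32(1.0) / s
        for j in range(L):
            out[r, j] *= inv


@njit(cache=False, fastmath=True, parallel=False, error_model="numpy")
def _softmax_bwd(y2: np.ndarray, g2: np.ndarray, out: np.ndarray) -> None:
    R, L = y2.shape
    for r in range(R):
        s = np.float32(0.0)
        for j in range(L):
            s += g2[r, j] * y2[r, j]
        for j in range(L):
            out[r, j] = y2[r, j] * (g2[r, j] - s)


@njit(cache=False, fastmath=True, parallel=False, error_model="numpy")
def _layernorm_fwd(
    x2: np.ndarray,
    gamma: np.ndarray,
    beta: np.ndarray,
    out: np.ndarray,
    xhat: np.ndarray,
    inv_std: np.ndarray,
    eps: np.float32,
) -> None:
    R, L = x2.shape
    for r in range(R):
        mu = np.float32(0.0)
        for j in range(L):
            mu += x2[r, j]
        mu /= L
        var = np.float32(0.0)
        for j in range(L):
            d = x2[r, j] - mu
            var += d * d
        var /= L
        inv = np.float32(1.0) / np.sqrt(var + eps)
        inv_std[r] = inv
        for j in range(L):
            h = (x2[r, j] - mu) * inv
            xhat[r, j] = h
            out[r, j] = h * gamma[j] + beta[j]


@njit(cache=False, fastmath=True, parallel=False, error_model="numpy")
def _layernorm_bwd_x(
    xhat: np.ndarray,
    inv_std: np.ndarray,
    gamma: np.ndarray,
    g2: np.ndarray,
    out: np.ndarray,
) -> None:
    R, L = xhat.shape
    for r in range(R):
        t1 = np.float32(0.0)
        t2 = np.float32(0.0)
        for j in range(L):
            gx = g2[r, j] * gamma[j]
            t1 += gx
            t2 += gx * xhat[r, j]
        t1 /= L
        t2 /= L
        for j in range(L):
            gx = g2[r, j] * gamma[j]
            out[r, j] = inv_std[r] * (gx - t1 - xhat[r, j] * t2)


def softmax_forward(x: np.ndarray) -> np.ndarray:
    if HAVE_NUMBA:
        x = np.ascontiguousarray(x)
        out = np.empty(x.shape, dtype=x.dtype)
        x2 = x.reshape(-1, x.shape[-1])
        _softmax_fwd(x2, out.reshape(x2.shape))
        return out
    out = x - x.max(axis=-1, keepdims=True)
    np.exp(out, out=out)
    out /= out.sum(axis=-1, keepdims=True)
    return out


def softmax_backward(y: np.ndarray, g: np.ndarray) -> np.ndarray:
    if HAVE_NUMBA:
        y = np.ascontiguousarray(y)
        out = np.empty(y.shape, dtype=y.dtype)
        y2 = y.reshape(-1, y.shape[-1])
        _softmax_bwd(
            y2, np.ascontiguousarray(g).reshape(y2.shape), out.reshape(y2.shape)
        )
        return out
    gy = g * y
    s = gy.sum(axis=-1, keepdims=True)
    gy -= y * s
    return gy


def layernorm_forward(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (out, xhat, inv_std); xhat and inv_std feed the backward."""
    if HAVE_NUMBA:
        x = np.ascontiguousarray(x)
        x2 = x.reshape(-1, x.shape[-1])
        out = np.empty(x.shape, dtype=x.dtype)
        xhat = np.empty(x.shape, dtype=x.dtype)
        inv_std = np.empty(x2.shape[0], dtype=np.float32)
        _layernorm_fwd(
            x2, gamma, beta, out.reshape(x2.shape), xhat.reshape(x2.shape),
            inv_std, np.float32(eps),
        )
        return out, xhat, inv_std
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return xhat * gamma + beta, xhat, inv[..., 0].ravel()


def layernorm_backward_x(
    xhat: np.ndarray, inv_std: np.ndarray, gamma: np.ndarray, g: np.ndarray
) -> np.ndarray:
    if HAVE_NUMBA:
        xhat = np.ascontiguousarray(xhat)
        out = np.empty(xhat.shape, dtype=xhat.dtype)
        x2 = xhat.reshape(-1, xhat.shape[-1])
        _layernorm_bwd_x(
            x2, inv_std, gamma,
            np.ascontiguousarray(g).reshape(x2.shape), out.reshape(x2.shape),
        )
        return out
    n = xhat.shape[-1]
    gx = g * gamma
    t1 = gx.sum(axis=-1, keepdims=True)
    t2 = (gx * xhat).sum(axis=-1, keepdims=True)
    inv = inv_std.reshape(xhat.shape[:-1] + (1,))
    return inv * (gx - t1 / n - xhat * t2 / n)


def warmup() -> None:
    """Trigger JIT compilation on tiny inputs (run once at import)."""
    if not HAVE_NUMBA:
        return
    x = np.random.default_rng(0).random((2, 3)).astype(np.float32)
    g = np.ones_like(x)
    softmax_backward(softmax_forward(x), g)
    out, xhat, inv = layernorm_forward(x, np.ones(3, np.float32), np.zeros(3, np.float32), 1e-5)
    layernorm_backward_x(xhat, inv, np.ones(3, np.float32), g)
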