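"""Fused elementwise kernels for the network's activations.

Single-pass numba implementations of ELU/sigmoid and their backward
products keep the training loop from being memory-bandwidth bound; plain
numpy fallbacks preserve identical semantics where numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every model test
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _elu_fwd_np(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, z, z.dtype.type(alpha) * np.expm1(z))


def _sigmoid_fwd_np(z: np.ndarray) -> np.ndarray:
    one = z.dtype.type(1.0)
    return one / (one + np.exp(-z))


def _elu_bwd_np(dx: np.ndarray, z: np.ndarray, a: np.ndarray, alpha: float) -> np.ndarray:
    one = z.dtype.type(1.0)
    return dx * np.where(z > 0, one, a + z.dtype.type(alpha))


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _elu_fwd_nb(z, alpha):  # pragma: no cover - compiled
        out = np.empty_like(z)
        flat_z = z.ravel()
        flat_o = out.ravel()
        for i in range(flat_z.size):
            v = flat_z[i]
            flat_o[i] = v if v > 0 else alpha * (np.exp(v) - 1.0)
        return out

    @njit(cache=True, fastmath=True)
    def _sigmoid_fwd_nb(z):  # pragma: no cover - compiled
        out = np.empty_like(z)
        flat_z = z.ravel()
        flat_o = out.ravel()
        for i in range(flat_z.size):
            flat_o[i] = 1.0 / (1.0 + np.exp(-flat_z[i]))
        return out

    @njit(cache=True, fastmath=True)
    def _elu_bwd_nb(dx, z, a, alpha):  # pragma: no cover - compiled
        out = np.empty_like(dx)
        fdx, fz, fa, fo = dx.ravel(), z.ravel(), a.ravel(), out.ravel()
        for i in range(fdx.size):
            fo[i] = fdx[i] * (1.0 if fz[i] > 0 else fa[i] + alpha)
        return out

    def elu_forward(z: np.ndarray, alpha: float) -> np.ndarray:
        return _elu_fwd_nb(np.ascontiguousarray(z), z.dtype.type(alpha))

    def sigmoid_forward(z: np.ndarray) -> np.ndarray:
        return _sigmoid_fwd_nb(np.ascontiguousarray(z))

    def elu_backward(dx: np.ndarray, z: np.ndarray, a: np.ndarray, alpha: float) -> np.ndarray:
        return _elu_bwd_nb(
            np.ascontiguousarray(dx),
            np.ascontiguousarray(z),
            np.ascontiguousarray(a),
            dx.dtype.type(alpha),
        )

else:  # pragma: no cover
    elu_forward = _elu_fwd_np
    sigmoid_forward = _sigmoid_fwd_np
    elu_backward = _elu_bwd_np
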