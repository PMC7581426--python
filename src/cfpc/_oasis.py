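"""Sparse nonnegative AR(1) deconvolution (pool-adjacent-violators).

Solves, per trace,

    minimize  0.5 * || c - y ||^2   subject to   s_t = c_t - g c_{t-1} >= 0,
    (with s_0 = c_0 >= 0)

by the online pool-adjacent-violators scheme: each frame opens a pool; adjacent
pools are merged while the later pool's fitted start value falls below the decayed
continuation of the earlier pool (which would imply negative spiking activity).
Within a pool the fit is the exponential decay ``v * g**k``.

The unpenalized problem (no L1 term) is used; sparsity is enforced downstream by
the amplitude floor at event detection. The Python inner loop is jit-compiled with
numba when available.
"""

from __future__ import annotations

import numpy as np

__all__ = ["deconvolve_ar1", "ar1_reconvolve"]


def _oasis_core(y, g):  # pragma: no cover - replaced by numba-compiled twin
    n = y.shape[0]
    # pool arrays: value at pool start, weight, start index, length
    v = np.empty(n)
    w = np.empty(n)
    t = np.empty(n, dtype=np.int64)
    l = np.empty(n, dtype=np.int64)
    m = 0  # number of pools
    for i in range(n):
        v[m] = y[i]
        w[m] = 1.0
        t[m] = i
        l[m] = 1
        m += 1
        # merge while the new pool violates s >= 0 against its predecessor
        while m > 1 and v[m - 1] < v[m - 2] * g ** l[m - 2]:
            gl = g ** l[m - 2]
            vnew = (w[m - 2] * v[m - 2] + gl * w[m - 1] * v[m - 1]) / (
                w[m - 2] + gl * gl * w[m - 1]
            )
            w[m - 2] = w[m - 2] + gl * gl * w[m - 1]
            v[m - 2] = vnew
            l[m - 2] = l[m - 2] + l[m - 1]
            m -= 1
    c = np.empty(n)
    for p in range(m):
        vp = v[p]
        if vp < 0.0:
            vp = 0.0
        for k in range(l[p]):
            c[t[p] + k] = vp * g ** k
    return c


try:  # jit-compile when numba is present (it is in the supported environments)
    from numba import njit

    _oasis_core_jit = njit(cache=False)(_oasis_core)
except Exception:  # pragma: no cover
    _oasis_core_jit = _oasis_core


def deconvolve_ar1(y: np.ndarray, g: float) -> tuple[np.ndarray, np.ndarray]:
    """Deconvolve one or many traces under an AR(1) kernel with decay ``g``.

    Parameters
    ----------
    y : ndarray, shape (T,) or (n, T)
        Input trace(s), typically z-scored fluorescence.
    g : float
        Per-frame decay, ``exp(-1 / (fs * tau))``, in (0, 1).

    Returns
    -------
    s : ndarray
        Nonnegative deconvolved activity (same shape as ``y``).
    c : ndarray
        Fitted calcium trace (reconvolution of ``s``).
    """
    if not (0.0 < g < 1.0):
        raise ValueError("AR(1) decay g must lie in (0, 1); check tau and fs")
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[None, :] if single else y
    S = np.empty_like(Y)
    C = np.empty_like(Y)
    for i in range(Y.shape[0]):
        c = _oasis_core_jit(np.ascontiguousarray(Y[i]), float(g))
        s = np.empty_like(c)
        s[0] = c[0]
        s[1:] = c[1:] - g * c[:-1]
        # clip the tiny negative round-off inside pools
        np.maximum(s, 0.0, out=s)
        S[i] = s
        C[i] = c
    if single:
        return S[0], C[0]
    return S, C


def ar1_reconvolve(s: np.ndarray, g: float) -> np.ndarray:
    """Reconvolve activity with the AR(1) kernel: ``c_t = g c_{t-1} + s_t``."""
    from scipy.signal import lfilter

    s = np.asarray(s, dtype=float)
    return lfilter([1.0], [1.0, -g], s, axis=-1)
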