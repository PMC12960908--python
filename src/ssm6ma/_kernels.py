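"""Compiled inner loops (numba) for the selective scan and the Adam update.

The scan is a strictly sequential recurrence over the window length; at
L=41 the per-step overhead of array operations dominates, so the forward
and backward (backprop-through-time) loops are JIT-compiled. Semantics are
identical to the naive recurrence the tests use as an oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["scan_forward", "scan_backward", "adam_update"]


@njit(cache=False, fastmath=True)
def scan_forward(A, Bb, C, G, hs, z):
    """h_t = A_t * h_{t-1} + Bb_t * g_t[f];  z_t[f] = <C_t, h_t>.

    A, Bb, C: (B, L, S); G: (B, L, F); outputs hs: (B, L, F, S), z: (B, L, F).
    """
    Bn, L, S = A.shape
    F = G.shape[2]
    for b in range(Bn):
        for f in range(F):
            acc = 0.0
            for s in range(S):
                h = Bb[b, 0, s] * G[b, 0, f]
                hs[b, 0, f, s] = h
                acc += C[b, 0, s] * h
            z[b, 0, f] = acc
        for t in range(1, L):
            for f in range(F):
                acc = 0.0
                for s in range(S):
                    h = A[b, t, s] * hs[b, t - 1, f, s] \
                        + Bb[b, t, s] * G[b, t, f]
                    hs[b, t, f, s] = h
                    acc += C[b, t, s] * h
                z[b, t, f] = acc


@njit(cache=False, fastmath=True)
def scan_backward(A, Bb, C, G, hs, grad, dA, dBb, dC, dG):
    """Reverse-mode pass of :func:`scan_forward` given dL/dz in ``grad``."""
    Bn, L, S = A.shape
    F = G.shape[2]
    dh = np.zeros((F, S), dtype=A.dtype)
    for b in range(Bn):
        for f in range(F):
            for s in range(S):
                dh[f, s] = 0.0
        for t in range(L - 1, -1, -1):
            for s in range(S):
                accC = 0.0
                for f in range(F):
                    accC += grad[b, t, f] * hs[b, t, f, s]
                dC[b, t, s] = accC
            for f in range(F):
                gv = grad[b, t, f]
                for s in range(S):
                    dh[f, s] += gv * C[b, t, s]
            for s in range(S):
                accA = 0.0
                accB = 0.0
                if t > 0:
                    for f in range(F):
                        accA += dh[f, s] * hs[b, t - 1, f, s]
                        accB += dh[f, s] * G[b, t, f]
                else:
                    for f in range(F):
                        accB += dh[f, s] * G[b, t, f]
                dA[b, t, s] = accA
                dBb[b, t, s] = accB
            for f in range(F):
                accG = 0.0
                for s in range(S):
                    accG += dh[f, s] * Bb[b, t, s]
                    dh[f, s] *= A[b, t, s]
                dG[b, t, f] = accG


@njit(cache=False, fastmath=True)
def adam_update(p, g, m, v, lr, b1, b2, eps, bias1, bias2):
    """In-place Adam step on flattened parameter/state arrays."""
    for i in range(p.size):
        m[i] = b1 * m[i] + (1.0 - b1) * g[i]
        v[i] = b2 * v[i] + (1.0 - b2) * g[i] * g[i]
        p[i] -= lr * (m[i] / bias1) / (np.sqrt(v[i] / bias2) + eps)
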