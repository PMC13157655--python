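"""Numba-compiled inner loops for the recurrent unroll and its adjoint.

The forward kernel mirrors ``ppo.forward_segment`` and the backward kernel
its hand-derived backpropagation-through-time adjoint; both fall back to
pure numpy implementations in :mod:`econrnn.ppo` when numba is absent.
Shapes: B envs, T steps, N neurons, I inputs, A actions.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be installed
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]


@njit(cache=True, fastmath=True)
def fwd_segment(alpha, W, U, b, h0, obs, noise, prev_done):
    B, T, N = noise.shape
    rates = np.empty((B, T, N))
    pos = np.empty((B, T, N), dtype=np.bool_)
    h = h0.copy()
    WT = np.ascontiguousarray(W.T)
    UT = np.ascontiguousarray(U.T)
    for t in range(T):
        for i in range(B):
            if prev_done[i, t]:
                h[i] = 0.0
        drive = h @ WT + obs[:, t] @ UT
        for i in range(B):
            for j in range(N):
                pre = (1.0 - alpha) * h[i, j] + alpha * (
                    drive[i, j] + b[j] + noise[i, t, j])
                p = pre > 0.0
                pos[i, t, j] = p
                h[i, j] = pre if p else 0.0
            rates[i, t] = h[i]
    return rates, pos


@njit(cache=True, fastmath=True)
def bwd_segment(alpha, W, U, A, c, rates, pos, h0, obs, prev_done,
                dlogits, dvalues):
    B, T, N = rates.shape
    nA = A.shape[0]
    I = U.shape[1]
    gW = np.zeros((N, N))
    gU = np.zeros((N, I))
    gb = np.zeros(N)
    carry = np.zeros((B, N))
    dpre = np.empty((B, N))
    for t in range(T - 1, -1, -1):
        # dh = dlogits @ A + dvalues * c + carry, gated by relu mask
        for i in range(B):
            for j in range(N):
                s = carry[i, j] + dvalues[i, t] * c[0, j]
                for k in range(nA):
                    s += dlogits[i, t, k] * A[k, j]
                dpre[i, j] = s if pos[i, t, j] else 0.0
        # parameter grads
        for i in range(B):
            if t > 0:
                hp = rates[i, t - 1]
            else:
                hp = h0[i]
            if prev_done[i, t]:
                for j in range(N):
                    gb[j] += alpha * dpre[i, j]
                    for k in range(I):
                        gU[j, k] += alpha * dpre[i, j] * obs[i, t, k]
            else:
                for j in range(N):
                    d = alpha * dpre[i, j]
                    gb[j] += d
                    for k in range(N):
                        gW[j, k] += d * hp[k]
                    for k in range(I):
                        gU[j, k] += d * obs[i, t, k]
        # carry to previous step
        carry = (1.0 - alpha) * dpre + alpha * (dpre @ W)
        for i in range(B):
            if prev_done[i, t]:
                carry[i] = 0.0
    return gW, gU, gb
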