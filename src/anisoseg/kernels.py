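"""Numba kernels for the selective-scan recurrence.

The recurrence is, per independent sequence g, time step t, channel c and
state index n (all parameters discretized per step by zero-order hold):

    a      = exp(dt[g,t,c] * A[c,n])
    bbar   = (a - 1) / A[c,n] * Bt[g,t,n]        (-> dt * Bt as |dt*A| -> 0)
    h[t]   = a * h[t-1] + bbar * x[g,t,c]
    y[g,t,c] = sum_n Ct[g,t,n] * h[t, c, n]

Two forward variants exist: a rolling-state one for inference and one that
stores the full state trajectory for backpropagation-through-time.  The
backward kernel consumes that trajectory and returns gradients with respect
to x, dt, Bt, Ct and A.  All loops are explicit and sequential in t.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SMALL = 1e-8


@njit(cache=True, fastmath=True)
def selscan_forward(x, dt, Bt, Ct, A):
    """Inference forward pass with a rolling hidden state.

    x, dt: (G, T, C); Bt, Ct: (G, T, N); A: (C, N).  Returns y (G, T, C).
    """
    G, T, C = x.shape
    N = A.shape[1]
    y = np.empty((G, T, C), dtype=x.dtype)
    h = np.zeros((C, N), dtype=x.dtype)
    for g in range(G):
        h[:, :] = 0.0
        for t in range(T):
            for c in range(C):
                d = dt[g, t, c]
                xv = x[g, t, c]
                acc = 0.0
                for n in range(N):
                    da = d * A[c, n]
                    a = np.exp(da)
                    if abs(da) < _SMALL:
                        bb = d * Bt[g, t, n]
                    else:
                        bb = (a - 1.0) / A[c, n] * Bt[g, t, n]
                    hv = a * h[c, n] + bb * xv
                    h[c, n] = hv
                    acc += Ct[g, t, n] * hv
                y[g, t, c] = acc
    return y


@njit(cache=True, fastmath=True)
def selscan_forward_train(x, dt, Bt, Ct, A):
    """Training forward pass; also returns the state trajectory (G,T,C,N)."""
    G, T, C = x.shape
    N = A.shape[1]
    y = np.empty((G, T, C), dtype=x.dtype)
    h = np.zeros((G, T, C, N), dtype=x.dtype)
    for g in range(G):
        for t in range(T):
            for c in range(C):
                d = dt[g, t, c]
                xv = x[g, t, c]
                acc = 0.0
                for n in range(N):
                    da = d * A[c, n]
                    a = np.exp(da)
                    if abs(da) < _SMALL:
                        bb = d * Bt[g, t, n]
                    else:
                        bb = (a - 1.0) / A[c, n] * Bt[g, t, n]
                    hp = h[g, t - 1, c, n] if t > 0 else 0.0
                    hv = a * hp + bb * xv
                    h[g, t, c, n] = hv
                    acc += Ct[g, t, n] * hv
                y[g, t, c] = acc
    return y, h


@njit(cache=True, fastmath=True)
def selscan_backward(x, dt, Bt, Ct, A, h, gy):
    """Backpropagation through time for the selective scan.

    Returns (gx, gdt, gBt, gCt, gA) matching the input shapes.
    """
    G, T, C = x.shape
    N = A.shape[1]
    gx = np.zeros_like(x)
    gdt = np.zeros_like(dt)
    gBt = np.zeros_like(Bt)
    gCt = np.zeros_like(Ct)
    gA = np.zeros_like(A)
    gh = np.zeros((C, N), dtype=x.dtype)
    for g in range(G):
        gh[:, :] = 0.0
        for t in range(T - 1, -1, -1):
            for c in range(C):
                d = dt[g, t, c]
                xv = x[g, t, c]
                gyv = gy[g, t, c]
                gd = 0.0
                gxv = 0.0
                for n in range(N):
                    Av = A[c, n]
                    da = d * Av
                    a = np.exp(da)
                    Bv = Bt[g, t, n]
                    if abs(da) < _SMALL:
                        bb = d * Bv
                        dbb_dA = Bv * d * d * 0.5
                        dbb_dB = d
                    else:
                        bb = (a - 1.0) / Av * Bv
                        dbb_dA = Bv * (d * a / Av - (a - 1.0) / (Av * Av))
                        dbb_dB = (a - 1.0) / Av
                    hv = h[g, t, c, n]
                    hp = h[g, t - 1, c, n] if t > 0 else 0.0
                    # gradient flowing into h[t,c,n]: readout + next step
                    ghv = gh[c, n] + Ct[g, t, n] * gyv
                    gCt[g, t, n] += gyv * hv
                    gA[c, n] += ghv * (hp * d * a + xv * dbb_dA)
                    gd += ghv * (hp * Av * a + xv * a * Bv)
                    gBt[g, t, n] += ghv * dbb_dB * xv
                    gxv += ghv * bb
                    gh[c, n] = ghv * a      # to h[t-1,c,n]
                gdt[g, t, c] = gd
                gx[g, t, c] = gxv
    return gx, gdt, gBt, gCt, gA


@njit(cache=True, fastmath=True)
def lti_scan(x, Abar, Bbar, Cmat):
    """LTI recurrence y_t = C h_t, h_t = Abar h_{t-1} + Bbar x_t.

    x: (G, T, C); Abar, Bbar, Cmat: (C, N).  Returns y (G, T, C).
    """
    G, T, C = x.shape
    N = Abar.shape[1]
    y = np.empty((G, T, C), dtype=x.dtype)
    h = np.zeros((C, N), dtype=x.dtype)
    for g in range(G):
        h[:, :] = 0.0
        for t in range(T):
            for c in range(C):
                acc = 0.0
                xv = x[g, t, c]
                for n in range(N):
                    hv = Abar[c, n] * h[c, n] + Bbar[c, n] * xv
                    h[c, n] = hv
                    acc += Cmat[c, n] * hv
                y[g, t, c] = acc
    return y
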