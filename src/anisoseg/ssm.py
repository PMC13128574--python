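"""Reference implementation of the discretized diagonal state-space model.

A linear time-invariant (LTI) SSM maps a 1D sequence x to y through a hidden
state h of dimension N per channel:

    h'(t) = A h(t) + B x(t),        y(t) = C h(t)

Discretized with a step size delta by zero-order hold (ZOH),

    Abar = exp(delta * A)
    Bbar = (delta A)^{-1} (exp(delta A) - I) * delta B

the recurrence h_t = Abar h_{t-1} + Bbar x_t, y_t = C h_t is exactly
equivalent to a causal convolution with the structured kernel
K = (C Bbar, C Abar Bbar, ..., C Abar^{M-1} Bbar).  The selective variant
re-derives delta, B and C from the input at every step, which breaks time
invariance (and hence the convolutional form) but keeps the same recurrence.

The state matrix A is diagonal throughout, stored as one vector of N real
entries per channel, following standard structured-SSM practice; every
channel is an independent single-input single-output system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import kernels
from .exceptions import (DimensionError, InvalidParameterError, NumericError,
                         UnsupportedModeError)

__all__ = ["SSMParams", "SequenceBatch", "SelectiveProjections", "discretize_zoh",
           "ssm_scan", "kernel_convolve", "selective_scan", "default_ssm_params"]

#: below this |delta * A| the ZOH input map switches to its analytic limit
#: delta * B to avoid catastrophic cancellation in (exp(dA) - 1) / A.
SMALL_ARG_THRESHOLD = 1e-8


@dataclass
class SSMParams:
    """Diagonal SSM parameters, one independent SISO system per channel.

    A, B, C have shape (channels, N); delta is a positive step size with
    shape (channels,) in LTI mode.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    delta: np.ndarray
    N: int = 0

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=np.float64))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=np.float64))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=np.float64))
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=np.float64))
        if not self.N:
            self.N = self.A.shape[1]
        if self.N < 1:
            raise InvalidParameterError("state dimension N must be >= 1")
        if self.A.shape != self.B.shape or self.A.shape != self.C.shape:
            raise DimensionError("A, B, C must share shape (channels, N)")
        if self.delta.shape[0] != self.A.shape[0]:
            raise DimensionError("delta needs one entry per channel")
        if not np.all(self.delta > 0):
            raise InvalidParameterError("delta must be strictly positive")

    @property
    def channels(self) -> int:
        return self.A.shape[0]


@dataclass
class SequenceBatch:
    """A batch of 1D sequences: x and y are (batch, L, channels)."""

    x: np.ndarray
    y: np.ndarray | None = None
    h: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.ndim != 3:
            raise DimensionError("sequence batch must be (batch, L, channels)")
        if self.x.shape[1] < 1:
            raise DimensionError("sequence length must be >= 1")

    @property
    def length(self) -> int:
        return self.x.shape[1]


def default_ssm_params(channels: int, N: int = 16,
                       rng: np.random.Generator | None = None) -> SSMParams:
    """Random stable parameters: A negative, delta log-uniform in [1e-3, 1e-1]."""
    rng = rng or np.random.default_rng(0)
    A = -np.exp(rng.uniform(np.log(0.5), np.log(4.0), size=(channels, N)))
    B = rng.standard_normal((channels, N))
    C = rng.standard_normal((channels, N))
    delta = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), size=channels))
    return SSMParams(A=A, B=B, C=C, delta=delta, N=N)


def discretize_zoh(params: SSMParams) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order-hold discretization of (A, B) with step size delta.

    Returns (Abar, Bbar), each (channels, N).  For a diagonal A the matrix
    expressions reduce elementwise to Abar = exp(dA) and
    Bbar = (exp(dA) - 1) / A * B, with the limit Bbar -> delta * B used when
    |delta * A| falls below ``SMALL_ARG_THRESHOLD``.
    """
    if not np.all(params.delta > 0):
        raise InvalidParameterError("delta must be strictly positive")
    d = params.delta[:, None]
    dA = d * params.A
    Abar = np.exp(dA)
    # expm1 keeps (exp(dA) - 1)/A accurate near zero; the explicit limit
    # delta*B guards the A -> 0 division itself.
    with np.errstate(divide="ignore", invalid="ignore"):
        Bbar = np.where(np.abs(dA) < SMALL_ARG_THRESHOLD,
                        d * params.B,
                        np.expm1(dA) / params.A * params.B)
    return Abar, Bbar


def ssm_scan(params: SSMParams, seq: SequenceBatch) -> SequenceBatch:
    """Left-to-right LTI recurrence from a zero initial state."""
    if seq.x.shape[2] != params.channels:
        raise DimensionError(
            f"sequence has {seq.x.shape[2]} channels, params have {params.channels}")
    Abar, Bbar = discretize_zoh(params)
    y = kernels.lti_scan(np.ascontiguousarray(seq.x),
                         np.ascontiguousarray(Abar),
                         np.ascontiguousarray(Bbar),
                         np.ascontiguousarray(params.C))
    return SequenceBatch(x=seq.x, y=y)


def kernel_convolve(params: SSMParams, seq: SequenceBatch) -> SequenceBatch:
    """Global-convolution form of the LTI SSM.

    Builds K = (C Bbar, C Abar Bbar, ..., C Abar^{M-1} Bbar) per channel and
    returns the causal convolution x * K.  Only valid for time-invariant
    parameters; selective parameters have no convolutional equivalent.
    """
    if seq.x.shape[2] != params.channels:
        raise DimensionError(
            f"sequence has {seq.x.shape[2]} channels, params have {params.channels}")
    if params.delta.ndim != 1:
        raise UnsupportedModeError("kernel_convolve requires time-invariant parameters")
    Abar, Bbar = discretize_zoh(params)
    L = seq.length
    # K[c, l] = sum_n C[c,n] * Abar[c,n]^l * Bbar[c,n]
    # cumulative powers: (C, L, N)
    pows = np.ones((params.channels, L, params.N), dtype=np.float64)
    if L > 1:
        pows[:, 1:, :] = np.cumprod(
            np.broadcast_to(Abar[:, None, :], (params.channels, L - 1, params.N)), axis=1)
    K = np.einsum("cn,cln->cl", params.C * Bbar, pows)
    # causal convolution along the time axis, batched over (batch, channel)
    x = seq.x  # (batch, L, C)
    full = fftconvolve(x, K.T[None, :, :], axes=1)
    y = full[:, :L, :]
    return SequenceBatch(x=seq.x, y=y)


@dataclass
class SelectiveProjections:
    """Per-step parameter maps for the selective scan.

    delta_t = softplus(x_t @ W_delta + b_delta)   (channels -> channels)
    B_t     = x_t @ W_B + b_B                     (channels -> N)
    C_t     = x_t @ W_C + b_C                     (channels -> N)
    A is a fixed (channels, N) matrix shared over time.  The biases b_B and
    b_C default to zero; setting the weight matrices to zero and the biases
    to constants freezes the projections, which reduces the scan to the LTI
    recurrence.
    """

    W_delta: np.ndarray
    b_delta: np.ndarray
    W_B: np.ndarray
    W_C: np.ndarray
    A: np.ndarray
    b_B: np.ndarray | None = None
    b_C: np.ndarray | None = None

    def __post_init__(self):
        for name in ("W_delta", "b_delta", "W_B", "W_C", "A"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        N = self.W_B.shape[1]
        self.b_B = np.zeros(N) if self.b_B is None else np.asarray(self.b_B, dtype=np.float64)
        self.b_C = np.zeros(N) if self.b_C is None else np.asarray(self.b_C, dtype=np.float64)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)


def selective_scan(seq: SequenceBatch, proj: SelectiveProjections) -> SequenceBatch:
    """Input-dependent (selective) scan: ZOH discretization at every step.

    With projections frozen to constants (W_delta = W_B = W_C = 0 plus an
    appropriate bias) this reduces exactly to :func:`ssm_scan`.
    """
    x = seq.x  # (batch, L, C)
    C = x.shape[2]
    if proj.A.shape[0] != C:
        raise DimensionError("A must have one row per channel")
    dt = _softplus(x @ proj.W_delta + proj.b_delta)
    if not np.all(np.isfinite(dt)):
        bad = np.argwhere(~np.isfinite(dt))[0]
        raise NumericError(f"non-finite projected delta at index {tuple(bad)}")
    Bt = x @ proj.W_B + proj.b_B
    Ct = x @ proj.W_C + proj.b_C
    y = kernels.selscan_forward(np.ascontiguousarray(x),
                                np.ascontiguousarray(dt),
                                np.ascontiguousarray(Bt),
                                np.ascontiguousarray(Ct),
                                np.ascontiguousarray(proj.A))
    return SequenceBatch(x=seq.x, y=y)
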