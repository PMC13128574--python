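"""Dice loss, foreground-proportion-weighted BCE, and composite totals.

The composite objective is L = alpha * L_Dice + beta * L_WBCE with

    L_Dice = 1 - (2 * sum(p*t) + eps) / (sum(t) + sum(p) + eps)

and the WBCE a per-voxel-weighted binary cross-entropy normalized by the
patch volume D*H*W.  The per-voxel weight depends on the foreground
proportion W_f of the patch:

    W_f > 0.5:   W_i = G_i + W_f/(1-W_f) * (1 - G_i)
    W_f <= 0.5:  W_i = W_f/(1-W_f) * G_i + (1 - G_i)

so at W_f = 0.5 both branches give uniform unit weights.  W_f is computed
from the ground-truth patch (stationary weights); a switch allows computing
it from the predictions instead.  Single-class patches (W_f in {0, 1}) fall
back to unit weights with a warning.

Two target schemes are supported: ``affinity`` (one composite loss over all
three affinity channels jointly) and ``mask_boundary`` (the sum of a mask
term and a boundary term).

All loss functions accept numpy arrays or autodiff Tensors and return a
scalar Tensor (use ``float(...)`` for the plain value); gradients flow when
the predictions are Tensors in a recorded graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .exceptions import ConfigurationError, DimensionError, NumericError

__all__ = ["LossSpec", "WeightMap", "dice_loss", "wbce_weights", "wbce_loss",
           "composite_loss", "total_loss"]

_CLAMP = 1e-7
SCHEMES = ("affinity", "mask_boundary")
SCHEME_CHANNELS = {"affinity": 3, "mask_boundary": 2}


@dataclass
class LossSpec:
    """Weights and scheme of the composite loss."""

    alpha: float = 1.0
    beta: float = 1.0
    epsilon: float = 1e-6
    scheme: str = "affinity"
    weight_source: str = "targets"   # or "predictions"

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ConfigurationError("alpha and beta must be >= 0 and not both 0")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.scheme not in SCHEMES:
            raise ConfigurationError(f"scheme must be one of {SCHEMES}")
        if self.weight_source not in ("targets", "predictions"):
            raise ConfigurationError("weight_source must be 'targets' or 'predictions'")


@dataclass
class WeightMap:
    """Per-voxel WBCE weights plus the foreground proportion they came from."""

    W_i: np.ndarray
    W_f: float


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _raw(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def dice_loss(p, t, epsilon: float = 1e-6) -> Tensor:
    """Soft Dice loss in [0, 1)."""
    p, t = _wrap(p), _wrap(t)
    if p.shape != t.shape:
        raise DimensionError(f"prediction shape {p.shape} != target shape {t.shape}")
    num = (p * t).sum() * 2.0 + epsilon
    den = t.sum() + p.sum() + epsilon
    return 1.0 - num / den


def wbce_weights(G) -> WeightMap:
    """Foreground-proportion weights for the WBCE term (two-branch form)."""
    G = _raw(G).astype(np.float64)
    wf = float(G.mean())
    if wf in (0.0, 1.0):
        warnings.warn("single-class patch: WBCE weights fall back to all ones",
                      stacklevel=2)
        return WeightMap(W_i=np.ones_like(G), W_f=wf)
    ratio = wf / (1.0 - wf)
    if wf > 0.5:
        W = G + ratio * (1.0 - G)
    else:
        W = ratio * G + (1.0 - G)
    return WeightMap(W_i=W, W_f=wf)


def wbce_loss(Y, G, weights: np.ndarray | WeightMap | None = None,
              weight_source: str = "targets") -> Tensor:
    """Weighted binary cross-entropy, normalized by the voxel count."""
    Yt, Gt = _wrap(Y), _wrap(G)
    if Yt.shape != Gt.shape:
        raise DimensionError(f"prediction shape {Yt.shape} != target shape {Gt.shape}")
    if not np.all(np.isfinite(_raw(Y))):
        raise NumericError("non-finite prediction passed to wbce_loss")
    if weights is None:
        ref = _raw(Y) if weight_source == "predictions" else _raw(G)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            weights = wbce_weights(np.round(ref) if weight_source == "predictions" else ref)
    W = weights.W_i if isinstance(weights, WeightMap) else np.asarray(weights)
    Yc = Yt.clamp(_CLAMP, 1.0 - _CLAMP)
    bce = -(Gt * Yc.log() + (1.0 - Gt) * (1.0 - Yc).log())
    return (bce * W).mean()


def composite_loss(Y, G, spec: LossSpec) -> Tensor:
    """alpha * Dice + beta * WBCE on one prediction/target pair."""
    out = None
    if spec.alpha:
        out = dice_loss(Y, G, spec.epsilon) * spec.alpha
    if spec.beta:
        term = wbce_loss(Y, G, weight_source=spec.weight_source) * spec.beta
        out = term if out is None else out + term
    return out


def total_loss(pred, target, spec: LossSpec) -> Tensor:
    """Scheme-dependent total over the channel axis.

    ``affinity``: one composite loss over the stacked affinity channels.
    ``mask_boundary``: composite(mask) + composite(boundary).
    Inputs are (C, ...) or (B, C, ...) with the channel count fixed by the
    scheme (3 for affinities, 2 for mask+boundary).
    """
    n_ch = SCHEME_CHANNELS[spec.scheme]
    p, t = _wrap(pred), _wrap(target)
    if p.shape != t.shape:
        raise DimensionError(f"prediction shape {p.shape} != target shape {t.shape}")
    if p.ndim == 4:
        ch_axis = 0
    elif p.ndim == 5:
        ch_axis = 1
    else:
        raise DimensionError("expected (C, D, H, W) or (B, C, D, H, W) inputs")
    if p.shape[ch_axis] != n_ch:
        raise ConfigurationError(
            f"scheme {spec.scheme!r} expects {n_ch} channels, got {p.shape[ch_axis]}")
    if spec.scheme == "affinity":
        return composite_loss(p, t, spec)
    sl = (slice(None),) * ch_axis
    mask = composite_loss(p[sl + (0,)], t[sl + (0,)], spec)
    boundary = composite_loss(p[sl + (1,)], t[sl + (1,)], spec)
    return mask + boundary
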