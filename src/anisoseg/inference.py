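"""Sliding-window inference with Gaussian-weighted patch blending.

Large volumes are covered by overlapping patches (default 8x256x256 with a
4x128x128 stride).  Each patch prediction is multiplied by a separable
Gaussian weight (peak 1 at the patch centre) before accumulation, and the
per-voxel weighted sum is normalized by the accumulated weight, which
suppresses patch-boundary artifacts.  Windows clamp to the volume edge; a
volume smaller than one patch is reflect-padded up to patch size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, NumericError

log = logging.getLogger(__name__)

__all__ = ["TilingPlan", "plan_tiling", "gaussian_weight", "blended_predict"]


@dataclass
class TilingPlan:
    """Window corner positions covering a (possibly padded) volume."""

    volume_shape: tuple
    patch: tuple
    stride: tuple
    positions: list
    blend_sigma_fraction: float = 0.125
    pad: tuple = ((0, 0), (0, 0), (0, 0))

    @property
    def padded_shape(self) -> tuple:
        return tuple(s + p[0] + p[1] for s, p in zip(self.volume_shape, self.pad))


def _axis_positions(extent: int, patch: int, stride: int) -> list[int]:
    if extent <= patch:
        return [0]
    pos = list(range(0, extent - patch + 1, stride))
    if pos[-1] != extent - patch:
        pos.append(extent - patch)      # clamp the last window to the edge
    return pos


def plan_tiling(volume_shape, patch, stride,
                blend_sigma_fraction: float = 0.125) -> TilingPlan:
    """Plan complete coverage of `volume_shape` by patch windows.

    Positions are sorted lexicographically.  If the volume is smaller than
    one patch along an axis, the plan records reflective padding for it.
    """
    volume_shape, patch, stride = tuple(volume_shape), tuple(patch), tuple(stride)
    if any(s <= 0 for s in stride):
        raise ConfigurationError("stride entries must be positive")
    if any(s > p for s, p in zip(stride, patch)):
        raise ConfigurationError("stride must not exceed the patch extent")
    pad = tuple((0, max(0, p - v)) for v, p in zip(volume_shape, patch))
    padded = tuple(v + pr[1] for v, pr in zip(volume_shape, pad))
    axes = [_axis_positions(e, p, s) for e, p, s in zip(padded, patch, stride)]
    positions = sorted(itertools.product(*axes))
    return TilingPlan(volume_shape=volume_shape, patch=patch, stride=stride,
                      positions=positions, blend_sigma_fraction=blend_sigma_fraction,
                      pad=pad)


def gaussian_weight(patch_shape, sigma_fraction: float = 0.125) -> np.ndarray:
    """Separable Gaussian blending weights: peak 1 at the patch centre,
    strictly positive everywhere; sigma = extent * sigma_fraction per axis."""
    if sigma_fraction <= 0:
        raise ConfigurationError("sigma_fraction must be positive")
    w = np.ones(tuple(patch_shape), dtype=np.float64)
    for axis, n in enumerate(patch_shape):
        sigma = max(n * sigma_fraction, 1e-6)
        centre = (n - 1) / 2.0
        prof = np.exp(-((np.arange(n) - centre) ** 2) / (2.0 * sigma ** 2))
        shape = [1] * len(patch_shape)
        shape[axis] = n
        w = w * prof.reshape(shape)
    return w


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def blended_predict(model, volume: np.ndarray, plan: TilingPlan,
                    out_channels: int | None = None) -> np.ndarray:
    """Gaussian-blended sliding-window probabilities over a 3D volume.

    `model` maps a (1, 1, D, H, W) patch to logits (1, C, D, H, W); either a
    callable or an object with a ``predict`` method.  Output is
    (C, *volume_shape) with values in [0, 1].
    """
    predict = model.predict if hasattr(model, "predict") else model
    vol = np.asarray(volume, dtype=np.float32)
    if vol.shape != plan.volume_shape:
        raise ConfigurationError(
            f"volume shape {vol.shape} does not match plan {plan.volume_shape}")
    if any(p[1] for p in plan.pad):
        vol = np.pad(vol, plan.pad, mode="reflect")
    weight = gaussian_weight(plan.patch, plan.blend_sigma_fraction)
    shape = vol.shape
    acc: np.ndarray | None = None
    wsum = np.zeros(shape, dtype=np.float64)
    running_min, running_max = np.inf, -np.inf
    for n_done, corner in enumerate(plan.positions, start=1):
        sl = tuple(slice(c, c + p) for c, p in zip(corner, plan.patch))
        logits = np.asarray(predict(vol[sl][None, None]))
        if not np.all(np.isfinite(logits)):
            raise NumericError(f"non-finite logits in window at corner {corner}")
        probs = _sigmoid(logits[0])
        if acc is None:
            C = probs.shape[0] if out_channels is None else out_channels
            acc = np.zeros((C,) + shape, dtype=np.float64)
        acc[(slice(None),) + sl] += weight * probs
        wsum[sl] += weight
        running_min = min(running_min, float(probs.min()))
        running_max = max(running_max, float(probs.max()))
        log.debug("window %d/%d at %s; running prob range [%.4f, %.4f]",
                  n_done, len(plan.positions), corner, running_min, running_max)
    log.info("blended %d windows; probability range [%.4f, %.4f]",
             len(plan.positions), running_min, running_max)
    out = acc / wsum[None]
    crop = tuple(slice(0, s) for s in plan.volume_shape)
    return out[(slice(None),) + crop]
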