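"""Directional scanning orders for 5-axis feature volumes.

A feature volume (B, C, D, H, W) is unfolded into batches of 1D sequences by
a permutation operator, processed by a sequence transform (an SSM in the
network, anything callable in tests), and folded back by the inverse
permutation.  Three composite strategies are built on top:

* 2D expanded scanning — each depth slice independently, along the four
  planar directions {row-forward, row-backward, col-forward, col-backward};
  the four outputs are averaged.
* 3D expanded scanning — the whole volume as one sequence, in a selectable
  axis order (depth-major ``dhw`` or width-major ``whd``).
* bidirectional scanning — forward and backward recursions over the z-major
  (depth-outermost) unfolding, summed: y_t = C(s_t_fwd + s_t_bwd).

Index convention: 0-based, row-major; depth is the anisotropic axis;
"row-forward" advances x within a row, "col-forward" advances y within a
column.  All functions accept either a :class:`FeatureVolume`, a raw numpy
array or an autodiff :class:`~anisoseg.autodiff.Tensor` and return the same
kind, so the network can differentiate through them unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping

import numpy as np

from .autodiff import Tensor
from .exceptions import ConfigurationError, DimensionError
from .ssm import SequenceBatch

__all__ = [
    "FeatureVolume", "PLANAR_DIRECTIONS", "VOLUMETRIC_ORDERS", "Z_DIRECTIONS",
    "unfold", "fold", "unfold_raw", "fold_raw",
    "scan_2d_expanded", "scan_3d_expanded", "scan_bidirectional",
]

PLANAR_DIRECTIONS = ("row-forward", "row-backward", "col-forward", "col-backward")
VOLUMETRIC_ORDERS = ("dhw", "whd")
Z_DIRECTIONS = ("z-forward", "z-backward")
_ALL_DIRECTIONS = PLANAR_DIRECTIONS + VOLUMETRIC_ORDERS + Z_DIRECTIONS

#: arrow aliases matching the planar direction set D_2D = {→, ←, ↓, ↑}
_ALIASES = {"→": "row-forward", "←": "row-backward",
            "↓": "col-forward", "↑": "col-backward"}


@dataclass
class FeatureVolume:
    """A 5-axis feature array (B, C, D, H, W) with physical voxel size.

    ``voxel_size`` is (z, y, x) in nanometres; anisotropic EM volumes have a
    z extent several times coarser than y and x.
    """

    data: np.ndarray
    voxel_size: tuple = (30.0, 6.0, 6.0)

    def __post_init__(self):
        if np.ndim(self.data) != 5:
            raise DimensionError("FeatureVolume data must be 5-axis (B, C, D, H, W)")
        if min(self.data.shape) < 1:
            raise DimensionError("all five extents must be >= 1")
        if len(self.voxel_size) != 3 or min(self.voxel_size) <= 0:
            raise ConfigurationError("voxel_size must be three positive values (z, y, x)")

    @property
    def shape(self):
        return self.data.shape


def canonical_direction(direction: str) -> str:
    direction = _ALIASES.get(direction, direction)
    if direction not in _ALL_DIRECTIONS:
        raise ConfigurationError(
            f"unknown scan direction {direction!r}; valid: {sorted(_ALL_DIRECTIONS)}")
    return direction


@lru_cache(maxsize=256)
def _perm(direction: str, D: int, H: int, W: int) -> np.ndarray:
    """Sequence-position -> source-flat-index permutation for a direction."""
    if direction == "row-forward":
        return np.arange(H * W)
    if direction == "row-backward":
        return np.arange(H * W)[::-1].copy()
    if direction == "col-forward":
        return np.arange(H * W).reshape(H, W).T.ravel().copy()
    if direction == "col-backward":
        return np.arange(H * W).reshape(H, W).T.ravel()[::-1].copy()
    if direction in ("dhw", "z-forward"):
        return np.arange(D * H * W)
    if direction == "z-backward":
        return np.arange(D * H * W)[::-1].copy()
    if direction == "whd":
        return np.arange(D * H * W).reshape(D, H, W).transpose(2, 1, 0).ravel().copy()
    raise ConfigurationError(f"unknown scan direction {direction!r}")


@lru_cache(maxsize=256)
def _inv_perm(direction: str, D: int, H: int, W: int) -> np.ndarray:
    return np.argsort(_perm(direction, D, H, W), kind="stable")


def _is_planar(direction: str) -> bool:
    return direction in PLANAR_DIRECTIONS


def unfold_raw(x, direction: str):
    """Unfold a raw 5-axis array/Tensor into (G, L, C) sequences.

    Planar directions give G = B*D, L = H*W; volumetric and z directions
    give G = B, L = D*H*W.
    """
    direction = canonical_direction(direction)
    B, C, D, H, W = x.shape
    xt = x.transpose(0, 2, 3, 4, 1)                     # (B, D, H, W, C)
    if _is_planar(direction):
        seq = xt.reshape(B * D, H * W, C)
    else:
        seq = xt.reshape(B, D * H * W, C)
    return seq.take(_perm(direction, D, H, W), 1)


def fold_raw(seq, direction: str, shape):
    """Exact inverse of :func:`unfold_raw` for the same direction and shape."""
    direction = canonical_direction(direction)
    B, C, D, H, W = shape
    L = H * W if _is_planar(direction) else D * H * W
    G = B * D if _is_planar(direction) else B
    if tuple(seq.shape) != (G, L, C):
        raise DimensionError(
            f"sequence shape {tuple(seq.shape)} does not match volume shape {tuple(shape)} "
            f"for direction {direction!r}")
    out = seq.take(_inv_perm(direction, D, H, W), 1)
    return out.reshape(B, D, H, W, C).transpose(0, 4, 1, 2, 3)


def unfold(vol: FeatureVolume, direction: str) -> SequenceBatch:
    """Unfold a feature volume into a batch of 1D sequences."""
    return SequenceBatch(x=unfold_raw(vol.data, direction))


def fold(seq: SequenceBatch, direction: str, shape) -> FeatureVolume:
    """Fold sequences (the y channel if present, else x) back to a volume."""
    arr = seq.y if seq.y is not None else seq.x
    return FeatureVolume(data=fold_raw(arr, direction, shape))


def _as_raw(vol):
    if isinstance(vol, FeatureVolume):
        return vol.data, lambda d: FeatureVolume(data=d, voxel_size=vol.voxel_size)
    return vol, lambda d: d


def _direction_transform(ssm, direction: str) -> Callable:
    if isinstance(ssm, Mapping):
        return ssm[direction]
    return ssm


def scan_2d_expanded(vol, ssm):
    """Apply `ssm` along all four planar directions per depth slice; average.

    Every depth slice is an independent sequence batch, so no information
    crosses slices.  `ssm` is a callable (G, L, C) -> (G, L, C), or a mapping
    from direction name to callable for direction-specific parameters.
    """
    x, rewrap = _as_raw(vol)
    shape = x.shape
    acc = None
    for direction in PLANAR_DIRECTIONS:
        seq = unfold_raw(x, direction)
        out = _direction_transform(ssm, direction)(seq)
        folded = fold_raw(out, direction, shape)
        acc = folded if acc is None else acc + folded
    return rewrap(acc * 0.25)


def scan_3d_expanded(vol, ssm, order: str = "dhw"):
    """Apply `ssm` to the whole volume unfolded in a volumetric axis order.

    A voxel's output may depend on voxels in other slices: the sequence spans
    the entire block, giving long-range cross-slice context.
    """
    order = canonical_direction(order)
    if order not in VOLUMETRIC_ORDERS:
        raise ConfigurationError(f"volumetric order must be one of {VOLUMETRIC_ORDERS}")
    x, rewrap = _as_raw(vol)
    seq = unfold_raw(x, order)
    out = _direction_transform(ssm, order)(seq)
    return rewrap(fold_raw(out, order, x.shape))


def scan_bidirectional(vol, ssm_fwd, ssm_bwd):
    """Forward plus backward recursion over the z-major unfolding, summed."""
    x, rewrap = _as_raw(vol)
    shape = x.shape
    fwd = fold_raw(ssm_fwd(unfold_raw(x, "z-forward")), "z-forward", shape)
    bwd = fold_raw(ssm_bwd(unfold_raw(x, "z-backward")), "z-backward", shape)
    return rewrap(fwd + bwd)
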