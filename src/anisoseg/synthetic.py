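"""Synthetic anisotropic EM-like volumes with instance labels.

Two generators emulate the structures the segmentation network is designed
for, at serial-section EM anisotropy (z voxels 5-10x coarser than x-y):

* ``generate_neuron_like`` — neurite-like tubes: per-instance random-walk
  centre lines running through the z-stack, rasterized as in-plane disks
  separated by one-voxel dark "membrane" gaps.
* ``generate_mito_like`` — mitochondria-like ellipsoids, physically
  near-isotropic and therefore squashed along z in voxel space, with sizes
  drawn to populate the small/medium/large AP-75 strata when the volume
  permits.

Both are procedural models, not EM simulations: their job is to provide
learnable structure and nontrivial metric inputs, deterministically per
seed.  Intensities lie in [0, 1].

``augment`` implements the eight training-time transforms (rotation,
scaling, flipping, elastic deformation, missing parts, missing slices,
motion blur, dislocation), applied in the order given.  Geometric transforms
act identically on image and labels (nearest-neighbour for labels);
degradations act on the image only.  In-plane rotation is restricted to 90°
multiples and elastic deformation is in-plane, because the z axis is not
exchangeable with x-y at this anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, GenerationError
from .targets import STRUCT_6, LabelVolume

__all__ = ["SynthSpec", "generate_neuron_like", "generate_mito_like",
           "augment", "AUGMENT_OPS"]

AUGMENT_OPS = ("rotation", "scaling", "flipping", "elastic",
               "missing_parts", "missing_slices", "motion_blur", "dislocation")


@dataclass
class SynthSpec:
    """Parameters of a synthetic volume; the seed fixes all randomness."""

    shape: tuple = (32, 128, 128)
    voxel_size: tuple = (30.0, 6.0, 6.0)
    n_instances: int = 8
    structure: str = "tube"
    noise_sigma: float = 0.03
    texture_scale: float = 8.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ConfigurationError("shape must be three positive extents (D, H, W)")
        vz, vy, vx = self.voxel_size
        if vz < vy or vz < vx:
            raise ConfigurationError(
                "anisotropic emulation requires z voxel size >= y, x voxel sizes")
        if self.structure not in ("tube", "ellipsoid"):
            raise ConfigurationError("structure must be 'tube' or 'ellipsoid'")
        if self.n_instances < 1:
            raise ConfigurationError("n_instances must be >= 1")

    @property
    def anisotropy(self) -> float:
        return self.voxel_size[0] / self.voxel_size[1]


def _keep_largest_component(mask: np.ndarray) -> np.ndarray:
    comp, n = ndimage.label(mask, structure=STRUCT_6)
    if n <= 1:
        return mask
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == sizes.argmax()


def _relabel(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int64)
    remap[ids] = np.arange(1, ids.size + 1)
    return remap[labels]


def _texture(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Smooth in-plane texture field with unit-ish amplitude."""
    raw = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(raw, sigma=(0.5, scale / 2.0, scale / 2.0))
    std = tex.std()
    return tex / std if std > 0 else tex


def _finalize_image(base: np.ndarray, rng: np.random.Generator,
                    spec: SynthSpec) -> np.ndarray:
    img = base + 0.06 * _texture(rng, spec.shape, spec.texture_scale)
    img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_neuron_like(spec: SynthSpec) -> tuple[np.ndarray, LabelVolume]:
    """Neurite-like tube volume: (image, labels)."""
    rng = np.random.default_rng(spec.seed)
    D, H, W = spec.shape
    labels = np.zeros(spec.shape, dtype=np.int64)
    yy, xx = np.mgrid[0:H, 0:W]
    next_id = 1
    for _ in range(spec.n_instances):
        placed = False
        for _attempt in range(20):
            r = rng.uniform(3.0, 5.0)
            if 2 * r + 2 >= min(H, W):
                raise GenerationError("volume too small in-plane for tube radius")
            cy = rng.uniform(r + 1, H - r - 2)
            cx = rng.uniform(r + 1, W - r - 2)
            steps = rng.normal(0.0, 0.7, size=(D, 2)).clip(-0.45 * r, 0.45 * r)
            steps[0] = 0.0
            centres = np.stack([cy, cx]) + np.cumsum(steps, axis=0)
            centres[:, 0] = centres[:, 0].clip(r, H - 1 - r)
            centres[:, 1] = centres[:, 1].clip(r, W - 1 - r)
            candidate = np.zeros(spec.shape, dtype=bool)
            for z in range(D):
                disk = (yy - centres[z, 0]) ** 2 + (xx - centres[z, 1]) ** 2 <= r * r
                forbidden = ndimage.binary_dilation(
                    labels[z] > 0, structure=np.ones((3, 3), dtype=bool))
                candidate[z] = disk & ~forbidden & (labels[z] == 0)
            candidate = _keep_largest_component(candidate)
            z_span = np.flatnonzero(candidate.any(axis=(1, 2)))
            long_enough = (D < 2) or (z_span.size >= 2 and np.any(np.diff(z_span) == 1))
            if candidate.sum() >= 4 and long_enough:
                labels[candidate] = next_id
                next_id += 1
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place tube {next_id} after bounded retries in shape {spec.shape}")
    labels = _relabel(labels)
    membrane = np.zeros(spec.shape, dtype=bool)
    for z in range(D):
        grown = ndimage.binary_dilation(labels[z] > 0, structure=np.ones((3, 3), dtype=bool))
        membrane[z] = grown & (labels[z] == 0)
    base = np.where(labels > 0, 0.72, np.where(membrane, 0.12, 0.55))
    return _finalize_image(base, rng, spec), LabelVolume(labels=labels,
                                                         voxel_size=spec.voxel_size)


def _ellipsoid_radii(target_voxels: float, anisotropy: float,
                     rng: np.random.Generator) -> tuple[float, float, float]:
    """In-plane radii (ry, rx) and z radius for a target voxel count."""
    r = (3.0 * anisotropy * target_voxels / (4.0 * np.pi)) ** (1.0 / 3.0)
    stretch = rng.uniform(0.8, 1.25)
    ry, rx = r * stretch, r / stretch
    rz = max(r / anisotropy, 1.0)
    return ry, rx, rz


def generate_mito_like(spec: SynthSpec) -> tuple[np.ndarray, LabelVolume]:
    """Mitochondria-like ellipsoid volume: (image, labels).

    The size law targets all three AP-75 strata: one instance aims below 5k
    voxels, one above 30k, the rest log-uniform in between — subject to the
    volume being large enough to hold them.
    """
    rng = np.random.default_rng(spec.seed)
    D, H, W = spec.shape
    volume = D * H * W
    targets = []
    if spec.n_instances >= 1:
        targets.append(min(2500.0, 0.05 * volume))
    if spec.n_instances >= 2:
        targets.append(min(45000.0, 0.12 * volume))
    for _ in range(spec.n_instances - 2):
        targets.append(float(np.exp(rng.uniform(np.log(3000.0), np.log(25000.0)))))
        targets[-1] = min(targets[-1], 0.08 * volume)
    labels = np.zeros(spec.shape, dtype=np.int64)
    zz, yy, xx = np.mgrid[0:D, 0:H, 0:W].astype(np.float64)
    next_id = 1
    for target in targets:
        placed = False
        for _attempt in range(60):
            ry, rx, rz = _ellipsoid_radii(target, spec.anisotropy, rng)
            ry = min(ry, (H - 4) / 2.2)
            rx = min(rx, (W - 4) / 2.2)
            rz = min(rz, max((D - 2) / 2.2, 1.0))
            cz = rng.uniform(rz, D - 1 - rz) if D > 2 * rz + 1 else (D - 1) / 2.0
            cy = rng.uniform(ry + 1, H - 2 - ry)
            cx = rng.uniform(rx + 1, W - 2 - rx)
            body = (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                    + ((xx - cx) / rx) ** 2) <= 1.0
            if not body.any():
                continue
            overlap_free = not (ndimage.binary_dilation(
                body, structure=STRUCT_6, iterations=2) & (labels > 0)).any()
            if not overlap_free and _attempt >= 40:
                # crowded volume: carve the candidate around existing bodies
                gap = ndimage.binary_dilation(labels > 0, structure=STRUCT_6,
                                              iterations=2)
                body = _keep_largest_component(body & ~gap)
                overlap_free = body.sum() >= 30
            if overlap_free and body.any():
                labels[body] = next_id
                next_id += 1
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"could not place ellipsoid {next_id} after bounded retries "
                f"in shape {spec.shape}")
    shade = rng.uniform(0.26, 0.38, size=next_id)
    base = np.where(labels > 0, shade[labels.clip(0, next_id - 1)], 0.65)
    return _finalize_image(base, rng, spec), LabelVolume(labels=labels,
                                                         voxel_size=spec.voxel_size)


# -- augmentation ----------------------------------------------------------

def _zoom_to_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """In-plane zoom followed by a centre crop/pad back to the input shape."""
    D, H, W = arr.shape
    out = ndimage.zoom(arr, (1.0, factor, factor), order=order, mode="nearest",
                       grid_mode=True)
    res = np.zeros_like(arr)
    h, w = out.shape[1], out.shape[2]
    sy, sx = max(0, (h - H) // 2), max(0, (w - W) // 2)
    ty, tx = max(0, (H - h) // 2), max(0, (W - w) // 2)
    ch, cw = min(H, h), min(W, w)
    res[:, ty:ty + ch, tx:tx + cw] = out[:, sy:sy + ch, sx:sx + cw]
    return res


def augment(image: np.ndarray, labels: np.ndarray, ops, seed: int = 0
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the requested transforms, in order, deterministically per seed."""
    for op in ops:
        if op not in AUGMENT_OPS:
            raise ConfigurationError(
                f"unknown augmentation {op!r}; valid: {AUGMENT_OPS}")
    img = np.asarray(image).copy()
    lab = np.asarray(labels).copy()
    rng = np.random.default_rng(seed)
    D, H, W = img.shape
    for op in ops:
        if op == "rotation":
            # k clockwise quarter-turns in-plane: (z, y, x) -> (z, x, H-1-y)
            k = int(rng.integers(0, 4))
            img = np.rot90(img, -k, axes=(1, 2)).copy()
            lab = np.rot90(lab, -k, axes=(1, 2)).copy()
        elif op == "scaling":
            f = float(rng.uniform(0.9, 1.1))
            img = _zoom_to_shape(img, f, order=1)
            lab = _zoom_to_shape(lab.astype(np.float64), f, order=0).astype(lab.dtype)
        elif op == "flipping":
            axis = int(rng.integers(0, 3))
            img = np.flip(img, axis=axis).copy()
            lab = np.flip(lab, axis=axis).copy()
        elif op == "elastic":
            sigma, alpha = 8.0, 5.0
            dy = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma) * alpha
            dx = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma) * alpha
            yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
            coords = np.stack([yy + dy, xx + dx])
            for z in range(D):
                img[z] = ndimage.map_coordinates(img[z], coords, order=1, mode="reflect")
                lab[z] = ndimage.map_coordinates(lab[z], coords, order=0, mode="reflect")
        elif op == "missing_parts":
            k = int(rng.integers(1, max(2, D // 4) + 1))
            for z in rng.choice(D, size=min(k, D), replace=False):
                rh = int(rng.integers(H // 8 + 1, max(H // 3, H // 8 + 2)))
                rw = int(rng.integers(W // 8 + 1, max(W // 3, W // 8 + 2)))
                y0 = int(rng.integers(0, H - rh + 1))
                x0 = int(rng.integers(0, W - rw + 1))
                img[z, y0:y0 + rh, x0:x0 + rw] = 0.0
        elif op == "missing_slices":
            k = int(rng.integers(1, max(1, D // 8) + 1))
            for z in rng.choice(D, size=min(k, D), replace=False):
                img[z] = 0.0
        elif op == "motion_blur":
            length = int(rng.integers(2, 5)) * 2 + 1
            horizontal = bool(rng.integers(0, 2))
            kern = np.full((1, length) if horizontal else (length, 1), 1.0 / length)
            for z in range(D):
                img[z] = ndimage.convolve(img[z], kern, mode="reflect")
        elif op == "dislocation":
            z = int(rng.integers(0, D))
            dy = int(rng.integers(-4, 5))
            dx = int(rng.integers(-4, 5))
            img[z] = np.roll(np.roll(img[z], dy, axis=0), dx, axis=1)
    return img, lab
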