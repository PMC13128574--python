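"""U-shaped segmentation network with state-space adaptation modules.

Encoder: stem convolution, three SSM-based anisotropic adaptation (SAA)
modules, three strided-convolution downsamples with the stride schedule
[1,2,2], [1,2,2], [1,1,1] (the third stage keeps resolution — implemented
exactly as configured, and flagged in the log).  Bottleneck: a [2,2,2]
downsample, two SSM-based isotropic adaptation (SIA) modules, trilinear
upsampling back, and an isotropic convolution (IC) module, residually fused
with the deepest skip.  Decoder: three trilinear upsamples, each followed by
skip concatenation and an anisotropic convolution (AC) module, then a 1x1x1
head convolution.

Two head modes are supported: ``affinity`` (3 sigmoid channels, nearest-
neighbour z/y/x affinities) and ``mask_boundary`` (2 sigmoid channels,
semantic mask + instance boundary).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml

from .autodiff import Tensor, concat, no_grad
from .blocks import (Conv3dLayer, ConvUnit, Downsample, Module, ResidualBlock,
                     SAAModule, SIAModule, Upsample)
from .exceptions import ConfigurationError, DimensionError, NumericError
from .losses import LossSpec, total_loss

log = logging.getLogger(__name__)

__all__ = ["NetworkConfig", "SegmentationNetwork", "build", "count_parameters",
           "AdamW", "train_step", "save_checkpoint", "load_checkpoint"]

DEFAULT_STRIDES = ((1, 2, 2), (1, 2, 2), (1, 1, 1), (2, 2, 2))
HEAD_CHANNELS = {"affinity": 3, "mask_boundary": 2}


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters (Table-style stride schedule included)."""

    in_channels: int = 1
    head: str = "affinity"
    out_channels: int = 0                   # 0 -> derived from head
    stage_widths: tuple = (12, 24, 48, 64)
    ds_strides: tuple = DEFAULT_STRIDES
    patch_size: tuple = (8, 256, 256)
    ssm_state_dim: int = 8
    expand: int = 2
    attention_reduction: int = 4
    use_ssm: bool = True                    # False -> pure-convolution ablation baseline

    def __post_init__(self):
        if self.head not in HEAD_CHANNELS:
            raise ConfigurationError(f"head must be one of {sorted(HEAD_CHANNELS)}")
        if not self.out_channels:
            self.out_channels = HEAD_CHANNELS[self.head]
        self.stage_widths = tuple(int(w) for w in self.stage_widths)
        self.ds_strides = tuple(tuple(int(s) for s in st) for st in self.ds_strides)
        self.patch_size = tuple(int(p) for p in self.patch_size)
        if len(self.stage_widths) != 4 or len(self.ds_strides) != 4:
            raise ConfigurationError("stage_widths and ds_strides must both have 4 entries")
        if any(w < 1 for w in self.stage_widths):
            raise ConfigurationError("stage widths must be positive")
        if int(np.prod(self.patch_size)) < 1:
            raise ConfigurationError("patch size must be positive")
        self.validate_patch(self.patch_size)

    @property
    def divisors(self) -> tuple:
        """Required divisibility of (D, H, W), from the stride schedule."""
        div = [1, 1, 1]
        for st in self.ds_strides:
            for a in range(3):
                div[a] *= st[a]
        return tuple(div)

    def validate_patch(self, spatial) -> None:
        for ax, (e, d) in enumerate(zip(spatial, self.divisors)):
            if e % d:
                raise ConfigurationError(
                    f"patch axis {ax} extent {e} not divisible by stride product {d}")

    def to_dict(self) -> dict:
        return {"in_channels": self.in_channels, "head": self.head,
                "out_channels": self.out_channels,
                "stage_widths": list(self.stage_widths),
                "ds_strides": [list(s) for s in self.ds_strides],
                "patch_size": list(self.patch_size),
                "ssm_state_dim": self.ssm_state_dim, "expand": self.expand,
                "attention_reduction": self.attention_reduction,
                "use_ssm": self.use_ssm}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


class SegmentationNetwork(Module):
    """Assembled encoder / bottleneck / decoder; see module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = config.stage_widths
        st = config.ds_strides
        kw = dict(state_dim=config.ssm_state_dim, expand=config.expand,
                  attention_reduction=config.attention_reduction,
                  use_ssm=config.use_ssm)
        self.stem = ConvUnit(config.in_channels, w0, (1, 3, 3), rng=rng)
        self.saa1 = SAAModule(w0, rng=rng, **kw)
        self.ds1 = Downsample(w0, w1, st[0], rng=rng)
        self.saa2 = SAAModule(w1, rng=rng, **kw)
        self.ds2 = Downsample(w1, w2, st[1], rng=rng)
        self.saa3 = SAAModule(w2, rng=rng, **kw)
        self.ds3 = Downsample(w2, w3, st[2], rng=rng)
        if st[2] == (1, 1, 1):
            log.info("third encoder downsample has stride [1,1,1]: "
                     "stage keeps resolution, channels map %d -> %d", w2, w3)
        self.bott_ds = Downsample(w3, w3, st[3], rng=rng)
        self.sia1 = SIAModule(w3, rng=rng, **kw)
        self.sia2 = SIAModule(w3, rng=rng, **kw)
        self.bott_up = Upsample(w3, w3, rng=rng)
        self.ic_conv = ConvUnit(w3, w3, (3, 3, 3), rng=rng)
        self.ic_res = ResidualBlock(w3, (3, 3, 3), rng=rng)
        self.up3 = Upsample(w3, w2, rng=rng)
        self.ac3_conv = ConvUnit(2 * w2, w2, (1, 3, 3), rng=rng)
        self.ac3_res = ResidualBlock(w2, (1, 3, 3), rng=rng)
        self.up2 = Upsample(w2, w1, rng=rng)
        self.ac2_conv = ConvUnit(2 * w1, w1, (1, 3, 3), rng=rng)
        self.ac2_res = ResidualBlock(w1, (1, 3, 3), rng=rng)
        self.up1 = Upsample(w1, w0, rng=rng)
        self.ac1_conv = ConvUnit(2 * w0, w0, (1, 3, 3), rng=rng)
        self.ac1_res = ResidualBlock(w0, (1, 3, 3), rng=rng)
        self.head = Conv3dLayer(w0, config.out_channels, (1, 1, 1), rng=rng)

    # -- forward ----------------------------------------------------------
    def _check_input(self, x) -> None:
        if x.ndim != 5:
            raise DimensionError("input patch must be (B, C, D, H, W)")
        if x.shape[1] != self.config.in_channels:
            raise DimensionError(
                f"expected {self.config.in_channels} input channels, got {x.shape[1]}")
        self.config.validate_patch(x.shape[2:])

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        self._check_input(x)
        s1 = self.saa1(self.stem(x))
        s2 = self.saa2(self.ds1(s1))
        s3 = self.saa3(self.ds2(s2))
        s4 = self.ds3(s3)
        self.last_skip_shapes = [t.shape[2:] for t in (s1, s2, s3, s4)]
        b = self.bott_ds(s4)
        b = self.sia2(self.sia1(b))
        b = self.ic_res(self.ic_conv(self.bott_up(b, s4.shape[2:])))
        b = b + s4
        d3 = self.ac3_res(self.ac3_conv(concat([self.up3(b, s3.shape[2:]), s3], axis=1)))
        d2 = self.ac2_res(self.ac2_conv(concat([self.up2(d3, s2.shape[2:]), s2], axis=1)))
        d1 = self.ac1_res(self.ac1_conv(concat([self.up1(d2, s1.shape[2:]), s1], axis=1)))
        return self.head(d1)

    def skip_shapes(self, patch_spatial) -> list[tuple]:
        """Spatial extents of the four encoder skip tensors for a patch."""
        shapes = []
        cur = tuple(patch_spatial)
        for i, stride in enumerate(self.config.ds_strides[:3]):
            shapes.append(cur)
            cur = tuple(-(-e // s) for e, s in zip(cur, stride))
        shapes.append(cur)
        return shapes

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """Inference forward pass; returns logits as a numpy array."""
        with no_grad():
            return self(np.asarray(patch, dtype=np.float32)).data


def build(config: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    """Build the network with deterministic parameter initialization."""
    model = SegmentationNetwork(config, seed=seed)
    log.info("built network: %d trainable parameters", model.n_parameters())
    return model


def count_parameters(model: Module) -> int:
    """Total trainable scalar count; per-stage breakdown goes to the log."""
    per_stage: dict[str, int] = {}
    seen: set[int] = set()
    for name, p in model.named_parameters():
        if id(p) in seen:
            continue
        seen.add(id(p))
        stage = name.split(".")[0]
        per_stage[stage] = per_stage.get(stage, 0) + int(p.data.size)
    for stage, n in sorted(per_stage.items()):
        log.info("parameters[%s] = %d", stage, n)
    return int(sum(per_stage.values()))


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.data.dtype)


def train_step(model: SegmentationNetwork, patch: np.ndarray, target: np.ndarray,
               loss_spec: LossSpec, optimizer: AdamW) -> float:
    """One gradient step on one patch; returns the scalar loss value."""
    model.zero_grad()
    logits = model(patch)
    probs = logits.sigmoid()
    loss = total_loss(probs, np.asarray(target, dtype=np.float32), loss_spec)
    value = float(loss)
    if not np.isfinite(value):
        raise NumericError(f"non-finite training loss ({value}) at step {optimizer.t + 1}")
    loss.backward()
    if optimizer.lr != 0.0:
        optimizer.step()
    return value


def save_checkpoint(model: SegmentationNetwork, path: str) -> None:
    """Single-file archive of named parameter arrays plus the YAML config."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    arrays["__config__"] = np.array(yaml.safe_dump(model.config.to_dict()))
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> SegmentationNetwork:
    with np.load(path, allow_pickle=False) as npz:
        config = NetworkConfig.from_dict(yaml.safe_load(str(npz["__config__"][()])))
        model = SegmentationNetwork(config, seed=0)
        for name, p in model.named_parameters():
            if name in npz.files:
                p.data = npz[name].copy()
    return model
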