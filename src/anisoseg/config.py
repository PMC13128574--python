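"""Run configuration: YAML-serializable settings for every pipeline stage.

One root seed fans out deterministically to parameter initialization, data
generation, augmentation and window ordering; two runs with identical
configs and seeds produce identical outputs in single-threaded mode.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .exceptions import ConfigurationError
from .losses import LossSpec
from .network import NetworkConfig

__all__ = ["RunConfig", "load_config", "child_seed"]


@dataclass
class PostprocessConfig:
    method: str = "watershed"          # watershed | affinity-agglomerate | none
    seed_threshold: float = 0.9
    mask_threshold: float = 0.8
    min_size: int = 128
    merge_threshold: float = 0.5

    def __post_init__(self):
        if self.method not in ("watershed", "affinity-agglomerate", "none"):
            raise ConfigurationError(f"unknown post-processing method {self.method!r}")


@dataclass
class TilingConfig:
    patch: tuple = (8, 256, 256)
    stride: tuple = (4, 128, 128)
    blend_sigma_fraction: float = 0.125

    def __post_init__(self):
        self.patch = tuple(int(p) for p in self.patch)
        self.stride = tuple(int(s) for s in self.stride)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 0.0
    iters: int = 200


@dataclass
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss: LossSpec = field(default_factory=LossSpec)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict:
        d = {"network": self.network.to_dict(), "loss": asdict(self.loss),
             "tiling": asdict(self.tiling), "postprocess": asdict(self.postprocess),
             "train": asdict(self.train), "seed": self.seed,
             "output_dir": self.output_dir}
        d["train"]["betas"] = list(self.train.betas)
        d["tiling"]["patch"] = list(self.tiling.patch)
        d["tiling"]["stride"] = list(self.tiling.stride)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        return cls(
            network=NetworkConfig.from_dict(d.get("network", {})),
            loss=LossSpec(**d.get("loss", {})),
            tiling=TilingConfig(**d.get("tiling", {})),
            postprocess=PostprocessConfig(**d.get("postprocess", {})),
            train=TrainConfig(**{**d.get("train", {}),
                                 "betas": tuple(d.get("train", {}).get("betas", (0.9, 0.999)))}),
            seed=int(d.get("seed", 0)),
            output_dir=d.get("output_dir", "runs"),
        )

    def save(self, path: str) -> None:
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)


def load_config(path: str) -> RunConfig:
    with open(path) as f:
        return RunConfig.from_dict(yaml.safe_load(f))


def child_seed(root_seed: int, stream: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2**31)."""
    h = 2166136261
    for ch in f"{root_seed}:{stream}".encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h % (2 ** 31 - 1)
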