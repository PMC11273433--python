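"""Pipeline configuration: nested dataclasses, YAML round-trip, seed fan-out.

Defaults follow the reference operating point of the pipeline: 226x226
grayscale input, GAN balancing with Adamax (lr 0.001, batch 12, 100
epochs), 100-region SLIC graphs, a six-layer Chebyshev GCN trained with
SGD (lr 1e-4, batch 32, dropout 0.2, weight decay 4e-4, cross-entropy,
150 epochs) and a 70/20/10 stratified split with 5-fold cross-validation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .chebnet import ModelConfig
from .gan import GanConfig
from .simulate import SimParams


@dataclass
class SegmentationConfig:
    n_regions: int = 100
    compactness: float = 1.0
    gaussian_sigma: float | None = None  # None = binary adjacency


@dataclass
class EvalConfig:
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    kfold: int = 5
    snr_list: list[float] = field(default_factory=list)  # empty = no sweep
    positive_class: str = "ALL"


@dataclass
class DataConfig:
    manifest: str | None = None  # path,label CSV; None = simulate
    n_per_class: int = 100
    separation: float = 1.0


@dataclass
class AugmentConfig:
    enabled: bool = False
    target_per_class: int = 250
    #: augment the training portion only (avoids leakage); set False to
    #: balance before splitting
    train_only: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    side: int = 226
    out_dir: str = "run"
    data: DataConfig = field(default_factory=DataConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["eval"]["fractions"] = list(d["eval"]["fractions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "data" in d:
            d["data"] = DataConfig(**d["data"])
        if "augment" in d:
            d["augment"] = AugmentConfig(**d["augment"])
        if "gan" in d:
            d["gan"] = GanConfig(**d["gan"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        if "eval" in d:
            e = dict(d["eval"])
            if "fractions" in e:
                e["fractions"] = tuple(e["fractions"])
            d["eval"] = EvalConfig(**e)
        return cls(**d)

    def save(self, path: str | Path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministically fan the global seed out to one stage (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def simparams_for(config: PipelineConfig) -> SimParams:
    return SimParams(
        side=config.side,
        separation=config.data.separation,
        seed=stage_seed(config.seed, "simulate"),
    )
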