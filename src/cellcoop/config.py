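"""Nested pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "PreprocessConfig",
    "CellGraphConfig",
    "WalkSection",
    "ModelSection",
    "TrainSection",
    "PipelineConfig",
]


def _from_mapping(cls, data: dict):
    if data is None:
        return cls()
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PreprocessConfig:
    upper_mult: float = 3.0
    lower_mult: float = 1.0
    qc_on: str = "total"
    n_top: int = 500
    n_bins: int = 20


@dataclass
class CellGraphConfig:
    k: int = 15


@dataclass
class WalkSection:
    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    window: int = 10
    dim: int = 128
    negative_samples: int = 5
    epochs: int = 1
    lr: float = 0.025
    min_confidence: float = 0.4
    case_fold: bool = False


@dataclass
class ModelSection:
    hidden: int = 512
    d_m: int = 256
    slope: float = 0.2


@dataclass
class TrainSection:
    total_epochs: int = 500
    lr: float = 1e-5
    lam: float = 100.0
    warmup_epochs: int = 100
    p_update_interval: int = 1
    k: int = 0  # 0 -> take from ground-truth labels


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cell_graph: CellGraphConfig = field(default_factory=CellGraphConfig)
    walk: WalkSection = field(default_factory=WalkSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    seed: int = 0
    use_gene_branch: bool = True
    use_clustering_loss: bool = True

    @classmethod
    def from_dict(cls, data: dict | None) -> "PipelineConfig":
        if not data:
            return cls()
        data = dict(data)
        sections = {
            "preprocess": PreprocessConfig,
            "cell_graph": CellGraphConfig,
            "walk": WalkSection,
            "model": ModelSection,
            "train": TrainSection,
        }
        kwargs = {}
        for key, section_cls in sections.items():
            if key in data:
                kwargs[key] = _from_mapping(section_cls, data.pop(key))
        allowed = {"seed", "use_gene_branch", "use_clustering_loss"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def desk_profile(cls, seed: int = 0, **overrides) -> "PipelineConfig":
        """Small-fixture profile: shallow widths, short schedule, small walks."""
        cfg = cls(
            preprocess=PreprocessConfig(n_top=500),
            cell_graph=CellGraphConfig(k=15),
            walk=WalkSection(walk_length=20, walks_per_node=5, window=5, dim=32),
            model=ModelSection(hidden=64, d_m=32),
            train=TrainSection(total_epochs=200, lr=1e-3, warmup_epochs=50),
            seed=seed,
        )
        for key, val in overrides.items():
            setattr(cfg, key, val)
        return cfg
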