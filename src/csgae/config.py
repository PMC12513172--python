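"""Run configuration: one serializable object covering every pipeline stage."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .model import ModelConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, round-trippable through YAML.

    Defaults follow the method's stated settings where it states one:
    ``n_hvg`` 3000, Leiden resolution 1.0, fusion weights 0.5/0.5, loss
    weights 0.1/0.1/1.0.
    """

    # io
    input_path: Optional[str] = None
    input_format: str = "mtx-dir"
    outdir: str = "csgae_run"
    simulate: Optional[dict] = None  # TissueSimSpec fields, if simulating
    # preprocessing
    target_sum: float = 1e4
    n_hvg: int = 3000
    # graphs
    metric: str = "euclidean"
    knn_radius_k: int = 6
    knn_img_k: int = 6
    ws: float = 0.5
    wh: float = 0.5
    # communities
    resolution: float = 1.0
    pca_dims: int = 50
    knn: int = 15
    # model (nested)
    model: ModelConfig = field(default_factory=ModelConfig)
    # clustering
    cluster_method: str = "gmm"
    cluster_param: float = 4
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.model, dict):
            self.model = ModelConfig(**self.model)
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")
        self.model.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def save(self, path: "str | Path") -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: "str | Path") -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
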