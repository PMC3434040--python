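"""Pipeline configuration: the printed defaults in one place.

radius 16, stride 16, codebook of 2000 visual words, sparsity weight
λ = 0.01, 3x6 spatial grid, linear SVM with C = 1, 30 random 1:1 partitions
and top-8 retrieval.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    radius: int = 16
    stride: int = 16
    codebook_size: int = 2000
    codebook_fraction: float = 0.15
    lam: float = 0.01
    grid: tuple[int, int] = (3, 6)
    classifier: str = "linear_svm"
    reg: float = 1.0
    n_partitions: int = 30
    retrieval_k: int = 8
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        d["grid"] = list(d["grid"])
        return json.dumps(d, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["grid"] = tuple(d["grid"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
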