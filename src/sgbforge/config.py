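"""Pipeline configuration: every workflow threshold in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    k: int = 21
    sketch_size: int = 10_000
    precluster_cutoff: float = 0.05
    candidate_cutoff: float = 0.10
    ani_cutoff: float = 95.0
    coverage_cutoff: float = 0.3
    fragment_length: int = 1020
    min_contig: int = 1500
    high_completeness: float = 90.0
    high_contamination: float = 5.0
    medium_completeness: float = 50.0
    medium_contamination: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be a positive odd integer")
        if self.sketch_size < 1:
            raise ValueError("sketch_size must be positive")
        for name in ("precluster_cutoff", "candidate_cutoff", "coverage_cutoff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} out of [0,1]: {v}")
        if not 0.0 <= self.ani_cutoff <= 100.0:
            raise ValueError("ani_cutoff out of [0,100]")
        if self.fragment_length <= 0 or self.min_contig <= 0:
            raise ValueError("lengths must be positive")

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
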