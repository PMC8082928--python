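"""Declarative pipeline configuration with recommended defaults.

Every threshold of the pipeline is exposed here; constructing a
``PipelineConfig`` with no arguments yields the recommended parameter set,
so the zero-config path is the documented behaviour. Configurations
round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .germline import GermlineConfig
from .somatic import SomaticConfig


@dataclass
class SimConfig:
    reference_length: int = 1_000_000
    n_repeat_copies: int = 40
    coverage: float = 20.0
    error_sub: float = 0.052
    error_ins: float = 0.044
    error_del: float = 0.066
    seed: int = 0


@dataclass
class PipelineConfig:
    germline: GermlineConfig = field(default_factory=GermlineConfig)
    min_normal_depth: int = 9
    tra_merge_window: int = 500
    consensus_flank: int = 500
    consensus_max_ins_distance: int = 100
    benchmark_max_dist: int = 500
    virus_min_support: int = 2
    virus_cluster_window: int = 500
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def somatic(self) -> SomaticConfig:
        return SomaticConfig(
            germline=self.germline,
            min_normal_depth=self.min_normal_depth,
            tra_merge_window=self.tra_merge_window,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        germ = GermlineConfig(**data.pop("germline", {}) or {})
        sim = SimConfig(**data.pop("sim", {}) or {})
        known = {f.name for f in fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(germline=germ, sim=sim, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
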