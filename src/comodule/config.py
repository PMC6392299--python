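"""Run configuration for the module-detection pipeline.

Defaults reproduce the published analysis settings: genes kept at mean
TPM > 1.0, soft powers searched over 1..20 against a scale-free fit target
of R^2 >= 0.8, minimum module size 30, eigengene merge threshold 0.05,
trait selection at |r| > 0.6 and p < 0.01 (the figure legend variant uses
r > 0.65; both are valid published values — 0.6 is the default here), and
pathway FDR at 0.05.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class AnalysisConfig:
    tpm_threshold: float = 1.0
    soft_power_grid: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_target: float = 0.8
    min_module_size: int = 30
    merge_dissimilarity: float = 0.05
    cut_quantile: float = 0.97
    split_dissimilarity: float = 0.1
    kme_threshold: float = 0.7
    refine_iterations: int = 3
    apply_power_floor: bool = True
    trait_r_threshold: float = 0.6
    trait_p_threshold: float = 0.01
    fdr_threshold: float = 0.05
    log_transform: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.soft_power_grid = tuple(int(b) for b in self.soft_power_grid)
        self.validate()

    def validate(self) -> None:
        if self.tpm_threshold < 0:
            raise ValueError("tpm_threshold must be >= 0")
        if not self.soft_power_grid:
            raise ValueError("soft_power_grid must be non-empty")
        if any(b < 1 for b in self.soft_power_grid):
            raise ValueError("soft powers must be >= 1")
        if not 0 < self.scale_free_r2_target <= 1:
            raise ValueError("scale_free_r2_target must be in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0 <= self.merge_dissimilarity < 1:
            raise ValueError("merge_dissimilarity must be in [0, 1)")
        if not 0 < self.split_dissimilarity < 1:
            raise ValueError("split_dissimilarity must be in (0, 1)")
        if not 0 < self.kme_threshold < 1:
            raise ValueError("kme_threshold must be in (0, 1)")
        if self.refine_iterations < 0:
            raise ValueError("refine_iterations must be >= 0")
        if not 0 < self.cut_quantile <= 1:
            raise ValueError("cut_quantile must be in (0, 1]")
        if not 0 < self.trait_r_threshold < 1:
            raise ValueError("trait_r_threshold must be in (0, 1)")
        for name in ("trait_p_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: "str | Path | None" = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: "str | Path") -> "AnalysisConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "AnalysisConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
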