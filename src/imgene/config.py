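"""Declarative pipeline configuration (YAML) with strict validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All stage parameters plus the single global seed.

    Unknown keys in a config file are rejected rather than ignored so typos
    cannot silently revert a parameter to its default.
    """

    seed: int = 0
    outdir: str = "imgene_run"
    # stage toggles
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "genomics", "phenotype", "spatial", "subtype", "imgene"])
    # input paths (unused when the simulate stage is enabled)
    cell_table: str | None = None
    mutation_table: str | None = None
    clinical_table: str | None = None
    # simulation scale
    n_patients: int = 257
    n_pn_positive: int = 53
    n_mihc_patients: int = 92
    cells_per_roi: float = 250.0
    # phenotyping
    cofactor: float = 1.0
    gate_threshold: float = 0.5
    # spatial
    knn_k: int = 20
    k_cn: int = 10
    n_perm: int = 1000
    interaction_radius_um: float = 4.0
    max_interaction_rois: int | None = 40   # subsample ROIs for the permutation test
    # subtyping
    rank: int = 2
    cnmf_iterations: int = 50
    # predictor
    k_features: int = 10
    val_fraction: float = 0.3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        valid_stages = {"simulate", "genomics", "phenotype", "spatial",
                        "subtype", "imgene"}
        unknown = set(self.stages) - valid_stages
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.cofactor <= 0 or self.interaction_radius_um <= 0:
            raise ConfigError("cofactor and interaction radius must be positive")
        if self.rank < 2:
            raise ConfigError("rank must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
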