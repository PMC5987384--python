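"""Shared run configuration: generator plus analysis parameters, YAML-backed."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .synthetic_data import ConfigError, GeneratorConfig


@dataclass
class AnalysisConfig:
    """Parameters of the analysis stages (dating, enrichment, quant)."""

    old_min: float = 435.0
    young_max: float = 96.0
    strict_old: bool = True
    min_orthologs: int = 4
    disorder_threshold: float = 0.5
    emergence_mode: str = "stretch"

    bootstrap_B: int = 1000
    kinase_score_max: float = 2.0
    match_residue: bool = True
    bonferroni: bool = False

    low_quantile: float = 1.0 / 3.0
    n_tissues: int = 9

    def validate(self) -> list[str]:
        errors: list[str] = []
        if not self.old_min > self.young_max > 0:
            errors.append(
                f"old_min ({self.old_min}) must exceed young_max "
                f"({self.young_max}) which must be positive"
            )
        if self.bootstrap_B < 1:
            errors.append(f"bootstrap_B: {self.bootstrap_B} must be >= 1")
        if not 0.0 <= self.disorder_threshold <= 1.0:
            errors.append(
                f"disorder_threshold: {self.disorder_threshold} outside [0, 1]"
            )
        if not 0.0 <= self.low_quantile <= 1.0:
            errors.append(f"low_quantile: {self.low_quantile} outside [0, 1]")
        if self.min_orthologs < 1:
            errors.append(f"min_orthologs: {self.min_orthologs} must be >= 1")
        if self.kinase_score_max < 0:
            errors.append(f"kinase_score_max: {self.kinase_score_max} negative")
        if self.emergence_mode not in ("stretch", "earliest"):
            errors.append(f"emergence_mode: unknown mode {self.emergence_mode!r}")
        if self.n_tissues < 1:
            errors.append(f"n_tissues: {self.n_tissues} must be >= 1")
        return errors

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown analysis config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunConfig:
    """Top-level config: a generator block and an analysis block."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> list[str]:
        errors = [f"generator.{e}" for e in self.generator.validate()]
        errors += [f"analysis.{e}" for e in self.analysis.validate()]
        if self.generator.old_min != self.analysis.old_min:
            errors.append(
                "generator.old_min and analysis.old_min disagree "
                f"({self.generator.old_min} vs {self.analysis.old_min})"
            )
        if self.generator.young_max != self.analysis.young_max:
            errors.append(
                "generator.young_max and analysis.young_max disagree "
                f"({self.generator.young_max} vs {self.analysis.young_max})"
            )
        return errors

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        unknown = set(data) - {"generator", "analysis"}
        if unknown:
            raise ConfigError(f"unknown top-level config keys {sorted(unknown)}")
        return cls(
            generator=GeneratorConfig.from_dict(data.get("generator", {}) or {}),
            analysis=AnalysisConfig.from_dict(data.get("analysis", {}) or {}),
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run config; ``None`` gives all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def validate_config(path: str | Path | None) -> list[str]:
    """Parse and validate a config file; returns the error list (empty = ok)."""
    try:
        config = load_config(path)
    except (ConfigError, yaml.YAMLError, OSError) as exc:
        return [str(exc)]
    return config.validate()
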