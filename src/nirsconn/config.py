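"""Pipeline configuration: every tunable with the study defaults.

``PipelineConfig`` nests the per-stage configurations and round-trips
to YAML; unknown keys anywhere in the file are rejected so typos do
not silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .preprocess import QualityConfig
from .synth import SimulationConfig


@dataclass
class EpochingConfig:
    epoch_length: float = 30.0
    overlap: float = 5.0
    saturation_limit: float = 10.0  # µM
    threshold: float = 0.5
    aggregate: str = "mean_abs_r"

    def __post_init__(self) -> None:
        if self.overlap >= self.epoch_length:
            raise ConfigurationError("overlap must be below epoch_length")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigurationError("threshold must lie in (0, 1]")
        if self.aggregate not in ("mean_abs_r", "concatenate"):
            raise ConfigurationError(f"unknown aggregate {self.aggregate!r}")


@dataclass
class SamplerConfig:
    n_chains: int = 8
    n_iter: int = 2000
    n_warmup: int = 1000
    target_accept: float = 0.95
    max_depth: int = 10

    def __post_init__(self) -> None:
        if self.n_warmup >= self.n_iter:
            raise ConfigurationError("n_warmup must be below n_iter")
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")


@dataclass
class InferenceConfig:
    n_pred_draws: int = 1000
    hdi_mass: float = 0.89
    rope_fraction: float = 0.1
    response_sd: float | None = None  # default: empirical SD of the degree column

    def __post_init__(self) -> None:
        if not 0.0 < self.hdi_mass < 1.0:
            raise ConfigurationError("hdi_mass must lie in (0, 1)")
        if self.rope_fraction <= 0:
            raise ConfigurationError("rope_fraction must be positive")


@dataclass
class CohortConfig:
    """Synthetic cohort: who is recorded and what effect is injected."""

    n_per_group: tuple[int, int, int] = (4, 5, 5)  # Sham, DLPFC, VLPFC
    n_clusters_base: int = 4
    n_clusters_effect: int = 2
    effect_cells: list[tuple[str, str]] = field(
        default_factory=lambda: [("DLPFC", "Post1month")]
    )
    coupling: tuple[float, float] = (0.6, 0.9)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_group):
            raise ConfigurationError("every group needs at least one participant")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    quality: QualityConfig = field(default_factory=QualityConfig)
    ppf: tuple[float, float] = (6.0, 6.0)
    epoching: EpochingConfig = field(default_factory=EpochingConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        return _from_dict(cls, raw, path="")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _from_dict(cls, raw: dict, path: str):
    if not isinstance(raw, dict):
        raise ConfigurationError(f"expected a mapping at {path or 'top level'}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigurationError(f"unknown config keys at {path or 'top level'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in raw.items():
        ftype = fields[name].type
        if isinstance(value, dict) and not str(ftype).startswith("dict"):
            sub = {
                "simulation": SimulationConfig,
                "quality": QualityConfig,
                "epoching": EpochingConfig,
                "sampler": SamplerConfig,
                "inference": InferenceConfig,
                "cohort": CohortConfig,
            }.get(name)
            if sub is None:
                raise ConfigurationError(f"unexpected mapping for key {path}{name}")
            kwargs[name] = _from_dict(sub, value, path=f"{path}{name}.")
        elif isinstance(value, list):
            kwargs[name] = [tuple(v) if isinstance(v, list) else v for v in value]
        else:
            kwargs[name] = value
    # YAML has no tuples; coerce list-valued fields back
    for name, v in list(kwargs.items()):
        default = getattr(cls(), name) if not dataclasses.is_dataclass(v) else None
        if isinstance(default, tuple) and isinstance(v, list):
            kwargs[name] = tuple(v)
    return cls(**kwargs)
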