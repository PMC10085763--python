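"""Run-configuration schema and tiny bundled-fixture generation.

A run is described by one YAML file with per-stage seeds; unknown keys
are rejected so typos fail loudly, and every stochastic stage must name
an explicit seed for full reproducibility.
"""

from __future__ import annotations

import dataclasses

import yaml

from .models import ChainSettings
from .scheme import SchemeConfig
from .simpop import TrainingPopConfig, make_training_population

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "fixture"]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration: a SchemeConfig plus seeds."""

    scheme: SchemeConfig
    seeds: dict[str, int]
    out_dir: str | None = None

    REQUIRED_SEEDS = ("scheme",)

    def seed(self, stage: str) -> int:
        return self.seeds[stage]


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if key == "training" and isinstance(value, dict):
            value = _build_dataclass(TrainingPopConfig, value, f"{path}.training")
        elif key == "chain" and isinstance(value, dict):
            value = _build_dataclass(ChainSettings, value, f"{path}.chain")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(data: dict) -> RunConfig:
    """Validate an already-parsed mapping into a RunConfig."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - {"scheme", "seeds", "out_dir"}
    if unknown:
        raise ConfigError(f"unknown top-level keys {sorted(unknown)}")
    seeds = data.get("seeds")
    if not isinstance(seeds, dict) or not seeds:
        raise ConfigError("config must declare a 'seeds' mapping")
    for stage in RunConfig.REQUIRED_SEEDS:
        if stage not in seeds:
            raise ConfigError(f"missing seed for stage {stage!r}")
        if not isinstance(seeds[stage], int):
            raise ConfigError(f"seed for stage {stage!r} must be an integer")
    scheme = _build_dataclass(SchemeConfig, data.get("scheme", {}), "scheme")
    return RunConfig(scheme=scheme, seeds=dict(seeds), out_dir=data.get("out_dir"))


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return load_config(data or {})


#: fixture registry: name -> TrainingPopConfig factory
_FIXTURES = {
    "mini14": lambda: TrainingPopConfig(
        n_founders=16, n_markers=200, n_chromosomes=5,
        family_sizes=(4,) * 14,
        family_h2_targets=(0.39, 0.44, 0.56, 0.73, 0.07, 0.55, 0.44,
                           0.01, 0.04, 0.32, 0.48, 0.55, 0.44, 0.28),
        n_qtl=40,
    ),
    "mini2": lambda: TrainingPopConfig(
        n_founders=4, n_markers=120, n_chromosomes=3,
        family_sizes=(20, 20), family_h2_targets=(0.5, 0.5), n_qtl=30,
    ),
}


def fixture(name: str, seed: int = 0):
    """A tiny in-memory dataset (<= 56 lines, <= 200 markers) for tests
    and documentation: returns (MarkerMatrix, Pedigree, phenotypes,
    family labels, extras)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    return make_training_population(_FIXTURES[name](), seed=seed)
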