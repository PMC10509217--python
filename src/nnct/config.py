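"""Run configuration: schema, defaults, validation.

Configs are YAML (or JSON) mappings.  Unknown keys are rejected with the
offending key names so that typos never silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULT_COVARIATES = (
    "sex",
    "brain_volume",
    "motion_translation",
    "motion_rotation",
    "outlier_ratio",
)

#: Covariates that may appear in a config; strength/density are computed
#: per subject from the connectome, the rest come from the cohort table.
ALLOWED_COVARIATES = DEFAULT_COVARIATES + ("network_strength", "network_density")


@dataclass
class PathsConfig:
    cohort: str = ""
    atlas: str = ""
    connectome_dir: str = ""
    out_dir: str = "nnct_out"


@dataclass
class NormalizationConfig:
    offset: float = 1.0
    threshold: float = 0.001


@dataclass
class EnergyConfig:
    T: float = 1.0
    n_grid: int = 1001
    state_cost_on: bool = True


@dataclass
class NullConfig:
    n_null: int = 100
    n_swaps_per_edge: int = 10
    #: null-model energy comparisons are expensive; run them on the first
    #: n_subjects cohort records only
    n_subjects: int = 5


@dataclass
class StatsConfig:
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    q: float = 0.05


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    nulls: NullConfig = field(default_factory=NullConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "paths": PathsConfig,
    "normalization": NormalizationConfig,
    "energy": EnergyConfig,
    "nulls": NullConfig,
    "stats": StatsConfig,
}
_SCALARS = {"seed", "log_level"}


def _build_section(cls, data, section):
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    known = set(cls.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown key(s) in section {section!r}: {unknown}")
    return cls(**data)


def load_config(path_or_dict) -> RunConfig:
    """Parse and validate a YAML/JSON config into a :class:`RunConfig`."""
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        text = Path(path_or_dict).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = sorted(set(raw) - set(_SECTIONS) - _SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {unknown}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build_section(cls, raw[name], name)
    for name in _SCALARS:
        if name in raw:
            kwargs[name] = raw[name]
    cfg = RunConfig(**kwargs)
    _check_values(cfg)
    return cfg


def validate_config(path, require_paths: bool = True) -> RunConfig:
    """Load a config file and (optionally) check referenced input paths
    exist.  ``out_dir`` is created rather than required."""
    cfg = load_config(path)
    if require_paths:
        for name in ("cohort", "atlas", "connectome_dir"):
            value = getattr(cfg.paths, name)
            if not value:
                raise ConfigError(f"paths.{name} is required")
            if not Path(value).exists():
                raise ConfigError(f"paths.{name} does not exist: {value}")
    return cfg


def _check_values(cfg: RunConfig) -> None:
    if cfg.energy.T <= 0:
        raise ConfigError("energy.T must be positive")
    if cfg.energy.n_grid < 2:
        raise ConfigError("energy.n_grid must be >= 2")
    if cfg.nulls.n_null < 0:
        raise ConfigError("nulls.n_null must be >= 0")
    if cfg.nulls.n_swaps_per_edge < 1:
        raise ConfigError("nulls.n_swaps_per_edge must be >= 1")
    if cfg.nulls.n_subjects < 0:
        raise ConfigError("nulls.n_subjects must be >= 0")
    if not 0 < cfg.stats.q < 1:
        raise ConfigError("stats.q must be in (0, 1)")
    if cfg.normalization.offset <= 0:
        raise ConfigError("normalization.offset must be positive")
    if cfg.normalization.threshold < 0:
        raise ConfigError("normalization.threshold must be >= 0")
    bad = sorted(set(cfg.stats.covariates) - set(ALLOWED_COVARIATES))
    if bad:
        raise ConfigError(
            f"unknown covariate(s) {bad}; allowed: {sorted(ALLOWED_COVARIATES)}"
        )
    if not isinstance(cfg.seed, int) or cfg.seed < 0:
        raise ConfigError("seed must be a non-negative integer")


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True))
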