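"""Experiment configuration: YAML schema, validation, seed fan-out.

A run is reproducible from a config file plus its seed list alone. Unknown
keys are rejected so typos fail loudly; parameter bounds baked into the
genome representation are validated rather than silently reinterpreted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .development import DevoConfig
from .evolution import EvoConfig
from .genome import ELL_MAX, ELL_MIN, PHI_MAX, PHI_MIN, EVO, EVO_DEVO, GridSpec, MutationParams
from .physics import PhysicsConfig

__all__ = ["ConfigError", "ExperimentConfig", "load_config", "save_config", "substream"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def substream(master_seed: int, *keys: int) -> np.random.Generator:
    """Derive an independent random substream from the master seed.

    Components draw from ``SeedSequence((master_seed, key...))`` so trials
    and analysis stages are reproducible in isolation without
    cross-contaminating each other's streams.
    """
    return np.random.default_rng(np.random.SeedSequence((master_seed,) + keys))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce an experiment: grid, development,
    physics, mutation and evolution settings, treatment, seed list."""

    seeds: list[int] = field(default_factory=lambda: [0])
    treatment: str = EVO_DEVO
    grid: GridSpec = field(default_factory=GridSpec)
    devo: DevoConfig = field(default_factory=DevoConfig)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    mutation: MutationParams = field(default_factory=MutationParams)
    pop_size: int = 30
    generations: int = 10_000
    record_interval: float = 0.01
    out_dir: str = "runs"

    def evo_config(self) -> EvoConfig:
        return EvoConfig(
            grid=self.grid,
            devo=self.devo,
            physics=self.physics,
            mutation=self.mutation,
            treatment=self.treatment,
            pop_size=self.pop_size,
            generations=self.generations,
            record_interval=self.record_interval,
        )

    def to_dict(self) -> dict:
        return {
            "seeds": list(self.seeds),
            "treatment": self.treatment,
            "grid": dataclasses.asdict(self.grid),
            "devo": dataclasses.asdict(self.devo),
            "physics": dataclasses.asdict(self.physics),
            "mutation": dataclasses.asdict(self.mutation),
            "evo": {"pop_size": self.pop_size, "generations": self.generations},
            "record_interval": self.record_interval,
            "out_dir": self.out_dir,
            "bounds": {
                "ell_min": ELL_MIN,
                "ell_max": ELL_MAX,
                "phi_min": PHI_MIN,
                "phi_max": PHI_MAX,
            },
        }


def _build(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' section: {exc}") from exc


_TOP_KEYS = {
    "seed",
    "seeds",
    "treatment",
    "grid",
    "devo",
    "physics",
    "mutation",
    "evo",
    "record_interval",
    "out_dir",
    "bounds",
}

_CANONICAL_BOUNDS = {
    "ell_min": ELL_MIN,
    "ell_max": ELL_MAX,
    "phi_min": PHI_MIN,
    "phi_max": PHI_MAX,
}


def config_from_dict(data: dict) -> ExperimentConfig:
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "seed" in data and "seeds" in data:
        raise ConfigError("give either 'seed' or 'seeds', not both")
    seeds = data.get("seeds", [data["seed"]] if "seed" in data else [0])
    if not isinstance(seeds, list) or not all(isinstance(s, int) for s in seeds):
        raise ConfigError("'seeds' must be a list of integers")

    treatment = data.get("treatment", EVO_DEVO)
    if treatment not in (EVO, EVO_DEVO):
        raise ConfigError(f"treatment must be {EVO!r} or {EVO_DEVO!r}")

    bounds = data.get("bounds", {})
    unknown_b = set(bounds) - set(_CANONICAL_BOUNDS)
    if unknown_b:
        raise ConfigError(f"unknown keys in 'bounds': {sorted(unknown_b)}")
    for key, value in bounds.items():
        if not math.isclose(value, _CANONICAL_BOUNDS[key], abs_tol=1e-9):
            raise ConfigError(
                f"bounds.{key}={value} unsupported; parameter bounds are fixed "
                f"at {_CANONICAL_BOUNDS[key]:.6g} by the genome representation"
            )

    evo = dict(data.get("evo", {}))
    unknown_e = set(evo) - {"pop_size", "generations"}
    if unknown_e:
        raise ConfigError(f"unknown keys in 'evo': {sorted(unknown_e)}")

    cfg = ExperimentConfig(
        seeds=seeds,
        treatment=treatment,
        grid=_build(GridSpec, dict(data.get("grid", {})), "grid"),
        devo=_build(DevoConfig, dict(data.get("devo", {})), "devo"),
        physics=_build(PhysicsConfig, dict(data.get("physics", {})), "physics"),
        mutation=_build(MutationParams, dict(data.get("mutation", {})), "mutation"),
        pop_size=evo.get("pop_size", 30),
        generations=evo.get("generations", 10_000),
        record_interval=data.get("record_interval", 0.01),
        out_dir=data.get("out_dir", "runs"),
    )
    try:
        cfg.evo_config()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
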