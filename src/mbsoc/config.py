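"""Run configuration: defaults, YAML key-value files, CLI overrides.

Precedence is CLI flag > config file > built-in default; the defaults
reproduce the standard study conditions (seed 999, 3+3 single-step trials,
50%-subsampled compound, ε = 0.05, ε_soc = 0.005).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import MASTER_SEED, MODEL_IDS, ConfigurationError


@dataclass
class RunConfig:
    model: str = "m4"
    seed: int = MASTER_SEED
    steps_per_trial: int = 1
    trials_foc: int = 3
    trials_soc: int = 3
    compound_mode: str = "subsampled"
    extension_odor3_trials: int = 0
    epsilon: float = 0.05
    epsilon_soc: float = 0.005
    grid_points: int = 100
    workers: int = 1
    radii: int = 100
    samples: int = 700
    n_instances: int = 100
    outdir: str = "results"

    def validate(self) -> "RunConfig":
        if self.model not in MODEL_IDS:
            raise ConfigurationError(f"unknown model {self.model!r}")
        if self.compound_mode not in ("subsampled", "additive"):
            raise ConfigurationError(f"unknown compound mode {self.compound_mode!r}")
        if min(self.trials_foc, self.trials_soc, self.extension_odor3_trials) < 0:
            raise ConfigurationError("trial counts must be >= 0")
        if self.steps_per_trial < 1 or self.grid_points < 1:
            raise ConfigurationError("steps_per_trial and grid_points must be >= 1")
        if self.epsilon < 0 or self.epsilon_soc < 0:
            raise ConfigurationError("tolerances must be >= 0")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def override(self, **kwargs) -> "RunConfig":
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates).validate()


def resolve_config(config_file: str | None, **cli_overrides) -> RunConfig:
    base = RunConfig.load(config_file) if config_file else RunConfig()
    return base.override(**cli_overrides)
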