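"""Run configuration: one nested mapping covering model, sampling, engine
and analysis parameters, (de)serialized as YAML.

Unknown keys are rejected with the offending key named, and a
configuration round-trips losslessly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields as dc_fields
from typing import Mapping

import yaml

from .engine import EngineParams
from .model import ConfigurationError, ModelParams
from .sampling import SamplingParams


@dataclass(frozen=True)
class AnalysisParams:
    """Post-processing parameters (lengths A, times fs, angles deg)."""

    min_prominence: float = 0.05         # A, frustrated-dissociation peak filter
    time_bin: float = 100.0              # fs, dissociation-time histogram bin
    angle_bin: float = 10.0              # deg, dissociation-dihedral bin
    omega_bin: float = 0.5               # deg/fs, initial-angular-velocity bin
    equilibrium_tolerance: float = 0.01  # population fraction
    equilibrium_window: float = 100.0    # fs

    @classmethod
    def from_dict(cls, data: Mapping[str, object] | None) -> "AnalysisParams":
        data = dict(data or {})
        known = {f.name for f in dc_fields(cls)}
        for key in data:
            if key not in known:
                raise ConfigurationError(f"unknown analysis parameter: {key!r}")
        return cls(**data)  # type: ignore[arg-type]


@dataclass(frozen=True)
class RunConfig:
    model: ModelParams = field(default_factory=ModelParams)
    sampling: SamplingParams = field(default_factory=SamplingParams)
    engine: EngineParams = field(default_factory=EngineParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    n_trajectories: int = 310

    @classmethod
    def from_dict(cls, data: Mapping[str, object] | None) -> "RunConfig":
        data = dict(data or {})
        known = {"model", "sampling", "engine", "analysis", "seed", "n_trajectories"}
        for key in data:
            if key not in known:
                raise ConfigurationError(f"unknown configuration section: {key!r}")
        return cls(
            model=ModelParams.from_dict(data.get("model")),
            sampling=SamplingParams.from_dict(data.get("sampling")),
            engine=EngineParams.from_dict(data.get("engine")),
            analysis=AnalysisParams.from_dict(data.get("analysis")),
            seed=int(data.get("seed", 0)),
            n_trajectories=int(data.get("n_trajectories", 310)),
        )

    def to_dict(self) -> dict:
        def plain(obj):
            d = asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return {
            "model": plain(self.model),
            "sampling": plain(self.sampling),
            "engine": plain(self.engine),
            "analysis": plain(self.analysis),
            "seed": self.seed,
            "n_trajectories": self.n_trajectories,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("configuration root must be a mapping")
        return cls.from_dict(data)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return RunConfig.from_yaml(fh.read())


def default_config() -> RunConfig:
    return RunConfig()
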