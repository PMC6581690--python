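"""Run configuration: one YAML document driving every pipeline stage.

The resolved configuration (defaults merged with the user's file and any
command-line overrides) is written next to each run's outputs together
with the tool version and seed, so any output can be regenerated from its
provenance file alone. Unknown keys are rejected rather than ignored — a
typo in a threshold name must not silently fall back to a default.

Randomness policy: each run derives one root RNG from the seed, and every
stochastic stage draws from a substream keyed by its stage name, so
adding a stage never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .hyb_sim import HybModel
from .probe_design import CandidateFilters
from .specificity import SpecificityThresholds


@dataclass
class CallingConfig:
    snr_threshold: float = 2.0
    ratio_threshold: float = 1.3
    min_positive_replicates: int | None = None  # None = majority rule
    alpha: float = 0.1
    bh_correct: bool = False


@dataclass
class RunConfig:
    thresholds: SpecificityThresholds = field(default_factory=SpecificityThresholds)
    filters: CandidateFilters = field(default_factory=CandidateFilters)
    model: HybModel = field(default_factory=HybModel)
    calling: CallingConfig = field(default_factory=CallingConfig)
    probes_per_target: int = 2
    design_step: int = 1  # candidate window step (1 = every position)
    n_subarrays: int = 4
    n_replicates: int = 3
    seed: int = 0

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage RNG substream, stable under pipeline growth."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(stage.encode()) & 0x7FFFFFFF,)
        )
        return np.random.default_rng(ss)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        return _build(cls, raw, path="")


_SECTION_TYPES = {
    "thresholds": SpecificityThresholds,
    "filters": CandidateFilters,
    "model": HybModel,
    "calling": CallingConfig,
}


def _build(cls, raw: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        where = path or "top level"
        raise ConfigError(f"unknown config key(s) at {where}: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        sub = _SECTION_TYPES.get(key) if cls is RunConfig else None
        if sub is not None:
            if not isinstance(val, dict):
                raise ConfigError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build(sub, val, path=key)
        else:
            kwargs[key] = val
    try:
        return cls(**kwargs)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    return RunConfig.from_yaml(Path(path).read_text())


def write_provenance(config: RunConfig, out_dir: str | Path, command: str) -> Path:
    """Write the resolved config + version + command next to the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{command}.provenance.yaml"
    doc = {
        "tool": "fgarray",
        "version": __version__,
        "command": command,
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path
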