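"""Declarative run configuration.

A single YAML file holds every threshold of the analysis plus the input
paths; CLI flags may override individual keys. All effective values are
echoed into the run manifest so a run is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .exceptions import ConfigurationError


@dataclass
class AnalysisConfig:
    """Thresholds and estimator settings for a forward/reverse MR run."""

    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    cis_window_bp: int = 500_000
    f_min: float = 10.0
    alpha: float = 0.05
    palindrome_eaf_limit: float = 0.42
    bootstrap_reps: int = 1000
    presso_sims: int = 1000
    presso_outlier_p: float = 0.05
    bandwidth_factor: float = 1.0
    seed: int = 0
    inputs: dict = field(default_factory=dict)

    REQUIRED_INPUTS = ("discovery", "estimation", "ld", "trial_effects",
                       "trial_directions", "gene_map", "outcomes")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"configuration file {path} must be a mapping")
        return cls.from_dict(raw)

    def require_inputs(self, *keys: str) -> None:
        keys = keys or self.REQUIRED_INPUTS
        for key in keys:
            if key not in self.inputs:
                raise ConfigurationError(f"missing required input key '{key}'")
            value = self.inputs[key]
            paths = value.values() if isinstance(value, dict) else [value]
            for p in paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"input path for '{key}' does not exist: {p}")
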