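"""Run configuration: one YAML file describes a whole pipeline run.

The config nests the simulation conditions, preprocessing tables
(acceptable ranges, early-warning bands), feature resolutions, model
hyperparameters and evaluation protocol (k folds, bootstrap iterations,
lead hours), with every source of randomness behind a named seed.  It
round-trips losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from cawarn.channels import DEFAULT_ACCEPTABLE_RANGES, DEFAULT_EWS_BANDS
from cawarn.errors import ConfigError
from cawarn.features import DEFAULT_RESOLUTIONS
from cawarn.model import ModelConfig
from cawarn.simulate import SimConfig


def _ranges_to_lists(ranges: dict) -> dict:
    return {ch: [float(lo), float(hi)] for ch, (lo, hi) in ranges.items()}


def _bands_to_lists(bands: dict) -> dict:
    return {
        ch: {"bounds": [[float(b), int(s)] for b, s in t["bounds"]], "above": int(t["above"])}
        for ch, t in bands.items()
    }


@dataclass
class PipelineConfig:
    window_hours: int = 24
    resolutions: list = field(default_factory=lambda: list(DEFAULT_RESOLUTIONS))
    acceptable_ranges: dict = field(default_factory=lambda: _ranges_to_lists(DEFAULT_ACCEPTABLE_RANGES))
    ews_bands: dict = field(default_factory=lambda: _bands_to_lists(DEFAULT_EWS_BANDS))
    sim: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    k: int = 10
    n_boot: int = 1000
    leads: list = field(default_factory=list)  # empty -> no lead-time curve
    cv_seed: int = 0
    records_path: str | None = None  # set to evaluate an on-disk cohort
    labels_path: str | None = None

    def __post_init__(self) -> None:
        if self.window_hours not in (12, 24):
            raise ConfigError("window_hours must be 12 or 24")
        if self.sim.window_hours != self.window_hours:
            raise ConfigError("sim.window_hours must match window_hours")
        if self.leads and self.sim.lead_reserve_hours < max(self.leads) - 1:
            raise ConfigError(
                "sim.lead_reserve_hours must be >= max(leads) - 1 for lead-time evaluation"
            )

    @property
    def ranges(self) -> dict:
        return {ch: (lo, hi) for ch, (lo, hi) in self.acceptable_ranges.items()}

    @property
    def bands(self) -> dict:
        return {
            ch: {"bounds": [(b, s) for b, s in t["bounds"]], "above": t["above"]}
            for ch, t in self.ews_bands.items()
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = asdict(self.sim)
        d["model"] = asdict(self.model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "model" in d and isinstance(d["model"], dict):
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
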