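"""Run configuration: one document that pins every tunable of a run.

A resolved :class:`RunConfig` round-trips losslessly through YAML (JSON is
valid YAML and therefore also accepted), and commands that write outputs
drop the resolved config beside them for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .compartment import DEFAULT_FLOW_FRACTIONS, DEFAULT_VOLUME_FRACTIONS
from .errors import ValidationError
from .synthetic import DEFAULT_MARGINALS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    # calibration
    kappa_hu_per_mg_ml: float = 25.0
    kvp: float = 120.0
    baseline_hu: float = 40.0
    # model
    heart_volume_coeff: float = 1.0
    volume_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_VOLUME_FRACTIONS))
    flow_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_FLOW_FRACTIONS))
    # estimator
    bracket_l_min: tuple = (2.0, 12.0)
    ttp_tolerance_l_min: float = 0.01
    dt_s: float = 0.05
    # cohort
    cohort_n: int = 50
    noise_sd_hu: float = 10.0
    baseline_sd_hu: float = 7.0
    sampling_interval_s: float = 2.0
    scan_delay_s: float = 12.0
    duration_s: float = 40.0
    sex_ratio: float = 0.5
    marginals: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_MARGINALS.items()})

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["bracket_l_min"] = list(self.bracket_l_min)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(doc)
        if "bracket_l_min" in kwargs:
            kwargs["bracket_l_min"] = tuple(kwargs["bracket_l_min"])
        if "marginals" in kwargs:
            kwargs["marginals"] = {k: list(v)
                                   for k, v in kwargs["marginals"].items()}
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as err:
        raise ValidationError(f"{path}: not valid YAML/JSON ({err})")
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(doc)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
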