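"""Configuration objects: geographic boundaries, grouping windows, prior hyperparameters.

All values are configurable via plain dataclasses and can be loaded from a
YAML/JSON mapping with :func:`load_config`.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class AreaBoundaries:
    """Rectangular approximation of the four sub-Saharan wintering areas.

    Boundaries are half-open with the southern/western side inclusive:
    a point exactly on ``southern_lat`` belongs to the Southern area, a point
    exactly on ``west_central_lon`` belongs to the Western area, and a point
    exactly on ``sahara_lat`` is still inside the sub-Saharan domain.
    """

    southern_lat: float = -15.4  # south of this -> Southern
    west_central_lon: float = 15.0  # west of this -> Western
    rift_lon: float = 30.0  # east of this -> Eastern
    sahara_lat: float = 15.0  # north of this -> outside the wintering domain


@dataclass(frozen=True)
class GroupingRules:
    """Seasonal windows and the Central/Southern latitude split for marking groups."""

    spring_months: tuple[int, ...] = (3, 4, 5)
    breeding_months: tuple[int, ...] = (6, 7)
    autumn_months: tuple[int, ...] = (8, 9, 10)
    winter_months: tuple[int, ...] = (11, 12, 1, 2)
    lat_split: float = 52.0  # >= lat_split -> Central (northern) prefix
    # chicks ringed in autumn months go to the autumn group rather than the
    # breeding group; set False to send every chick to *_breeding instead
    chicks_follow_autumn: bool = True


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of every prior distribution in the joint model."""

    mu_s_d13c_mean: float = 0.97
    mu_s_d13c_sd: float = 0.07
    theta_sd: float = 1.0  # half-normal on -theta
    mu_d15n_sd: float = 1.0  # standard normal on both d15N means
    rho0_southern_beta: tuple[float, float] = (10.0, 4.0)
    rho0_wce_beta: tuple[float, float] = (2.0, 4.0)
    sigma_sd: float = 2.0  # half-normal on isotope component SDs
    a_sd: float = 5.0  # half-normal on the prevalence ratio


@dataclass(frozen=True)
class ModelConfig:
    boundaries: AreaBoundaries = field(default_factory=AreaBoundaries)
    grouping: GroupingRules = field(default_factory=GroupingRules)
    priors: PriorConfig = field(default_factory=PriorConfig)
    active_sources: tuple[str, ...] = ("rings", "isotopes", "parasites")


def _from_mapping(cls, mapping: dict[str, Any]):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in mapping:
            continue
        value = mapping[f.name]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "boundaries",
            "grouping",
            "priors",
        ):
            sub = {"boundaries": AreaBoundaries, "grouping": GroupingRules, "priors": PriorConfig}[f.name]
            value = _from_mapping(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> ModelConfig:
    """Load a :class:`ModelConfig` from a YAML or JSON file.

    Missing keys fall back to the package defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    return _from_mapping(ModelConfig, data)


def dump_config(config: ModelConfig) -> dict[str, Any]:
    """Round-trippable plain-dict snapshot of a configuration."""
    return dataclasses.asdict(config)
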