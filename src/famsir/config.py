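"""YAML configuration loading for the command-line pipeline.

A config file is a mapping with optional sections ``registry``,
``intervals``, ``simulate``, ``grid``, ``spm`` and ``comparison``; every key
falls back to the package default, so an empty file is a valid config.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Optional

import yaml

from .pipeline import AnalysisSpec, default_grid
from .registry import RegistryConfig
from .simulate import SimulationParams

__all__ = [
    "load_config",
    "registry_config_from",
    "simulation_params_from",
    "grid_from",
]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return data


def registry_config_from(data: dict, paper_mode: Optional[bool] = None) -> RegistryConfig:
    section = dict(data.get("registry", {}))
    intervals = data.get("intervals", {})
    if "breaks" in intervals:
        section["age_breaks"] = tuple(intervals["breaks"])
    if paper_mode is not None:
        section["paper_mode"] = paper_mode
    return RegistryConfig(**section)


def simulation_params_from(data: dict, seed: Optional[int] = None) -> SimulationParams:
    section: dict[str, Any] = dict(data.get("simulate", {}))
    if "children_dist" in section:
        section["children_dist"] = {int(k): float(v) for k, v in section["children_dist"].items()}
    if "birth_year_range" in section:
        section["birth_year_range"] = tuple(section["birth_year_range"])
    if seed is not None:
        section["seed"] = seed
    section["config"] = registry_config_from(data)
    return SimulationParams(**section)


def grid_from(data: dict, family: str = "relatives") -> list[AnalysisSpec]:
    key = "grid" if family == "relatives" else "spm"
    section = data.get(key, {})
    if not section:
        if family == "relatives":
            return default_grid("relatives")
        return default_grid("spm", modes=("any_cancer",))
    filters = section.get("proband_filters", ["any", "hematologic", "solid"])
    modes = section.get("modes", ["any_cancer"])
    pops = section.get("populations", ["all"])
    return [
        AnalysisSpec(pf, mode, pop, family)
        for pf in filters
        for mode in modes
        for pop in pops
    ]
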