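"""YAML configuration: shipped defaults and user overrides.

All tunable constants — lamella width, serial-section separations,
benchmark workflow areas and mill times, imaging geometry and planner
thresholds — ship in ``data/defaults.yaml``, mirroring the in-code
defaults.  A user YAML with the same structure (any subset of keys)
overrides them, which is how alternative separations (sub-4-um serial
sections) or transition boundaries are explored.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .entries import Freezing, Sectioning
from .lamella import ImagingGeometry, PlannerThresholds, WorkflowSpec

__all__ = [
    "load_defaults",
    "planner_thresholds_from_config",
    "imaging_geometry_from_config",
    "workflows_from_config",
    "default_richness_path",
]


def load_defaults(overrides: str | Path | None = None) -> dict:
    """Shipped default constants, optionally shallow-merged with a user YAML."""
    with resources.files("cryoet_census.data").joinpath("defaults.yaml").open() as fh:
        config = yaml.safe_load(fh)
    if overrides is not None:
        with open(overrides) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


def planner_thresholds_from_config(config: dict) -> PlannerThresholds:
    section = config.get("planner_thresholds", {})
    return PlannerThresholds(**section)


def imaging_geometry_from_config(config: dict) -> ImagingGeometry:
    section = config.get("imaging_geometry", {})
    return ImagingGeometry(**section)


def workflows_from_config(config: dict) -> dict[str, WorkflowSpec]:
    out = {}
    for name, spec in config.get("workflows", {}).items():
        out[name] = WorkflowSpec(
            name=name,
            freezing=Freezing(spec["freezing"]),
            sectioning=Sectioning(spec["sectioning"]),
            lamella_area_al_um2=float(spec["lamella_area_al_um2"]),
            mill_time_tl_min=float(spec["mill_time_tl_min"]),
        )
    return out


def default_richness_path() -> Path:
    """Path to the shipped synthetic richness-constants table."""
    return Path(
        str(resources.files("cryoet_census.data").joinpath("richness_synthetic.yaml"))
    )
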