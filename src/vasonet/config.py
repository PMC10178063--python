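"""Run configuration: fluid, binning, physiological ranges and growth policy.

Loaded from a YAML file; unknown keys are rejected so typos fail loudly.
CLI flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import yaml

from .errors import NetworkFileError
from .growth import GrowthPolicy
from .network import FluidProperties
from .shear import VELOCITY_BIN_WIDTH, BinningScheme, PhysiologicalRanges

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RunConfig:
    fluid: FluidProperties = field(default_factory=FluidProperties)
    binning: BinningScheme = field(default_factory=BinningScheme)
    ranges: PhysiologicalRanges = field(default_factory=PhysiologicalRanges)
    policy: GrowthPolicy = field(default_factory=GrowthPolicy)
    velocity_bin: float = VELOCITY_BIN_WIDTH
    log_level: str = "info"


_SECTIONS = {
    "fluid": FluidProperties,
    "binning": BinningScheme,
    "ranges": PhysiologicalRanges,
    "policy": GrowthPolicy,
}


def _build_section(cls, data, context):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise NetworkFileError(f"{context}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise NetworkFileError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise NetworkFileError(f"{context}: {exc}") from exc


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    ``overrides`` maps ``section.key`` (e.g. ``fluid.viscosity``) to values.
    """
    doc: dict = {}
    if path is not None:
        try:
            with open(path, "r", encoding="utf-8") as fh:
                doc = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise NetworkFileError(f"{path}: not valid YAML: {exc}") from exc
        if not isinstance(doc, dict):
            raise NetworkFileError(f"{path}: expected a mapping at top level")
    known_top = set(_SECTIONS) | {"velocity_bin", "log_level"}
    unknown = set(doc) - known_top
    if unknown:
        raise NetworkFileError(f"{path}: unknown config keys {sorted(unknown)}")

    for dotted, value in (overrides or {}).items():
        if value is None:
            continue
        section, _, key = dotted.partition(".")
        if section in _SECTIONS and key:
            doc.setdefault(section, {})
            if doc[section] is None:
                doc[section] = {}
            doc[section][key] = value
        else:
            doc[dotted] = value

    parts = {name: _build_section(cls, doc.get(name), f"config section {name!r}")
             for name, cls in _SECTIONS.items()}
    return RunConfig(
        velocity_bin=float(doc.get("velocity_bin", VELOCITY_BIN_WIDTH)),
        log_level=str(doc.get("log_level", "info")),
        **parts,
    )


def dump_config(config: RunConfig, path) -> None:
    """Write the effective configuration back out (round-trippable)."""
    doc = {
        "fluid": {"density": config.fluid.density, "viscosity": config.fluid.viscosity},
        "binning": {
            "bin_width": config.binning.bin_width,
            "max_edge": config.binning.max_edge,
            "stagnation_floor": config.binning.stagnation_floor,
        },
        "ranges": {
            "wss_low": config.ranges.wss_low,
            "wss_high": config.ranges.wss_high,
            "velocity_low": config.ranges.velocity_low,
            "velocity_high": config.ranges.velocity_high,
            "diameter_low": config.ranges.diameter_low,
            "diameter_high": config.ranges.diameter_high,
        },
        "policy": {
            "sprout_length": config.policy.sprout_length,
            "sprout_radius": config.policy.sprout_radius,
            "max_iterations": config.policy.max_iterations,
            "site_selection": config.policy.site_selection,
            "attach_fraction": config.policy.attach_fraction,
            "terminal_bc_kind": config.policy.terminal_bc_kind,
            "terminal_bc_value": config.policy.terminal_bc_value,
        },
        "velocity_bin": config.velocity_bin,
        "log_level": config.log_level,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
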