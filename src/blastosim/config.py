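"""Simulation configuration: defaults, TOML loading and validation."""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .division import DivisionTiming
from .mechanics import ForceParams

__all__ = ["SimConfig", "read_config", "default_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed or incomplete configuration file."""


# section -> required keys
_SCHEMA: dict[str, tuple[str, ...]] = {
    "eggshell": ("volume_um3",),
    "cells": ("volume_fraction", "ab_volume_fraction"),
    "forces": ("F0", "shell_gain", "default_alpha", "alpha_pairs"),
    "integration": ("dt_s", "noise_variance_um2"),
    "division": (
        "t_first_s",
        "stagger_s",
        "ab_daughter_fraction",
        "p1_daughter_fraction",
        "placement_offset_um",
        "settle_s",
    ),
    "sweep": ("ar_min", "ar_max", "ar_step", "n_reps"),
}


@dataclass(frozen=True)
class SimConfig:
    """Complete, validated parameter set for runs and sweeps."""

    eggshell_volume: float
    cell_volume_fraction: float
    ab_volume_fraction: float
    F0: float
    shell_gain: float
    default_alpha: float
    alpha_pairs: dict[frozenset[str], float] = field(default_factory=dict)
    dt: float = 5.0
    noise_variance: float = 0.027
    t_first: float = 300.0
    stagger: float = 120.0
    ab_daughter_fraction: float = 0.5
    p1_daughter_fraction: float = 0.55
    placement_offset: float = 2.0
    settle: float = 600.0
    ar_min: float = 1.0
    ar_max: float = 4.0
    ar_step: float = 0.1
    n_reps: int = 30

    @property
    def total_cell_volume(self) -> float:
        return self.cell_volume_fraction * self.eggshell_volume

    def force_params(self) -> ForceParams:
        return ForceParams(
            F0=self.F0,
            default_alpha=self.default_alpha,
            alpha_table=dict(self.alpha_pairs),
            shell_gain=self.shell_gain,
            noise_variance=self.noise_variance,
            dt=self.dt,
        )

    def division_timing(self) -> DivisionTiming:
        return DivisionTiming(
            t_first=self.t_first,
            stagger=self.stagger,
            ab_daughter_fraction=self.ab_daughter_fraction,
            p1_daughter_fraction=self.p1_daughter_fraction,
            placement_offset=self.placement_offset,
            settle=self.settle,
        )

    def repulsion_only(self) -> "SimConfig":
        """Copy with every alpha forced to 1 (repulsion-only model)."""
        return replace(self, default_alpha=1.0, alpha_pairs={})

    def uniform_alpha(self, alpha: float) -> "SimConfig":
        return replace(self, default_alpha=alpha, alpha_pairs={})


def _parse_alpha_pairs(raw: dict) -> dict[frozenset[str], float]:
    pairs = {}
    for key, value in raw.items():
        labels = tuple(p.strip() for p in key.split("-"))
        if len(labels) != 2 or not all(labels):
            raise ConfigError(
                f"alpha_pairs key {key!r} is not of the form 'LABEL1-LABEL2'"
            )
        pairs[frozenset(labels)] = float(value)
    return pairs


def _validated(data: dict, source: str) -> SimConfig:
    unknown_sections = sorted(set(data) - set(_SCHEMA))
    if unknown_sections:
        raise ConfigError(f"{source}: unknown section(s) {unknown_sections}")
    for section, keys in _SCHEMA.items():
        if section not in data:
            raise ConfigError(f"{source}: missing section [{section}]")
        got = data[section]
        missing = sorted(set(keys) - set(got))
        if missing:
            raise ConfigError(
                f"{source}: section [{section}] is missing key(s) {missing}"
            )
        unknown = sorted(set(got) - set(keys))
        if unknown:
            raise ConfigError(
                f"{source}: section [{section}] has unknown key(s) {unknown}"
            )
    try:
        cfg = SimConfig(
            eggshell_volume=float(data["eggshell"]["volume_um3"]),
            cell_volume_fraction=float(data["cells"]["volume_fraction"]),
            ab_volume_fraction=float(data["cells"]["ab_volume_fraction"]),
            F0=float(data["forces"]["F0"]),
            shell_gain=float(data["forces"]["shell_gain"]),
            default_alpha=float(data["forces"]["default_alpha"]),
            alpha_pairs=_parse_alpha_pairs(data["forces"]["alpha_pairs"]),
            dt=float(data["integration"]["dt_s"]),
            noise_variance=float(data["integration"]["noise_variance_um2"]),
            t_first=float(data["division"]["t_first_s"]),
            stagger=float(data["division"]["stagger_s"]),
            ab_daughter_fraction=float(data["division"]["ab_daughter_fraction"]),
            p1_daughter_fraction=float(data["division"]["p1_daughter_fraction"]),
            placement_offset=float(data["division"]["placement_offset_um"]),
            settle=float(data["division"]["settle_s"]),
            ar_min=float(data["sweep"]["ar_min"]),
            ar_max=float(data["sweep"]["ar_max"]),
            ar_step=float(data["sweep"]["ar_step"]),
            n_reps=int(data["sweep"]["n_reps"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    if cfg.eggshell_volume <= 0 or not math.isfinite(cfg.eggshell_volume):
        raise ConfigError(f"{source}: eggshell volume must be positive and finite")
    if not (0.0 < cfg.cell_volume_fraction <= 1.5):
        raise ConfigError(f"{source}: cells.volume_fraction out of range")
    if not (0.0 < cfg.ab_volume_fraction < 1.0):
        raise ConfigError(f"{source}: cells.ab_volume_fraction out of range")
    cfg.force_params()  # force-law parameter validation
    return cfg


def read_config(path: str | Path) -> SimConfig:
    """Load and validate a TOML configuration file."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: TOML parse error: {exc}") from exc
    return _validated(data, str(path))


def default_config() -> SimConfig:
    """The frozen default configuration shipped with the package."""
    text = resources.files("blastosim").joinpath("data/default.toml").read_text()
    return _validated(tomllib.loads(text), "default.toml")
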