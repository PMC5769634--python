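"""Replicated aspect-ratio sweeps and frequency tables.

A sweep runs ``n_reps`` seeded replicates of a division program at every
aspect ratio on a grid (constant eggshell volume), classifies each final
four-cell state and tabulates pattern frequencies.  The repulsion-only (RO)
model is the asymmetric-attraction (AA) model with every alpha forced to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PATTERN_LABELS, classify_pattern, contact_graph
from .config import SimConfig
from .division import ORIENTATION_CLASSES, DivisionProgram, build_program
from .geometry import axes_from_ar
from .simulator import EmbryoState, Trajectory, run

__all__ = [
    "MODELS",
    "ProgramSpec",
    "WILD_TYPE",
    "ar_grid",
    "run_replicate",
    "ar_sweep",
    "first_ar_with_pattern",
    "last_ar_with_pattern",
    "write_sweep_csv",
    "read_sweep_csv",
]

MODELS = ("RO", "AA")
_CLASS_CODE = {name: k for k, name in enumerate(sorted(ORIENTATION_CLASSES))}


@dataclass(frozen=True)
class ProgramSpec:
    """Division-program selector for a sweep condition."""

    orientation_class: str = "T-div"
    timing_mode: str = "asynchronous"
    volume_mode: str = "asymmetric"


WILD_TYPE = ProgramSpec("T-div", "asynchronous", "asymmetric")


def ar_grid(ar_min: float, ar_max: float, ar_step: float) -> list[float]:
    """Aspect-ratio grid [ar_min, ar_max] with the given step, rounded to
    avoid floating-point drift across the sweep."""
    if ar_min < 1.0 or ar_max < ar_min or ar_step <= 0.0:
        raise ValueError(
            f"invalid grid: ar_min={ar_min}, ar_max={ar_max}, ar_step={ar_step}"
        )
    n = int(round((ar_max - ar_min) / ar_step)) + 1
    return [round(ar_min + k * ar_step, 10) for k in range(n)]


def _model_config(config: SimConfig, model: str) -> SimConfig:
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    return config.repulsion_only() if model == "RO" else config


def _replicate_seed(
    master_seed: int, spec: ProgramSpec, ar_index: int, rep: int
) -> np.random.SeedSequence:
    """Independent, insertion-order-invariant stream per replicate.

    The model is deliberately not part of the entropy so that a
    repulsion-only sweep is bitwise identical to an all-alpha=1 sweep under
    the same master seed.
    """
    return np.random.SeedSequence(
        entropy=(
            int(master_seed),
            _CLASS_CODE[spec.orientation_class],
            int(ar_index),
            int(rep),
        )
    )


def _program(config: SimConfig, spec: ProgramSpec) -> DivisionProgram:
    return build_program(
        spec.orientation_class,
        spec.timing_mode,
        spec.volume_mode,
        config.division_timing(),
    )


def run_replicate(
    config: SimConfig,
    model: str,
    spec: ProgramSpec,
    ar: float,
    seed,
    record_stride: int = 10,
) -> tuple[EmbryoState, Trajectory, str]:
    """One seeded run at one aspect ratio; returns final state, trajectory
    and the classified pattern label."""
    cfg = _model_config(config, model)
    shell = axes_from_ar(ar, cfg.eggshell_volume)
    program = _program(cfg, spec)
    ab_fraction = 0.5 if spec.volume_mode == "equal" else cfg.ab_volume_fraction
    final, traj = run(
        shell,
        program,
        cfg.force_params(),
        duration=program.duration,
        seed=seed,
        total_cell_volume=cfg.total_cell_volume,
        ab_fraction=ab_fraction,
        record_stride=record_stride,
    )
    return final, traj, classify_pattern(contact_graph(final))


def ar_sweep(
    config: SimConfig,
    model: str,
    spec: ProgramSpec = WILD_TYPE,
    ar_min: float | None = None,
    ar_max: float | None = None,
    ar_step: float | None = None,
    n_reps: int | None = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Pattern-frequency table over an aspect-ratio grid.

    Returns one row per (model, orientation_class, AR, pattern) with columns
    ``count``, ``fraction``, ``n_reps`` and ``master_seed``; fractions per
    condition sum to 1.
    """
    ar_min = config.ar_min if ar_min is None else ar_min
    ar_max = config.ar_max if ar_max is None else ar_max
    ar_step = config.ar_step if ar_step is None else ar_step
    n_reps = config.n_reps if n_reps is None else n_reps
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    grid = ar_grid(ar_min, ar_max, ar_step)
    rows = []
    for ar_index, ar in enumerate(grid):
        counts = dict.fromkeys(PATTERN_LABELS, 0)
        for rep in range(n_reps):
            seed = _replicate_seed(master_seed, spec, ar_index, rep)
            _, _, pattern = run_replicate(config, model, spec, ar, seed)
            counts[pattern] += 1
        for pattern in PATTERN_LABELS:
            rows.append(
                {
                    "model": model,
                    "orientation_class": spec.orientation_class,
                    "ar": ar,
                    "pattern": pattern,
                    "count": counts[pattern],
                    "fraction": counts[pattern] / n_reps,
                    "n_reps": n_reps,
                    "master_seed": master_seed,
                }
            )
    return pd.DataFrame(rows)


def _ars_with_pattern(result: pd.DataFrame, pattern: str) -> list[float]:
    if result.empty:
        raise ValueError("empty sweep result")
    hit = result[(result["pattern"] == pattern) & (result["fraction"] > 0.0)]
    return sorted(hit["ar"].unique())


def first_ar_with_pattern(result: pd.DataFrame, pattern: str) -> float | None:
    """Smallest grid AR with a nonzero fraction of ``pattern`` (None if absent)."""
    ars = _ars_with_pattern(result, pattern)
    return ars[0] if ars else None


def last_ar_with_pattern(result: pd.DataFrame, pattern: str) -> float | None:
    """Largest grid AR with a nonzero fraction of ``pattern`` (None if absent)."""
    ars = _ars_with_pattern(result, pattern)
    return ars[-1] if ars else None


def write_sweep_csv(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, index=False)


def read_sweep_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = [
        "model",
        "orientation_class",
        "ar",
        "pattern",
        "count",
        "fraction",
        "n_reps",
        "master_seed",
    ]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"sweep file {path} is missing columns {missing}")
    return df
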