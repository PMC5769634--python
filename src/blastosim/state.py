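"""Core state containers: cells, embryo snapshots, trajectories."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import Eggshell, contains

__all__ = ["Cell", "EmbryoState", "Trajectory", "radius_from_volume"]


def radius_from_volume(volume: float) -> float:
    """Radius of a sphere with the given volume."""
    if volume <= 0.0:
        raise ValueError(f"volume must be positive, got {volume}")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class Cell:
    """A blastomere modelled as a soft sphere."""

    label: str
    position: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.radius <= 0.0:
            raise ValueError(f"radius must be positive, got {self.radius}")

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3

    def copy(self) -> "Cell":
        return Cell(self.label, self.position.copy(), self.radius)


@dataclass
class EmbryoState:
    """Time-stamped set of cells inside an eggshell."""

    time: float
    cells: list[Cell]
    shell: Eggshell

    def __post_init__(self) -> None:
        labels = [c.label for c in self.cells]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate cell labels: {labels}")
        for c in self.cells:
            if not contains(self.shell, c.position):
                raise ValueError(
                    f"cell {c.label} centre {c.position} is outside the shell"
                )

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cells]

    @property
    def total_cell_volume(self) -> float:
        return sum(c.volume for c in self.cells)

    def cell(self, label: str) -> Cell:
        for c in self.cells:
            if c.label == label:
                return c
        raise KeyError(f"no cell labelled {label!r}")

    def copy(self) -> "EmbryoState":
        return replace(self, cells=[c.copy() for c in self.cells])


@dataclass
class Trajectory:
    """Recorded (time, label, position, radius) samples of a run."""

    records: list[tuple[float, str, float, float, float, float]] = field(
        default_factory=list
    )

    def append_state(self, state: EmbryoState) -> None:
        for c in state.cells:
            self.records.append(
                (state.time, c.label, *(float(v) for v in c.position), c.radius)
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["time_s", "label", "x_um", "y_um", "z_um", "radius_um"],
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)
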