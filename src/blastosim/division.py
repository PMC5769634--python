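"""Division scheduling and the mother-to-daughters state transformation.

The two-cell-stage division round is parametrised by an orientation class:

* ``T-div`` (wild type): AB divides along z, P1 along x;
* ``I-div``: both divide along x;
* ``H-div``: both divide along z;
* ``C-div``: AB divides along z, P1 along y.

Timing is either ``asynchronous`` (AB before P1 by a configurable stagger)
or ``simultaneous``; volumes are split ``asymmetric`` (configured fractions)
or ``equal``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import contains
from .state import Cell, EmbryoState, radius_from_volume

__all__ = [
    "DivisionEvent",
    "DivisionProgram",
    "DivisionTiming",
    "build_program",
    "apply_division",
    "ORIENTATION_CLASSES",
]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

#: orientation class -> (AB axis, P1 axis)
ORIENTATION_CLASSES: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "T-div": (_Z, _X),
    "I-div": (_X, _X),
    "H-div": (_Z, _Z),
    "C-div": (_Z, _Y),
}

MIN_PLACEMENT_OFFSET = 0.1


@dataclass(frozen=True)
class DivisionEvent:
    mother: str
    time: float
    axis: np.ndarray
    volume_fraction_first_daughter: float
    daughter_labels: tuple[str, str]
    placement_offset: float = 2.0

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(axis)), 1.0, rel_tol=1e-9):
            raise ValueError(f"axis must be a unit vector, got {axis}")
        object.__setattr__(self, "axis", axis)
        if not (0.0 < self.volume_fraction_first_daughter < 1.0):
            raise ValueError("volume fraction must lie in (0, 1)")
        if self.placement_offset <= 0.0:
            raise ValueError("placement offset must be positive")


@dataclass(frozen=True)
class DivisionTiming:
    """Timing/volume knobs for the two-cell-stage division round."""

    t_first: float = 300.0
    stagger: float = 120.0
    ab_daughter_fraction: float = 0.5
    p1_daughter_fraction: float = 0.55
    placement_offset: float = 2.0
    settle: float = 600.0


@dataclass(frozen=True)
class DivisionProgram:
    events: tuple[DivisionEvent, ...]
    orientation_class: str = "T-div"
    timing_mode: str = "asynchronous"
    volume_mode: str = "asymmetric"
    settle: float = 600.0

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if sorted(times) != times:
            raise ValueError("events must be sorted by time")
        mothers = [e.mother for e in self.events]
        if len(set(mothers)) != len(mothers):
            raise ValueError("each mother divides at most once")
        daughters = [lab for e in self.events for lab in e.daughter_labels]
        if len(set(daughters)) != len(daughters):
            raise ValueError("daughter labels must be unique")

    @property
    def last_event_time(self) -> float:
        return max((e.time for e in self.events), default=0.0)

    @property
    def duration(self) -> float:
        """Run length covering all divisions plus the settling interval."""
        return self.last_event_time + self.settle


def build_program(
    orientation_class: str = "T-div",
    timing_mode: str = "asynchronous",
    volume_mode: str = "asymmetric",
    timing: DivisionTiming | None = None,
) -> DivisionProgram:
    """Division program for the AB and P1 divisions of the four-cell stage.

    Wild type is ``("T-div", "asynchronous", "asymmetric")``: AB divides
    along z before P1 divides along x.  EMS is placed on the anterior (-x)
    side of P1 and receives ``p1_daughter_fraction`` of its volume; the
    provisional ABa daughter sits at +z (AB daughters are interchangeable
    for classification).
    """
    if orientation_class not in ORIENTATION_CLASSES:
        raise ValueError(
            f"unknown orientation class {orientation_class!r}; "
            f"expected one of {sorted(ORIENTATION_CLASSES)}"
        )
    if timing_mode not in ("asynchronous", "simultaneous"):
        raise ValueError(f"unknown timing mode {timing_mode!r}")
    if volume_mode not in ("asymmetric", "equal"):
        raise ValueError(f"unknown volume mode {volume_mode!r}")
    timing = timing or DivisionTiming()

    ab_axis, p1_axis = ORIENTATION_CLASSES[orientation_class]
    t_ab = timing.t_first
    t_p1 = t_ab if timing_mode == "simultaneous" else t_ab + timing.stagger
    ab_frac = 0.5 if volume_mode == "equal" else timing.ab_daughter_fraction
    p1_frac = 0.5 if volume_mode == "equal" else timing.p1_daughter_fraction

    # first daughter is placed on the -axis side, so ABa (second) sits at +z
    ab_event = DivisionEvent(
        mother="AB",
        time=t_ab,
        axis=ab_axis,
        volume_fraction_first_daughter=ab_frac,
        daughter_labels=("ABp", "ABa"),
        placement_offset=timing.placement_offset,
    )
    # first P1 daughter (EMS) is placed on the -axis side: anterior for the
    # wild-type x-oriented division.
    p1_event = DivisionEvent(
        mother="P1",
        time=t_p1,
        axis=p1_axis,
        volume_fraction_first_daughter=p1_frac,
        daughter_labels=("EMS", "P2"),
        placement_offset=timing.placement_offset,
    )
    events = sorted((ab_event, p1_event), key=lambda e: e.time)
    return DivisionProgram(
        events=tuple(events),
        orientation_class=orientation_class,
        timing_mode=timing_mode,
        volume_mode=volume_mode,
        settle=timing.settle,
    )


def _daughter_positions(
    state: EmbryoState, centre: np.ndarray, axis: np.ndarray, offset: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Place daughters at centre +/- (offset/2)*axis, shrinking the offset
    (never below MIN_PLACEMENT_OFFSET) until both centres are interior."""
    off = offset
    while off >= MIN_PLACEMENT_OFFSET:
        p_plus = centre + 0.5 * off * axis
        p_minus = centre - 0.5 * off * axis
        if contains(state.shell, p_plus) and contains(state.shell, p_minus):
            return p_plus, p_minus, off
        off *= 0.5
    raise ValueError(
        "cannot place daughters inside the shell even at the minimum offset"
    )


def apply_division(state: EmbryoState, event: DivisionEvent) -> EmbryoState:
    """Replace the mother cell with its two daughters.

    Daughter 1 (``daughter_labels[0]``) receives
    ``volume_fraction_first_daughter`` of the mother volume and is placed on
    the -axis side; total cell volume is conserved exactly.
    """
    mother = state.cell(event.mother)  # KeyError if absent
    v1 = event.volume_fraction_first_daughter * mother.volume
    v2 = mother.volume - v1
    p_plus, p_minus, _ = _daughter_positions(
        state, mother.position, event.axis, event.placement_offset
    )
    d1 = Cell(event.daughter_labels[0], p_minus, radius_from_volume(v1))
    d2 = Cell(event.daughter_labels[1], p_plus, radius_from_volume(v2))
    cells = [c.copy() for c in state.cells if c.label != event.mother]
    cells.extend([d1, d2])
    return replace(state, cells=cells)
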