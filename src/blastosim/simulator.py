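"""Overdamped Langevin integration of cell centres with division events.

Positions advance by explicit Euler-Maruyama steps,

    r_i(t + dt) = r_i(t) + F_i(t) * dt + xi,

where the mobility is unity (forces are velocities, um/s) and each component
of ``xi`` is an independent Gaussian displacement with mean 0 and the
configured per-step variance.  Centres that would leave the rigid shell are
projected back to 99% of the boundary coordinate along the ray from the
shell centre.
"""

from __future__ import annotations

import math

import numpy as np

from .division import DivisionProgram, apply_division
from .geometry import Eggshell, contains
from .mechanics import ForceParams, net_forces
from .state import Cell, EmbryoState, Trajectory, radius_from_volume

__all__ = [
    "Cell",
    "EmbryoState",
    "Trajectory",
    "initial_two_cell_state",
    "step",
    "run",
]

INITIAL_SEPARATION = 2.0  # um, centre-to-centre on the x-axis
_CLAMP_LEVEL = 0.99


def initial_two_cell_state(
    shell: Eggshell,
    total_cell_volume: float,
    ab_fraction: float = 0.55,
) -> EmbryoState:
    """Two-cell starting configuration: AB and P1 2.0 um apart on the x-axis.

    AB (anterior, -x) gets ``ab_fraction`` of the total embryo volume.
    """
    if not (0.0 < ab_fraction < 1.0):
        raise ValueError(f"ab_fraction must lie in (0, 1), got {ab_fraction}")
    half = INITIAL_SEPARATION / 2.0
    ab = Cell("AB", np.array([-half, 0.0, 0.0]), radius_from_volume(ab_fraction * total_cell_volume))
    p1 = Cell("P1", np.array([half, 0.0, 0.0]), radius_from_volume((1.0 - ab_fraction) * total_cell_volume))
    for c in (ab, p1):
        if not contains(shell, c.position):
            raise ValueError("shell too small for the initial configuration")
    return EmbryoState(time=0.0, cells=[ab, p1], shell=shell)


def _clamp_inside(shell: Eggshell, pos: np.ndarray) -> np.ndarray:
    """Project a centre back inside the shell (rigid-wall constraint)."""
    x, y, z = pos
    m2 = x * x / shell.lx**2 + (y * y + z * z) / shell.ly**2
    if m2 < 1.0:
        return pos
    return pos * (_CLAMP_LEVEL / math.sqrt(m2))


def step(
    state: EmbryoState, params: ForceParams, rng: np.random.Generator
) -> EmbryoState:
    """Advance all cell centres by one Euler-Maruyama step of length dt."""
    forces = net_forces(state, params)
    sigma = math.sqrt(params.noise_variance)
    new_cells = []
    for cell, force in zip(state.cells, forces):
        pos = cell.position + force * params.dt
        if sigma > 0.0:
            pos = pos + rng.normal(0.0, sigma, size=3)
        pos = _clamp_inside(state.shell, pos)
        new_cells.append(Cell(cell.label, pos, cell.radius))
    return EmbryoState(time=state.time + params.dt, cells=new_cells, shell=state.shell)


def run(
    shell: Eggshell,
    program: DivisionProgram,
    params: ForceParams,
    duration: float,
    seed,
    *,
    total_cell_volume: float,
    ab_fraction: float = 0.55,
    record_stride: int = 1,
) -> tuple[EmbryoState, Trajectory]:
    """Integrate from the two-cell configuration through the division program.

    ``seed`` may be an int, a ``numpy.random.SeedSequence`` or a
    ``numpy.random.Generator``; identical seeds and configurations yield
    bit-identical trajectories.  Division events fire between integration
    steps once the clock passes their scheduled time.
    """
    if duration < program.last_event_time:
        raise ValueError(
            f"duration {duration} s does not cover the last division at "
            f"{program.last_event_time} s"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.Generator(np.random.PCG64(seed))
    )
    state = initial_two_cell_state(shell, total_cell_volume, ab_fraction)
    pending = list(program.events)
    traj = Trajectory()
    traj.append_state(state)
    n_steps = int(round(duration / params.dt))
    for k in range(n_steps):
        while pending and pending[0].time <= state.time:
            state = apply_division(state, pending[0])
            pending.pop(0)
        state = step(state, params, rng)
        if (k + 1) % record_stride == 0 or k == n_steps - 1:
            traj.append_state(state)
    while pending and pending[0].time <= state.time:
        state = apply_division(state, pending.pop(0))
        traj.append_state(state)
    return state, traj
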