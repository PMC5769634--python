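"""Pairwise cell-cell and cell-eggshell forces.

Force conventions: all "forces" are overdamped velocities (mobility is unity,
so micrometres per second).  The signed pairwise magnitude ``f(d)`` is
positive for repulsion and negative for attraction; the force on cell *i* is
``-f(d) * e_ij`` with ``e_ij`` the unit vector from *i* to *j*.

The piecewise law, for radii ``Ri, Rj`` and stable-repulsion ratio
``alpha`` (``m = min(Ri,Rj)``, ``s = Ri+Rj``, ``z = alpha*s``,
``c = 0.5*(1+alpha)*s``):

* ``0 < d <= m``  : constant ``F0`` (cytokinetic elongation at constant
  velocity);
* ``m < d <= c``  : linear, from ``F0`` at ``m`` through zero at ``z``;
* ``c < d <= s``  : linear back to zero at contact loss ``s``;
* ``d > s``       : zero.

With ``alpha = 1`` the attraction window ``(z, s]`` is empty and the law is
repulsion-only.  The shell response is linear in the overlap:
``shell_gain * (R - a) / R`` along the inward normal for ``a <= R``, zero
otherwise, with ``a`` the centre-to-shell minimum distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Eggshell, min_shell_distance, shell_inward_normal

__all__ = [
    "ForceParams",
    "pair_force_magnitude",
    "pairwise_force",
    "shell_force",
    "net_forces",
]

_ZERO3 = np.zeros(3)


@dataclass(frozen=True)
class ForceParams:
    """Force-law and integration parameters.

    ``alpha_table`` maps unordered lineage-label pairs to alpha values;
    lookups fall back to ``default_alpha``.
    """

    F0: float = 0.2
    default_alpha: float = 0.75
    alpha_table: dict[frozenset[str], float] = field(default_factory=dict)
    shell_gain: float = 0.5
    noise_variance: float = 0.027
    dt: float = 5.0

    def __post_init__(self) -> None:
        if self.F0 <= 0.0:
            raise ValueError(f"F0 must be positive, got {self.F0}")
        if self.shell_gain <= 0.0:
            raise ValueError(f"shell_gain must be positive, got {self.shell_gain}")
        if self.noise_variance < 0.0:
            raise ValueError(f"noise_variance must be >= 0, got {self.noise_variance}")
        if self.dt <= 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        for alpha in list(self.alpha_table.values()) + [self.default_alpha]:
            if not (0.0 < alpha <= 1.0):
                raise ValueError(f"alpha must be in (0, 1], got {alpha}")

    def alpha_for(self, label_i: str, label_j: str) -> float:
        return self.alpha_table.get(frozenset((label_i, label_j)), self.default_alpha)

    def with_all_alpha(self, alpha: float) -> "ForceParams":
        """Copy with a uniform alpha (alpha=1 gives the repulsion-only law)."""
        return ForceParams(
            F0=self.F0,
            default_alpha=alpha,
            alpha_table={},
            shell_gain=self.shell_gain,
            noise_variance=self.noise_variance,
            dt=self.dt,
        )


def pair_force_magnitude(
    d: float, R_i: float, R_j: float, alpha: float, F0: float
) -> float:
    """Signed magnitude of the pairwise law (positive = repulsive)."""
    if d <= 0.0:
        raise ValueError("cell centres coincide")
    m = min(R_i, R_j)
    s = R_i + R_j
    z = alpha * s
    if z <= m:
        raise ValueError(
            f"alpha*(Ri+Rj)={z} must exceed min(Ri,Rj)={m} for the piecewise law"
        )
    if d <= m:
        return F0
    c = 0.5 * (1.0 + alpha) * s
    if d <= c:
        return F0 * (z - d) / (z - m)
    if d <= s:
        f_c = F0 * (z - c) / (z - m)
        return f_c * (s - d) / (s - c)
    return 0.0


def pairwise_force(
    pos_i: np.ndarray,
    R_i: float,
    pos_j: np.ndarray,
    R_j: float,
    alpha: float,
    F0: float,
) -> np.ndarray:
    """Force on cell *i* from cell *j*."""
    dvec = np.asarray(pos_j, float) - np.asarray(pos_i, float)
    d = float(np.linalg.norm(dvec))
    if d == 0.0:
        raise ValueError("cell centres coincide")
    if d > R_i + R_j:
        return _ZERO3.copy()
    f = pair_force_magnitude(d, R_i, R_j, alpha, F0)
    return (-f / d) * dvec


def shell_force(
    shell: Eggshell, pos: np.ndarray, R: float, params: ForceParams
) -> np.ndarray:
    """Repulsive force of the rigid shell on a cell of radius ``R``."""
    a = min_shell_distance(shell, pos)
    if a >= R:
        return _ZERO3.copy()
    e = shell_inward_normal(shell, pos)
    return params.shell_gain * (R - a) / R * e


def net_forces(state, params: ForceParams) -> np.ndarray:
    """Net force on every cell of ``state`` (pairwise + shell), shape (N, 3)."""
    cells = state.cells
    n = len(cells)
    forces = np.zeros((n, 3))
    for i in range(n):
        ci = cells[i]
        for j in range(i + 1, n):
            cj = cells[j]
            fij = pairwise_force(
                ci.position,
                ci.radius,
                cj.position,
                cj.radius,
                params.alpha_for(ci.label, cj.label),
                params.F0,
            )
            forces[i] += fij
            forces[j] -= fij
        forces[i] += shell_force(state.shell, ci.position, ci.radius, params)
    return forces
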