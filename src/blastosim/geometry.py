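"""Rigid ellipsoidal eggshell geometry.

The eggshell is an ellipsoid of revolution about the x (anterior-posterior)
axis, centred at the origin, with semi-axes ``lx >= ly = lz``.  All lengths
are in micrometres.

The central primitive is the minimum distance from an interior point to the
shell surface, obtained from the perpendicular-foot condition: the nearest
surface point ``s`` satisfies ``p - s = lam * n(s)`` with ``n`` the outward
normal direction ``(s_x/lx^2, s_y/ly^2, s_z/lz^2)``.  Using the axial
symmetry this reduces to a one-dimensional root problem in the Lagrange
parameter ``lam``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Eggshell",
    "axes_from_ar",
    "contains",
    "min_shell_distance",
    "shell_inward_normal",
    "nearest_surface_point",
]


@dataclass(frozen=True)
class Eggshell:
    """Ellipsoid of revolution: semi-axes ``lx`` (long, x) and ``ly = lz``."""

    lx: float
    ly: float

    def __post_init__(self) -> None:
        if not (self.ly > 0.0 and self.lx >= self.ly):
            raise ValueError(
                f"require lx >= ly > 0, got lx={self.lx}, ly={self.ly}"
            )

    @property
    def lz(self) -> float:
        return self.ly

    @property
    def aspect_ratio(self) -> float:
        return self.lx / self.ly

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.lx * self.ly * self.ly


def axes_from_ar(ar: float, volume: float) -> Eggshell:
    """Build the shell with aspect ratio ``ar`` and the given volume.

    Solves ``lx/ly = ar`` and ``(4/3) pi lx ly^2 = volume``, so
    ``ly = (3 V / (4 pi ar))^(1/3)``.
    """
    if ar < 1.0:
        raise ValueError(f"aspect ratio must be >= 1, got {ar}")
    if volume <= 0.0:
        raise ValueError(f"volume must be positive, got {volume}")
    ly = (3.0 * volume / (4.0 * math.pi * ar)) ** (1.0 / 3.0)
    return Eggshell(lx=ar * ly, ly=ly)


def contains(shell: Eggshell, point: np.ndarray) -> bool:
    """True iff ``point`` is strictly inside the shell."""
    x, y, z = np.asarray(point, dtype=float)
    return bool(x * x / (shell.lx**2) + (y * y + z * z) / (shell.ly**2) < 1.0)


def _foot_2d(shell: Eggshell, x: float, rho: float) -> tuple[float, float]:
    """Nearest point on the meridian ellipse to interior point ``(x, rho)``.

    Returns the foot point ``(sx, srho)`` with ``srho >= 0``.  ``rho`` is the
    cylindrical radius ``sqrt(y^2 + z^2) >= 0``.
    """
    A = shell.lx**2
    B = shell.ly**2
    S = x * x
    T = rho * rho

    # Cylindrical radii far below float resolution of B are treated as
    # on-axis: the root bracket in lam collapses below eps(B) there, and the
    # induced distance error is O(rho), well under solver tolerance.
    if rho > 1e-8 * shell.ly:
        # F(lam) = S*A/(A+lam)^2 + T*B/(B+lam)^2 - 1 is strictly decreasing
        # on (-B, inf); interior point => unique root in (-B, 0).
        def F(lam: float) -> float:
            return S * A / (A + lam) ** 2 + T * B / (B + lam) ** 2 - 1.0

        lo = -B / 2.0
        # expand toward -B until the bracket sign flips
        for _ in range(200):
            if F(lo) > 0.0:
                break
            lo = -B + (lo + B) / 2.0
        else:  # pragma: no cover - interior precondition violated
            raise ValueError("failed to bracket foot-point root")
        lam = brentq(F, lo, 0.0, xtol=1e-13, rtol=1e-15)
        return A * x / (A + lam), B * rho / (B + lam)

    # On-axis point: candidates are the near pole and (for prolate shells
    # with |x| below the evolute threshold) a ring of equatorial feet.
    pole_x = math.copysign(shell.lx, x) if x != 0.0 else shell.lx
    best = (pole_x, 0.0)
    best_d2 = (shell.lx - abs(x)) ** 2
    if A > B:
        sx = A * x / (A - B)
        if sx * sx < A:
            srho = math.sqrt(B * (1.0 - sx * sx / A))
            d2 = (x - sx) ** 2 + srho * srho
            if d2 < best_d2:
                best = (sx, srho)
    return best


def nearest_surface_point(shell: Eggshell, point: np.ndarray) -> np.ndarray:
    """Nearest point on the shell surface to an interior ``point``."""
    p = np.asarray(point, dtype=float)
    if not contains(shell, p):
        raise ValueError(f"point {p} is not strictly inside the shell")
    x = float(p[0])
    rho = math.hypot(float(p[1]), float(p[2]))
    sx, srho = _foot_2d(shell, x, rho)
    if rho > 0.0:
        u = p[1:] / rho
    else:
        u = np.array([1.0, 0.0])  # azimuth undefined on axis; fixed choice
    return np.array([sx, srho * u[0], srho * u[1]])


def min_shell_distance(shell: Eggshell, point: np.ndarray) -> float:
    """Minimum distance from an interior point to the shell surface."""
    p = np.asarray(point, dtype=float)
    s = nearest_surface_point(shell, p)
    return float(np.linalg.norm(p - s))


def shell_inward_normal(shell: Eggshell, point: np.ndarray) -> np.ndarray:
    """Unit vector from the nearest surface point toward the interior point.

    At the exact centre of a spherical shell the direction is undefined; a
    fixed +x sentinel is returned (measure-zero state, broken by noise).
    """
    p = np.asarray(point, dtype=float)
    if shell.lx == shell.ly and float(np.linalg.norm(p)) == 0.0:
        return np.array([1.0, 0.0, 0.0])
    s = nearest_surface_point(shell, p)
    v = p - s
    return v / np.linalg.norm(v)
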