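"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the surface-distance
oracle minimises over a dense surface parametrisation instead of solving the
perpendicular-foot root problem, and the pattern oracle evaluates the verbal
contact definitions predicate by predicate instead of template matching.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize_scalar


def brute_force_shell_distance(lx: float, ly: float, point, n_grid: int = 200_001) -> float:
    """Min distance from an interior point to the ellipsoid of revolution,
    by dense sampling of the meridian ellipse plus bounded refinement."""
    x, y, z = np.asarray(point, dtype=float)
    rho = float(np.hypot(y, z))
    theta = np.linspace(0.0, np.pi, n_grid)
    d2 = (lx * np.cos(theta) - x) ** 2 + (ly * np.sin(theta) - rho) ** 2
    i = int(np.argmin(d2))
    lo = theta[max(i - 2, 0)]
    hi = theta[min(i + 2, n_grid - 1)]

    def f(t: float) -> float:
        return (lx * np.cos(t) - x) ** 2 + (ly * np.sin(t) - rho) ** 2

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-14})
    return float(np.sqrt(min(res.fun, d2[i])))


def brute_force_shell_foot(lx: float, ly: float, point, n_grid: int = 200_001):
    """Nearest surface point (3-vector) by the same dense parametrisation."""
    x, y, z = np.asarray(point, dtype=float)
    rho = float(np.hypot(y, z))
    theta = np.linspace(0.0, np.pi, n_grid)
    d2 = (lx * np.cos(theta) - x) ** 2 + (ly * np.sin(theta) - rho) ** 2
    i = int(np.argmin(d2))

    def f(t: float) -> float:
        return (lx * np.cos(t) - x) ** 2 + (ly * np.sin(t) - rho) ** 2

    res = minimize_scalar(
        f,
        bounds=(theta[max(i - 2, 0)], theta[min(i + 2, n_grid - 1)]),
        method="bounded",
        options={"xatol": 1e-14},
    )
    t = float(res.x)
    srho = ly * np.sin(t)
    u = np.array([y, z]) / rho if rho > 0 else np.array([1.0, 0.0])
    return np.array([lx * np.cos(t), srho * u[0], srho * u[1]])


LABELS = ("ABa", "ABp", "EMS", "P2")
ALL_PAIRS = tuple(itertools.combinations(LABELS, 2))


def has(edges, a, b) -> bool:
    return frozenset((a, b)) in edges


def oracle_classify(edges: frozenset) -> str:
    """Predicate-by-predicate arrangement classification (AB daughters
    interchangeable), written directly from the contact definitions."""
    for abx, aby in (("ABa", "ABp"), ("ABp", "ABa")):
        sister = has(edges, abx, aby)
        if len(edges) == 6:
            return "pyramid"
        if (
            len(edges) == 5
            and sister
            and has(edges, abx, "EMS")
            and has(edges, aby, "EMS")
            and has(edges, "EMS", "P2")
            and has(edges, aby, "P2")
            and not has(edges, abx, "P2")
        ):
            return "diamond"
        if (
            len(edges) == 4
            and sister
            and has(edges, abx, "EMS")
            and has(edges, aby, "EMS")
            and has(edges, "EMS", "P2")
        ):
            return "T_shaped"
        if (
            len(edges) == 3
            and sister
            and has(edges, aby, "EMS")
            and has(edges, "EMS", "P2")
        ):
            return "linear"
        if (
            len(edges) == 4
            and sister
            and has(edges, aby, "EMS")
            and has(edges, aby, "P2")
            and has(edges, "EMS", "P2")
        ):
            return "T_reverse"
    degrees = {lab: sum(1 for e in edges if lab in e) for lab in LABELS}
    if len(edges) == 4 and all(d == 2 for d in degrees.values()):
        return "H_shaped"
    return "other"


def all_contact_graphs():
    """All 64 contact graphs over the four labels, as edge frozensets."""
    for mask in range(64):
        yield frozenset(
            frozenset(pair) for k, pair in enumerate(ALL_PAIRS) if mask >> k & 1
        )
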