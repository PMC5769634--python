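"""Contact-graph construction and four-cell arrangement classification.

Two cells are in contact iff their centre distance is strictly smaller than
the sum of their radii.  The arrangement label is determined by the contact
graph over {ABa, ABp, EMS, P2}, up to swapping the two (interchangeable) AB
daughters:

* ``pyramid``   — all six pairs in contact;
* ``diamond``   — all contacts except one AB-daughter--P2 pair;
* ``T_shaped``  — diamond additionally missing the other ABd--P2 contact;
* ``linear``    — chain ABd--ABd--EMS--P2;
* ``T_reverse`` — one ABd contacts EMS and P2, the other only its sister;
* ``H_shaped``  — a four-cycle: every cell touches exactly two neighbours;
* ``other``     — anything else.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .state import Cell, EmbryoState

__all__ = [
    "FOUR_CELL_LABELS",
    "PATTERN_LABELS",
    "contact_graph",
    "classify_pattern",
    "stable_repulsion_ratio",
    "read_cells_csv",
]

FOUR_CELL_LABELS = frozenset({"ABa", "ABp", "EMS", "P2"})
PATTERN_LABELS = (
    "pyramid",
    "diamond",
    "T_shaped",
    "linear",
    "T_reverse",
    "H_shaped",
    "other",
)


def contact_graph(state: EmbryoState) -> nx.Graph:
    """Contact graph of a four-cell state (edge iff d_ij < R_i + R_j)."""
    if len(state.cells) != 4:
        raise ValueError(f"expected exactly 4 cells, got {len(state.cells)}")
    g = nx.Graph()
    g.add_nodes_from(c.label for c in state.cells)
    cells = state.cells
    for i in range(4):
        for j in range(i + 1, 4):
            d = float(np.linalg.norm(cells[i].position - cells[j].position))
            if d < cells[i].radius + cells[j].radius:
                g.add_edge(cells[i].label, cells[j].label)
    return g


def _e(a: str, b: str) -> frozenset[str]:
    return frozenset((a, b))


_ALL_EDGES = frozenset(
    _e(a, b)
    for i, a in enumerate(sorted(FOUR_CELL_LABELS))
    for b in sorted(FOUR_CELL_LABELS)[i + 1 :]
)

# reference edge sets; matching is attempted with ABa/ABp swapped as well
_TEMPLATES: dict[str, frozenset[frozenset[str]]] = {
    "pyramid": _ALL_EDGES,
    "diamond": _ALL_EDGES - {_e("ABa", "P2")},
    "T_shaped": _ALL_EDGES - {_e("ABa", "P2"), _e("ABp", "P2")},
    "linear": frozenset({_e("ABa", "ABp"), _e("ABp", "EMS"), _e("EMS", "P2")}),
    "T_reverse": frozenset(
        {_e("ABa", "ABp"), _e("ABp", "EMS"), _e("ABp", "P2"), _e("EMS", "P2")}
    ),
}


def _swap_abd(edges: frozenset[frozenset[str]]) -> frozenset[frozenset[str]]:
    sw = {"ABa": "ABp", "ABp": "ABa"}
    return frozenset(frozenset(sw.get(v, v) for v in edge) for edge in edges)


def classify_pattern(graph: nx.Graph) -> str:
    """Arrangement label for a four-cell contact graph."""
    if set(graph.nodes) != set(FOUR_CELL_LABELS):
        raise ValueError(
            f"graph must cover labels {sorted(FOUR_CELL_LABELS)}, "
            f"got {sorted(graph.nodes)}"
        )
    edges = frozenset(_e(a, b) for a, b in graph.edges)
    for name, template in _TEMPLATES.items():
        if edges == template or edges == _swap_abd(template):
            return name
    if len(edges) == 4 and all(deg == 2 for _, deg in graph.degree):
        return "H_shaped"
    return "other"


def stable_repulsion_ratio(d_ij: float, R_i: float, R_j: float) -> float:
    """Equilibrium separation ratio alpha = d_ij / (R_i + R_j).

    Equals 1.0 for two cells that barely touch (pure repulsion limit) and
    falls below 1 with net adhesion.
    """
    if d_ij <= 0.0 or R_i <= 0.0 or R_j <= 0.0:
        raise ValueError("all inputs must be positive")
    return d_ij / (R_i + R_j)


def read_cells_csv(path: str | Path) -> list[Cell]:
    """Read a fixture table of cells (columns: label, x, y, z, radius)."""
    df = pd.read_csv(path)
    required = ["label", "x", "y", "z", "radius"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"fixture file {path} is missing columns {missing}")
    return [
        Cell(str(r.label), np.array([r.x, r.y, r.z], dtype=float), float(r.radius))
        for r in df.itertuples()
    ]
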