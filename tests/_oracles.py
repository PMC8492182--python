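"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the move set is
written out by hand, shortest paths come from Bellman–Ford edge
relaxation, front propagation from a breadth-first ring expansion, and
logistic growth from direct numerical ODE integration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp

# 8 queen steps + 8 knight steps, written out by hand
HAND_MOVES = [
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
    (-2, -1), (-2, 1), (-1, -2), (-1, 2), (1, -2), (1, 2), (2, -1), (2, 1),
]


def bellman_ford_distances(
    friction: np.ndarray, cell_size: float, origin: tuple[int, int]
) -> np.ndarray:
    """Brute-force shortest paths over the 16-move graph by edge relaxation.

    ``friction`` uses NaN for impassable cells; edge weight is the
    Euclidean centre-to-centre length times the mean endpoint friction.
    """
    n_rows, n_cols = friction.shape
    passable = ~np.isnan(friction)
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            if not passable[r, c]:
                continue
            for dr, dc in HAND_MOVES:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and passable[rr, cc]:
                    w = (
                        cell_size
                        * math.hypot(dr, dc)
                        * 0.5
                        * (friction[r, c] + friction[rr, cc])
                    )
                    edges.append(((r, c), (rr, cc), w))
    dist = np.full(friction.shape, np.inf)
    dist[origin] = 0.0
    for _ in range(int(passable.sum())):
        changed = False
        for (u, v, w) in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    return dist


def ring_expansion_arrival(
    suitable: np.ndarray,
    origin: tuple[int, int],
    start: float,
    end: float,
    tau: float,
) -> np.ndarray:
    """Breadth-first one-cell-per-generation front over a static mask.

    Models the exact-arithmetic consequence of "every inhabited cell emits
    to all 8 suitable neighbours each generation".
    """
    arrival = np.full(suitable.shape, np.nan)
    arrival[origin] = start
    frontier = {origin}
    date = start
    n_rows, n_cols = suitable.shape
    while frontier and date - tau >= end:
        date -= tau
        nxt = set()
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (
                        0 <= rr < n_rows
                        and 0 <= cc < n_cols
                        and suitable[rr, cc]
                        and np.isnan(arrival[rr, cc])
                    ):
                        arrival[rr, cc] = date
                        nxt.add((rr, cc))
        frontier = nxt
    return arrival


def logistic_ode_population(
    n0: float, k: float, a: float, tau: float
) -> float:
    """Integrate dN/dt = a N (1 - N/K) over tau years numerically."""
    sol = solve_ivp(
        lambda _, n: a * n * (1.0 - n / k),
        (0.0, tau),
        [n0],
        rtol=1e-10,
        atol=1e-12,
        dense_output=False,
    )
    return float(sol.y[0, -1])
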