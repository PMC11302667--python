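"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: closed forms typed
in from hand algebra, and brute-force enumeration at tiny sizes.
"""

from __future__ import annotations

import numpy as np


def p3_resolvent_closed_form(gamma: float) -> np.ndarray:
    """Resolvent of the 3-node undirected path, from the hand-derived
    closed form (prefactor 1/(1 - 2*gamma**2)):

        [[1-g^2, g,   g^2 ],
         [g,     1,   g   ],
         [g^2,   g,   1-g^2]] / (1 - 2 g^2)
    """
    g = gamma
    pre = 1.0 / (1.0 - 2.0 * g * g)
    return pre * np.array(
        [
            [1 - g * g, g, g * g],
            [g, 1.0, g],
            [g * g, g, 1 - g * g],
        ]
    )


def brute_force_path_counts(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive shortest-path distances and multiplicities for tiny
    unweighted graphs, by recursive enumeration of all simple paths.

    ``weights[i, j]`` finite means an edge j -> i.  Returns (D, S) with
    D[i, j] = distance j -> i and S[i, j] = number of distinct shortest
    paths j -> i (S[i, i] = 1, the empty walk).
    """
    n = weights.shape[0]
    succ = [list(np.flatnonzero(np.isfinite(weights[:, j]))) for j in range(n)]
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n), dtype=object)
    for src in range(n):
        paths_to: dict[int, list[int]] = {v: [] for v in range(n)}  # lengths of simple paths src -> v

        def walk(v: int, used: set, length: int) -> None:
            paths_to[v].append(length)
            for u in succ[v]:
                if u not in used:
                    walk(u, used | {u}, length + 1)

        walk(src, {src}, 0)
        for v in range(n):
            if paths_to[v]:
                d = min(paths_to[v])
                D[v, src] = d
                S[v, src] = sum(1 for x in paths_to[v] if x == d)
    return D, S


def brute_force_walk_counts(weights: np.ndarray, kmax: int) -> list[np.ndarray]:
    """k-step walk counts by explicit enumeration of all walks (not via
    matrix powers), for tiny graphs; element [k][i, j] counts walks
    j -> i of exactly k steps."""
    n = weights.shape[0]
    succ = [list(np.flatnonzero(np.isfinite(weights[:, j]))) for j in range(n)]
    counts = [np.zeros((n, n), dtype=object) for _ in range(kmax + 1)]
    for src in range(n):
        frontier = {src: 1}
        counts[0][src, src] = 1
        for k in range(1, kmax + 1):
            nxt: dict[int, int] = {}
            for v, c in frontier.items():
                for u in succ[v]:
                    nxt[u] = nxt.get(u, 0) + c
            for u, c in nxt.items():
                counts[k][u, src] = c
            frontier = nxt
    return counts
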