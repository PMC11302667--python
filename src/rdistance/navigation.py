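"""Greedy descent on the R-distance.

From the current node, move to the out-neighbor with the smallest
R-distance to the goal.  Because ``R = log_gamma Y`` with base below 1,
minimizing R over the successors is the same as maximizing the resolvent
entry Y[goal, j]; comparisons here use Y directly, which avoids
log-of-underflow artifacts while inducing the identical ordering.

Guarantee: when ``gamma < 1/Delta`` (Delta the max out-degree), every node
other than the goal has a successor with a strictly larger Y[goal, .], so
greedy descent reaches the goal without revisiting a node — though not
necessarily along a shortest path, except on trees where the cycle-free
path is unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import RDistanceResult
from .errors import NavigationError
from .graphs import DistanceMatrix, Graph

__all__ = ["GreedyTrace", "greedy_step", "greedy_path", "local_correctness", "local_counts"]


@dataclass
class GreedyTrace:
    start: int
    goal: int
    visited: list[int]
    reached: bool
    steps: int
    stuck_reason: str | None = None  # cycle_detected | no_finite_successor | step_limit


def greedy_step(g: Graph, res: RDistanceResult, current: int, goal: int) -> int:
    """One greedy move: the out-neighbor of ``current`` maximizing
    Y[goal, j] (equivalently minimizing R[goal, j]); ties break to the
    smallest node id."""
    if current == goal:
        raise ValueError("already at the goal")
    nbrs = g.successors(current)
    if nbrs.size == 0:
        raise NavigationError(f"node {current} has no out-neighbors")
    scores = res.Y[goal, nbrs]
    if np.all(scores <= 0.0):
        raise NavigationError(
            f"goal {goal} unreachable from every successor of {current} "
            "(all resolvent entries vanish)"
        )
    return int(nbrs[int(np.argmax(scores))])  # argmax returns first max = smallest id


def greedy_path(
    g: Graph, res: RDistanceResult, start: int, goal: int, step_limit: int | None = None
) -> GreedyTrace:
    """Iterate greedy steps until the goal, a revisit, or the step limit.

    A revisited node means the descent entered a cycle, which can only
    happen at gains >= 1/Delta; below that the trace provably reaches the
    goal."""
    if step_limit is None:
        step_limit = g.n
    if step_limit < 1:
        raise ValueError("step_limit must be >= 1")
    visited = [start]
    seen = {start}
    current = start
    while current != goal:
        if len(visited) - 1 >= step_limit:
            return GreedyTrace(start, goal, visited, False, len(visited) - 1, "step_limit")
        try:
            nxt = greedy_step(g, res, current, goal)
        except NavigationError:
            return GreedyTrace(start, goal, visited, False, len(visited) - 1, "no_finite_successor")
        visited.append(nxt)
        if nxt in seen:
            return GreedyTrace(start, goal, visited, False, len(visited) - 1, "cycle_detected")
        seen.add(nxt)
        current = nxt
    return GreedyTrace(start, goal, visited, True, len(visited) - 1, None)


def local_counts(
    g: Graph, res: RDistanceResult, oracle: DistanceMatrix, rtol: float = 1e-9
) -> tuple[int, int]:
    """Count correct greedy successor choices over ordered (start, goal)
    pairs with start != goal and a finite oracle distance.

    The greedy choice j* is correct iff it agrees with the same rule run on
    the exact distances, i.e. ``D[goal, j*] == min_j D[goal, j]`` over the
    successors (relative tolerance ``rtol`` for real-weighted graphs, where
    exact ties have measure zero).  On unweighted graphs this is equivalent
    to j* lying on a shortest path, since the minimizing successor always
    sits at distance ``D[goal, start] - 1``.
    """
    d = oracle.D
    n = g.n
    correct = 0
    total = 0
    for start in range(n):
        nbrs = g.successors(start)
        goals = np.flatnonzero(np.isfinite(d[:, start]))
        goals = goals[goals != start]
        total += goals.size
        if nbrs.size == 0 or goals.size == 0:
            continue
        chosen = nbrs[np.argmax(res.Y[goals][:, nbrs], axis=1)]
        best = d[goals][:, nbrs].min(axis=1)
        got = d[goals, chosen]
        ok = (got == best) | np.isclose(got, best, rtol=rtol, atol=0.0)
        correct += int(ok.sum())
    return correct, total


def local_correctness(
    g: Graph, res: RDistanceResult, oracle: DistanceMatrix, rtol: float = 1e-9
) -> float:
    """Fraction of (start, goal) pairs whose greedy choice is optimal;
    pairs with start == goal or an unreachable goal are excluded."""
    c, t = local_counts(g, res, oracle, rtol=rtol)
    return c / t if t else 1.0
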