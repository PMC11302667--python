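"""Gain regimes for the R-distance: when is rounding the resolvent exact?

The useful window for the gain gamma is bracketed by several quantities:

* critical gain ``gamma_c = 1 / rho(A)`` — above it the resolvent series
  diverges and Y stops representing walk counts (necessary);
* redundant-path bound ``1 / max_ij S_ij`` — shortest-path multiplicity
  inflates Y_ij by S_ij, so global correctness *requires* gamma below the
  reciprocal of the largest multiplicity (necessary);
* sufficient bound ``1 / (Delta + Delta**(d-1))`` in the out-degree Delta
  and diameter d — below it the geometric tail of longer walks cannot spill
  a rounded distance across an integer (sufficient, any directed graph);
* tree bound ``(-1 + sqrt(1 + 4*Delta*(d+2))) / (2*Delta*(d+2))`` —
  undirected trees have no redundant paths, and admit this much more
  generous sufficient bound, O(1/sqrt(Delta*d)) instead of O(Delta**-(d-1));
* precision floor ``delta**(1/d)`` — the smallest representable number
  delta must not swallow gamma**d, the resolvent entry of the most distant
  pair.  Combined with the critical gain this caps the workable diameter at
  ``d < log(delta) / log(gamma_c)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleGammaError
from .graphs import DistanceMatrix, Graph, GraphStats, graph_stats, is_tree, oracle_apsp

__all__ = [
    "GainBounds",
    "critical_gain",
    "theorem_necessary_multiplicity_bound",
    "theorem_sufficient_bound",
    "tree_sufficient_bound",
    "precision_bounds",
    "compute_bounds",
    "recommend_gamma",
    "DEFAULT_DELTA",
]

#: smallest positive (subnormal) double — the default precision model.
DEFAULT_DELTA = float(np.nextafter(0, 1))


@dataclass
class GainBounds:
    """All gain bounds for one graph, plus a feasibility verdict.

    ``feasible`` is True when the precision floor lies strictly below the
    smallest applicable upper bound, i.e. a globally-correct gain window
    exists under the precision model ``delta``.
    """

    critical: float
    redundant_path_upper: float | None
    sufficient_upper: float
    tree_upper: float | None
    precision_lower: float
    max_distance: float
    feasible: bool
    delta: float
    recommended: float | None = None


def critical_gain(stats: GraphStats) -> float:
    """gamma_c = 1 / rho(A); +inf for nilpotent adjacency (a DAG), where the
    series converges for every gamma in (0, 1)."""
    rho = stats.spectral_radius
    if rho <= 1e-12:
        return math.inf
    return 1.0 / rho


def theorem_necessary_multiplicity_bound(dist: DistanceMatrix) -> float:
    """Necessary upper bound 1 / max_ij S_ij from shortest-path redundancy
    (unweighted graphs; S must have been computed by the oracle)."""
    if dist.S is None:
        raise ValueError("shortest-path multiplicities unavailable (weighted graph?)")
    n = dist.D.shape[0]
    off = ~np.eye(n, dtype=bool)
    reach = off & np.isfinite(dist.D)
    if not reach.any():
        return 1.0
    return 1.0 / int(max(dist.S[reach].max(), 1))


def theorem_sufficient_bound(stats: GraphStats) -> float:
    """Sufficient upper bound 1 / (Delta + Delta**(d-1)) for any directed
    unweighted graph with max out-degree Delta and (reachable-pair)
    diameter d."""
    delta_deg = stats.max_out_degree
    d = stats.diameter
    if delta_deg < 1 or d < 1:
        return 1.0  # edgeless or single-node: any gamma in (0,1) works
    return 1.0 / (delta_deg + delta_deg ** (d - 1))


def tree_sufficient_bound(stats: GraphStats, diameter_free_n: int | None = None) -> float:
    """Sufficient upper bound for undirected trees.

    With ``diameter_free_n`` set, the diameter is replaced by the vertex
    count N (an upper bound on d available from the adjacency alone),
    giving an O(1/sqrt(N*Delta)) bound independent of the diameter.
    """
    delta_deg = max(stats.max_out_degree, 1)
    d = diameter_free_n if diameter_free_n is not None else stats.diameter
    c = delta_deg * (d + 2)
    return (-1.0 + math.sqrt(1.0 + 4.0 * c)) / (2.0 * c)


def precision_bounds(stats: GraphStats, delta: float = DEFAULT_DELTA) -> tuple[float, float, bool]:
    """Lower bound on gamma from finite precision, and the diameter cap.

    Returns ``(lower, max_distance, feasible)`` where ``lower =
    delta**(1/d)`` (gamma**d must stay above the smallest representable
    magnitude delta), ``max_distance = floor(log delta / log gamma_c)`` is
    the largest diameter compatible with both the precision floor and the
    critical gain, and ``feasible`` is the strict test d < log delta / log
    gamma_c.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    d = stats.diameter
    lower = delta ** (1.0 / d) if d >= 1 else 0.0
    gc = critical_gain(stats)
    if gc >= 1.0:
        return lower, math.inf, True
    cap = math.log(delta) / math.log(gc)
    return lower, float(math.floor(cap)), bool(d < cap)


def compute_bounds(
    g: Graph,
    dist: DistanceMatrix | None = None,
    stats: GraphStats | None = None,
    delta: float = DEFAULT_DELTA,
) -> GainBounds:
    """Evaluate every applicable bound for a graph and pick a recommended
    gain (global mode when the window is feasible, local mode otherwise)."""
    if dist is None:
        dist = oracle_apsp(g)
    if stats is None:
        stats = graph_stats(g, dist)
    crit = critical_gain(stats)
    redundant = theorem_necessary_multiplicity_bound(dist) if dist.S is not None else None
    sufficient = theorem_sufficient_bound(stats)
    tree_b = tree_sufficient_bound(stats) if is_tree(g) else None
    lower, max_d, _ = precision_bounds(stats, delta)
    upper = min(x for x in (crit, redundant, sufficient, tree_b) if x is not None)
    # the more generous tree bound supersedes the generic sufficient bound
    if tree_b is not None:
        upper = min(x for x in (crit, redundant, tree_b) if x is not None)
    feasible = lower < upper
    b = GainBounds(
        critical=crit,
        redundant_path_upper=redundant,
        sufficient_upper=sufficient,
        tree_upper=tree_b,
        precision_lower=lower,
        max_distance=max_d,
        feasible=feasible,
        delta=delta,
    )
    try:
        b.recommended = recommend_gamma(b, mode="global", max_out_degree=stats.max_out_degree)
    except InfeasibleGammaError:
        b.recommended = recommend_gamma(b, mode="local", max_out_degree=stats.max_out_degree)
    return b


def recommend_gamma(bounds: GainBounds, mode: str = "global", max_out_degree: int | None = None) -> float:
    """Pick a gain inside the valid window.

    ``global``: log-scale midpoint of (precision_lower, smallest upper
    bound) — the performance curves plateau across the window, so the
    midpoint maximizes margin to both cliffs.  Raises
    :class:`InfeasibleGammaError` when the window is empty.

    ``local``: 0.9 * min(gamma_c, 1/Delta), honoring the greedy-descent
    guarantee (requires ``max_out_degree``).
    """
    if mode == "global":
        uppers = [bounds.critical, bounds.sufficient_upper]
        if bounds.tree_upper is not None:
            uppers = [bounds.critical, bounds.tree_upper]
        if bounds.redundant_path_upper is not None:
            uppers.append(bounds.redundant_path_upper)
        upper = min(uppers)
        lower = bounds.precision_lower
        if not lower < upper:
            raise InfeasibleGammaError(
                f"no globally-correct gain window: precision floor {lower:.3g} >= "
                f"upper bound {upper:.3g} (critical={bounds.critical:.3g}, "
                f"sufficient={bounds.sufficient_upper:.3g}); the diameter exceeds "
                f"the precision cap {bounds.max_distance}"
            )
        upper = min(upper, 1.0 - 1e-12)
        lo = max(lower, 1e-300)
        return math.exp(0.5 * (math.log(lo) + math.log(upper)))
    if mode == "local":
        if max_out_degree is None:
            raise ValueError("local mode needs max_out_degree")
        return 0.9 * min(bounds.critical, 1.0 / max(max_out_degree, 1))
    raise ValueError(f"unknown mode {mode!r}")
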