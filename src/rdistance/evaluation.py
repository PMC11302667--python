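"""Scoring harnesses: global/local correctness, gain sweeps, weighted-graph
correlation, communicability, and a wall-clock benchmark.

*Global* correctness asks whether the rounded R-distance reproduces the
exact distance for every ordered pair; *local* correctness asks only
whether greedy descent picks an optimal successor for every (start, goal)
pair.  Sweeping the gain maps the valid regime per graph family: the global
window is clipped from above by path redundancy and from below by the
precision floor, while the local window typically extends up to the
critical gain.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bounds as _bounds
from .core import RDistanceResult, rdistance, resolvent
from .errors import BeyondCriticalGainError, RDistanceError
from .graphs import DistanceMatrix, Graph, graph_stats, oracle_apsp
from .navigation import local_counts

__all__ = [
    "plot_sweep",
    "SweepResult",
    "WeightedEval",
    "CommunicabilityResult",
    "global_correctness",
    "global_counts",
    "gamma_sweep",
    "weighted_eval",
    "communicability",
    "benchmark",
]


def global_counts(res: RDistanceResult, oracle: DistanceMatrix) -> tuple[int, int]:
    """Count ordered pairs (diagonal and unreachable pairs included — both
    are predictions the method makes) whose rounded R-distance equals the
    exact distance; unreachable pairs require +inf on both sides."""
    d = oracle.D
    if np.any(np.isfinite(d) & (d != np.round(d))):
        raise RDistanceError(
            "global correctness needs integer distances; discretize the weights "
            "first or use weighted_eval for real-weighted graphs"
        )
    agree = res.rounded == d  # inf == inf is True
    return int(agree.sum()), int(d.size)


def global_correctness(res: RDistanceResult, oracle: DistanceMatrix) -> float:
    """Fraction of ordered pairs with ceil(R) equal to the exact distance."""
    c, t = global_counts(res, oracle)
    return c / t


@dataclass
class SweepResult:
    """Per-gain global and local correctness fractions for one graph.

    Entries at gains at/beyond the critical gain are NaN with
    ``valid=False`` rather than scored.  Denominator conventions: global
    counts all n**2 ordered pairs; local counts ordered (start, goal) pairs
    with start != goal and goal reachable.
    """

    gammas: np.ndarray
    global_fraction: np.ndarray
    local_fraction: np.ndarray
    valid: np.ndarray
    bounds: _bounds.GainBounds
    graph_meta: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gamma": self.gammas,
                "global_fraction": self.global_fraction,
                "local_fraction": self.local_fraction,
                "valid": self.valid,
            }
        )


def gamma_sweep(
    g: Graph,
    gammas,
    oracle: DistanceMatrix | None = None,
    delta: float = _bounds.DEFAULT_DELTA,
) -> SweepResult:
    """Score global and local correctness across a gain grid (sorted
    ascending).  Deterministic: the same graph and grid give identical
    results."""
    gammas = np.sort(np.asarray(list(gammas), dtype=float))
    if np.any((gammas <= 0) | (gammas >= 1)):
        raise ValueError("all gains must lie strictly inside (0, 1)")
    if oracle is None:
        oracle = oracle_apsp(g)
    stats = graph_stats(g, oracle)
    b = _bounds.compute_bounds(g, dist=oracle, stats=stats, delta=delta)
    glob = np.full(gammas.shape, np.nan)
    loc = np.full(gammas.shape, np.nan)
    valid = np.zeros(gammas.shape, dtype=bool)
    counts: dict = {"global": [], "local": []}
    integer_dist = not np.any(np.isfinite(oracle.D) & (oracle.D != np.round(oracle.D)))
    for k, gam in enumerate(gammas):
        try:
            res = rdistance(g, gam)
        except BeyondCriticalGainError:
            counts["global"].append(None)
            counts["local"].append(None)
            continue
        valid[k] = True
        if integer_dist:
            gc, gt = global_counts(res, oracle)
            glob[k] = gc / gt
            counts["global"].append((gc, gt))
        else:
            counts["global"].append(None)
        lc, lt = local_counts(g, res, oracle)
        loc[k] = lc / lt if lt else 1.0
        counts["local"].append((lc, lt))
    return SweepResult(
        gammas=gammas,
        global_fraction=glob,
        local_fraction=loc,
        valid=valid,
        bounds=b,
        graph_meta=dict(g.meta, n=g.n, directed=g.directed),
        counts=counts,
    )


def plot_sweep(sweep: SweepResult, path=None):
    """Correctness-vs-gain curves with the bound overlays (requires
    matplotlib; install the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.semilogx(sweep.gammas, sweep.global_fraction, "o-", label="global")
    ax.semilogx(sweep.gammas, sweep.local_fraction, "s-", label="local")
    b = sweep.bounds
    for value, name, style in (
        (b.critical, "critical", ":"),
        (b.sufficient_upper, "sufficient", "--"),
        (b.redundant_path_upper, "multiplicity", "-."),
        (b.precision_lower, "precision floor", ":"),
    ):
        if value is not None and np.isfinite(value) and 0 < value < 1:
            ax.axvline(value, linestyle=style, alpha=0.5, label=name)
    ax.set_xlabel("gain $\\gamma$")
    ax.set_ylabel("fraction correct")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


@dataclass
class WeightedEval:
    """Correlation-based scoring for real-weighted graphs, where exact
    integer agreement is not meaningful: r^2 is the squared Pearson
    correlation between R and the exact distance over finite off-diagonal
    pairs, and ``local_fraction`` the weight-aware greedy successor score."""

    r_squared: float
    local_fraction: float
    gamma: float
    n_pairs: int


def weighted_eval(g: Graph, gamma: float, oracle: DistanceMatrix | None = None) -> WeightedEval:
    if oracle is None:
        oracle = oracle_apsp(g)
    res = rdistance(g, gamma)
    n = g.n
    off = ~np.eye(n, dtype=bool)
    if not np.any(res.Y[off] > 0):
        raise RDistanceError(
            "every off-diagonal resolvent entry underflowed: gamma too small "
            "for this weight scale"
        )
    sel = off & np.isfinite(res.R) & np.isfinite(oracle.D)
    r_vals = res.R[sel]
    d_vals = oracle.D[sel]
    if d_vals.size < 2 or np.ptp(d_vals) == 0:
        raise RDistanceError("need >= 2 distinct finite distances for a correlation")
    r2 = float(np.corrcoef(r_vals, d_vals)[0, 1] ** 2)
    lc, lt = local_counts(g, res, oracle)
    return WeightedEval(
        r_squared=r2,
        local_fraction=lc / lt if lt else 1.0,
        gamma=float(gamma),
        n_pairs=int(d_vals.size),
    )


@dataclass
class CommunicabilityResult:
    """Total resolvent communicability and its small-gain reinterpretation
    as a sum of gamma**D over all pairs."""

    total: float
    distance_approx: float
    rel_diff: float


def communicability(g: Graph, gamma: float, oracle: DistanceMatrix | None = None) -> CommunicabilityResult:
    """Sum of all resolvent entries, plus the distance-based approximation
    sum_ij gamma**D_ij that it approaches for small gains."""
    y, _ = resolvent(g, gamma)
    total = float(y.sum())
    if oracle is None:
        oracle = oracle_apsp(g)
    with np.errstate(under="ignore"):
        approx = float(np.sum(np.where(np.isfinite(oracle.D), gamma**oracle.D, 0.0)))
    rel = abs(total - approx) / abs(total) if total else 0.0
    return CommunicabilityResult(total=total, distance_approx=approx, rel_diff=rel)


def benchmark(
    g: Graph,
    methods: tuple[str, ...] = ("rdistance", "floyd_warshall", "dijkstra", "johnson"),
    gamma: float | None = None,
    repeats: int = 5,
) -> pd.DataFrame:
    """Median wall-clock time per APSP method, normalized to the R-distance.

    Hardware-dependent by nature; the returned frame is for inspection, and
    all methods are cross-checked to produce identical distances in the
    valid gain window.
    """
    from scipy.sparse import csr_array
    from scipy.sparse.csgraph import shortest_path

    oracle = oracle_apsp(g)
    if gamma is None:
        stats = graph_stats(g, oracle)
        gamma = 0.99 * _bounds.theorem_sufficient_bound(stats)
    tgt, src = np.nonzero(np.isfinite(g.weights))
    m = csr_array((g.weights[tgt, src], (src, tgt)), shape=(g.n, g.n))
    dense = np.ascontiguousarray(np.where(np.isfinite(g.weights.T), g.weights.T, 0.0))

    def run(name: str) -> tuple[float, np.ndarray]:
        times = []
        out = None
        for _ in range(repeats):
            t0 = time.perf_counter()
            if name == "rdistance":
                out = rdistance(g, gamma).rounded
            elif name == "floyd_warshall":
                out = shortest_path(dense, method="FW", directed=True).T
            elif name == "dijkstra":
                out = shortest_path(m, method="D", directed=True, unweighted=g.unweighted).T
            elif name == "johnson":
                out = shortest_path(m, method="J", directed=True).T
            else:
                raise ValueError(f"unknown method {name!r}")
            times.append(time.perf_counter() - t0)
        return float(np.median(times)), out

    rows = []
    results = {}
    for name in methods:
        med, out = run(name)
        results[name] = out
        rows.append({"method": name, "median_s": med, "repeats": repeats})
    for name, out in results.items():
        if not np.array_equal(out, oracle.D):
            raise RDistanceError(f"method {name} disagrees with the exact oracle")
    frame = pd.DataFrame(rows)
    base = frame.loc[frame["method"] == "rdistance", "median_s"]
    if len(base):
        frame["ratio_to_rdistance"] = frame["median_s"] / float(base.iloc[0])
    frame["n"] = g.n
    frame["edges"] = g.n_edges
    return frame
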