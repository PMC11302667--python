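"""Graph container, generators, exact shortest-path oracles, and file I/O.

Direction convention
--------------------
The whole package stores edges *column-to-row*: the weight matrix entry
``W[i, j]`` is the weight of the edge FROM node ``j`` TO node ``i`` (absent
edges are ``+inf``), and the 0/1 adjacency has ``A[i, j] = 1`` for the same
edge.  Under this convention the out-degree of node ``j`` is the ``j``-th
*column* sum of ``A``, and matrix powers ``A**k`` count k-step walks
``[A**k][i, j] = #walks from j to i``.  Every downstream formula (resolvent,
R-distance, gain bounds, greedy descent) relies on this orientation.

File I/O, by contrast, uses the ubiquitous ``source target [weight]``
edge-list convention and transposes on read/write, so files interoperate
with other tools.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .errors import GraphFormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "DistanceMatrix",
    "GraphStats",
    "generate_family",
    "path_graph",
    "cycle_graph",
    "grid_graph",
    "binary_tree",
    "dense_random",
    "power_law",
    "hanoi",
    "with_log_uniform_weights",
    "oracle_apsp",
    "graph_stats",
    "spectral_radius",
    "is_tree",
    "read_graph",
    "write_graph",
]

FAMILIES = ("path", "cycle", "grid", "binary_tree", "dense_random", "power_law", "hanoi")


@dataclass
class Graph:
    """A dense directed or undirected graph with positive edge weights.

    ``weights[i, j]`` is the weight of the edge from node ``j`` to node
    ``i``; absent edges are ``+inf``.  A graph is *unweighted* when every
    finite weight equals 1.
    """

    weights: np.ndarray
    directed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weight matrix must be square")
        finite = np.isfinite(self.weights)
        if np.any(self.weights[finite] <= 0):
            raise ValueError("all finite edge weights must be strictly positive")
        if not self.directed:
            if not np.array_equal(self.weights, self.weights.T):
                raise ValueError("undirected graph requires a symmetric weight matrix")

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def unweighted(self) -> bool:
        finite = np.isfinite(self.weights)
        return bool(np.all(self.weights[finite] == 1.0))

    @property
    def adjacency(self) -> np.ndarray:
        """0/1 adjacency, A[i, j] = 1 iff there is an edge j -> i."""
        return np.isfinite(self.weights).astype(float)

    @property
    def n_edges(self) -> int:
        m = int(np.isfinite(self.weights).sum())
        return m if self.directed else m // 2

    def out_degrees(self) -> np.ndarray:
        """Out-degree of each node (column sums of the adjacency)."""
        return np.isfinite(self.weights).sum(axis=0)

    def successors(self, j: int) -> np.ndarray:
        """Nodes reachable from ``j`` in one step, in ascending id order."""
        return np.flatnonzero(np.isfinite(self.weights[:, j]))

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Iterable[tuple],
        directed: bool = False,
        meta: dict | None = None,
    ) -> "Graph":
        """Build a graph from ``(source, target[, weight])`` tuples."""
        w = np.full((n, n), np.inf)
        for e in edges:
            s, t = int(e[0]), int(e[1])
            wt = float(e[2]) if len(e) > 2 else 1.0
            w[t, s] = wt
            if not directed:
                w[s, t] = wt
        return cls(w, directed=directed, meta=meta or {})

    def edges(self) -> list[tuple[int, int, float]]:
        """Edges as ``(source, target, weight)``; undirected edges once."""
        out = []
        tgt, src = np.nonzero(np.isfinite(self.weights))
        for i, j in zip(tgt, src):
            if not self.directed and j > i:
                continue
            out.append((int(j), int(i), float(self.weights[i, j])))
        return out


@dataclass
class DistanceMatrix:
    """Exact shortest-path distances and multiplicities.

    ``D[i, j]`` is the shortest-path distance from node ``j`` to node ``i``
    (``+inf`` when unreachable, 0 on the diagonal).  For unweighted graphs
    ``S[i, j]`` counts the distinct shortest paths from ``j`` to ``i`` as
    arbitrary-precision integers (``S[i, i] = 1``, the empty walk); for
    weighted graphs ``S`` is ``None``.
    """

    D: np.ndarray
    S: np.ndarray | None = None


@dataclass
class GraphStats:
    """Summary quantities entering the gain bounds.

    ``max_out_degree`` is Delta = max column sum of the adjacency;
    ``diameter`` is the largest *finite* ordered-pair distance (unreachable
    pairs are ignored so the bounds stay finite on disconnected graphs);
    ``max_shortest_path_count`` is max S_ij over reachable pairs i != j.
    """

    max_out_degree: int
    diameter: float
    spectral_radius: float
    max_shortest_path_count: int | None = None


# ---------------------------------------------------------------------------
# generators


def path_graph(n: int) -> Graph:
    """Undirected path on ``n`` nodes (0-1-2-...-n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return Graph.from_edges(n, [(i, i + 1) for i in range(n - 1)], meta={"family": "path", "n": n})


def cycle_graph(n: int, directed: bool = False) -> Graph:
    """Cycle on ``n`` nodes; the directed variant is a cyclic permutation."""
    if n < 3:
        raise ValueError("cycle needs n >= 3")
    edges = [(i, (i + 1) % n) for i in range(n)]
    return Graph.from_edges(n, edges, directed=directed, meta={"family": "cycle", "n": n})


def grid_graph(m: int) -> Graph:
    """Square m x m lattice; each node connects to its 4 nearest neighbors."""
    if m < 1:
        raise ValueError("grid side must be >= 1")
    edges = []
    for r in range(m):
        for c in range(m):
            u = r * m + c
            if c + 1 < m:
                edges.append((u, u + 1))
            if r + 1 < m:
                edges.append((u, u + m))
    return Graph.from_edges(m * m, edges, meta={"family": "grid", "M": m})


def binary_tree(levels: int) -> Graph:
    """Complete binary tree with ``levels`` levels (2**levels - 1 nodes),
    undirected: node k has children 2k+1 and 2k+2."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    n = 2**levels - 1
    edges = [(k, c) for k in range(n) for c in (2 * k + 1, 2 * k + 2) if c < n]
    return Graph.from_edges(n, edges, meta={"family": "binary_tree", "levels": levels})


def dense_random(n: int, p: float = 0.5, directed: bool = False, seed: int = 0) -> Graph:
    """Erdos-Renyi graph: each (ordered, if directed) pair of distinct nodes
    is connected independently with probability ``p``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    w = np.full((n, n), np.inf)
    if directed:
        mask = rng.random((n, n)) < p
        np.fill_diagonal(mask, False)
        w[mask] = 1.0
    else:
        iu = np.triu_indices(n, k=1)
        mask = rng.random(len(iu[0])) < p
        w[iu[0][mask], iu[1][mask]] = 1.0
        w = np.minimum(w, w.T)
    return Graph(w, directed=directed, meta={"family": "dense_random", "n": n, "p": p, "seed": seed})


def power_law(n: int, exponent: float = 3.0, seed: int = 0) -> Graph:
    """Undirected configuration-model graph with a discrete power-law degree
    sequence P(k) ~ k**(-exponent), k >= 1; self-loops and parallel edges are
    collapsed, so realized degrees can fall slightly below the drawn ones."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling from the zeta-like distribution, truncated at n-1
    ks = np.arange(1, n)
    pmf = ks.astype(float) ** (-exponent)
    pmf /= pmf.sum()
    degrees = rng.choice(ks, size=n, p=pmf)
    if degrees.sum() % 2:
        degrees[rng.integers(n)] += 1
    g = nx.configuration_model(degrees.tolist(), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse parallel edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return Graph.from_edges(
        n,
        list(g.edges()),
        meta={
            "family": "power_law",
            "n": n,
            "exponent": exponent,
            "seed": seed,
            "note": "configuration model, self-loops/multi-edges collapsed",
        },
    )


def hanoi(disks: int) -> Graph:
    """State graph of the 3-peg Towers-of-Hanoi puzzle with ``disks`` disks.

    States are assignments of each disk to a peg (3**disks nodes); edges are
    legal single-disk moves (the top disk of a peg may move onto a peg whose
    top disk is larger).  Undirected; diameter 2**disks - 1.
    """
    if disks < 1:
        raise ValueError("disks must be >= 1")
    states = list(itertools.product(range(3), repeat=disks))
    index = {s: k for k, s in enumerate(states)}
    edges = []
    for s in states:
        # disk 0 is the smallest; the movable disk on peg p is min{d : s[d]==p}
        top = {}
        for d in range(disks - 1, -1, -1):
            top[s[d]] = d
        for p, d in top.items():
            for q in range(3):
                if q == p or (q in top and top[q] < d):
                    continue
                t = list(s)
                t[d] = q
                u, v = index[s], index[tuple(t)]
                if u < v:
                    edges.append((u, v))
    return Graph.from_edges(3**disks, edges, meta={"family": "hanoi", "disks": disks})


def with_log_uniform_weights(
    g: Graph, low: float = 1.0, high: float = 100.0, seed: int = 0
) -> Graph:
    """Replace every edge weight with an independent draw from a log-uniform
    distribution on [low, high] (symmetric draws for undirected graphs)."""
    if not 0 < low <= high:
        raise ValueError("need 0 < low <= high")
    rng = np.random.default_rng(seed)
    w = np.array(g.weights)
    mask = np.isfinite(w)
    draws = np.exp(rng.uniform(np.log(low), np.log(high), size=w.shape))
    w[mask] = draws[mask]
    if not g.directed:
        # mirror the upper triangle so both directions carry the same draw
        iu = np.triu_indices(g.n)
        sym = np.full_like(w, np.inf)
        sym[iu] = w[iu]
        w = np.minimum(sym, sym.T)
    meta = dict(g.meta, weights=f"log-uniform[{low},{high}]", weight_seed=seed)
    return Graph(w, directed=g.directed, meta=meta)


def generate_family(family: str, params: dict | None = None, seed: int = 0) -> Graph:
    """Dispatch to the named generator.  ``seed`` only affects the random
    families (dense_random, power_law); deterministic families ignore it."""
    params = dict(params or {})
    if family == "path":
        return path_graph(int(params.get("n", 10)))
    if family == "cycle":
        return cycle_graph(int(params.get("n", 10)), directed=bool(params.get("directed", False)))
    if family == "grid":
        return grid_graph(int(params.get("M", params.get("m", 4))))
    if family == "binary_tree":
        return binary_tree(int(params.get("levels", 4)))
    if family == "dense_random":
        return dense_random(
            int(params.get("n", 50)),
            p=float(params.get("p", 0.5)),
            directed=bool(params.get("directed", False)),
            seed=seed,
        )
    if family == "power_law":
        return power_law(int(params.get("n", 50)), exponent=float(params.get("exponent", 3.0)), seed=seed)
    if family == "hanoi":
        return hanoi(int(params.get("disks", 3)))
    raise ValueError(f"unknown graph family {family!r}; choose from {FAMILIES}")


# ---------------------------------------------------------------------------
# exact oracles


def oracle_apsp(g: Graph) -> DistanceMatrix:
    """Exact all-pairs shortest-path distances (BFS for unweighted graphs,
    Dijkstra otherwise), plus shortest-path multiplicities for unweighted
    graphs via a layered DP with arbitrary-precision counts."""
    n = g.n
    # scipy's csgraph convention is row-to-column, ours is column-to-row
    tgt, src = np.nonzero(np.isfinite(g.weights))
    m = csr_array((g.weights[tgt, src], (src, tgt)), shape=(n, n))
    dist = shortest_path(m, method="auto", directed=True, unweighted=g.unweighted)
    D = np.ascontiguousarray(dist.T)
    S = _count_shortest_paths(g, D) if g.unweighted else None
    return DistanceMatrix(D=D, S=S)


def _count_shortest_paths(g: Graph, D: np.ndarray) -> np.ndarray:
    """S[i, j] = number of distinct shortest paths j -> i (exact integers)."""
    n = g.n
    succ = [g.successors(j) for j in range(n)]
    S = np.zeros((n, n), dtype=object)
    for j in range(n):
        dcol = D[:, j]
        counts = [0] * n
        counts[j] = 1
        finite = np.flatnonzero(np.isfinite(dcol))
        for v in sorted(finite, key=lambda v: dcol[v]):
            cv = counts[v]
            if cv == 0:
                continue
            for u in succ[v]:
                if dcol[u] == dcol[v] + 1:
                    counts[u] += cv
        for i in range(n):
            S[i, j] = counts[i]
    return S


def spectral_radius(a: np.ndarray, tol: float = 1e-10, seed: int = 0, maxiter: int = 100_000) -> float:
    """Spectral radius of a non-negative matrix.

    Small matrices (n < 500) go through a full eigendecomposition
    (symmetric-aware); larger ones use power iteration with a random start
    and the given relative tolerance.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if n < 500:
        if np.array_equal(a, a.T):
            vals = np.linalg.eigvalsh(a)
        else:
            vals = np.linalg.eigvals(a)
        return float(np.max(np.abs(vals))) if n else 0.0
    rng = np.random.default_rng(seed)
    v = rng.random(n) + 1e-3
    v /= np.linalg.norm(v)
    lam = 0.0
    for _ in range(maxiter):
        w = a @ v
        nrm = np.linalg.norm(w)
        if nrm == 0.0:
            return 0.0
        v_new = w / nrm
        lam_new = float(v_new @ (a @ v_new))
        if abs(lam_new - lam) <= tol * max(abs(lam_new), 1e-300):
            return abs(lam_new)
        v, lam = v_new, lam_new
    return abs(lam)


def graph_stats(g: Graph, dist: DistanceMatrix | None = None) -> GraphStats:
    """Summary statistics for the gain bounds; computes the exact oracle if
    one is not supplied."""
    if dist is None:
        dist = oracle_apsp(g)
    D = dist.D
    off = ~np.eye(g.n, dtype=bool)
    finite = off & np.isfinite(D)
    diameter = float(D[finite].max()) if finite.any() else 0.0
    max_s = None
    if dist.S is not None:
        max_s = int(max((dist.S[finite].max(initial=0), 1))) if finite.any() else 1
    return GraphStats(
        max_out_degree=int(g.out_degrees().max(initial=0)),
        diameter=diameter,
        spectral_radius=spectral_radius(g.adjacency),
        max_shortest_path_count=max_s,
    )


def is_tree(g: Graph) -> bool:
    """True iff the graph is an undirected, connected tree (n-1 edges)."""
    if g.directed:
        return False
    if g.n_edges != g.n - 1:
        return False
    D = oracle_apsp(g).D
    return bool(np.all(np.isfinite(D)))


# ---------------------------------------------------------------------------
# file I/O


def write_graph(g: Graph, path, format: str = "edge_list") -> None:
    """Write a graph; ``edge_list`` rows are ``source target weight`` (the
    reader transposes into the internal column-to-row storage)."""
    if format == "edge_list":
        _write_edge_list(g, path)
    elif format == "dense_matrix":
        _write_dense(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_graph(path, format: str = "edge_list") -> Graph:
    if format == "edge_list":
        return _read_edge_list(path)
    if format == "dense_matrix":
        return _read_dense(path)
    raise ValueError(f"unknown format {format!r}")


def _write_edge_list(g: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nodes={g.n}\n")
        fh.write(f"# directed={'true' if g.directed else 'false'}\n")
        fh.write("# rows: source target weight (transposed to W[target,source] internally)\n")
        if g.meta:
            fh.write(f"# meta={json.dumps(g.meta, sort_keys=True)}\n")
        for s, t, w in g.edges():
            if w == 1.0 and g.unweighted:
                fh.write(f"{s} {t}\n")
            else:
                fh.write(f"{s} {t} {w!r}\n")


def _read_edge_list(path) -> Graph:
    n = None
    directed = False
    meta: dict = {}
    rows: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("nodes="):
                    n = int(body[6:])
                elif body.startswith("directed="):
                    directed = body[9:].strip().lower() == "true"
                elif body.startswith("meta="):
                    meta = json.loads(body[5:])
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise GraphFormatError(f"{path}:{lineno}: malformed edge row {line!r}")
            s, t = int(parts[0]), int(parts[1])
            w = float(parts[2]) if len(parts) == 3 else 1.0
            if w <= 0:
                raise GraphFormatError(f"{path}:{lineno}: non-positive weight {w}")
            rows.append((s, t, w))
    if not rows and n is None:
        raise GraphFormatError(f"{path}: no edges and no node count header")
    if n is None:
        n = max(max(s, t) for s, t, _ in rows) + 1
    w = np.full((n, n), np.inf)
    for s, t, wt in rows:
        if s >= n or t >= n or s < 0 or t < 0:
            raise GraphFormatError(f"{path}: node id out of range in edge {s}->{t}")
        if np.isfinite(w[t, s]):
            logger.warning("%s: duplicate edge %d->%d, last value wins", path, s, t)
        w[t, s] = wt
        if not directed:
            w[s, t] = wt
    return Graph(w, directed=directed, meta=meta)


def _write_dense(g: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nodes={g.n}\n")
        fh.write(f"# directed={'true' if g.directed else 'false'}\n")
        fh.write("# dense weight matrix, entry (i,j) = weight of edge j->i; +inf = absent\n")
        if g.meta:
            fh.write(f"# meta={json.dumps(g.meta, sort_keys=True)}\n")
        for row in g.weights:
            fh.write(" ".join("+inf" if not np.isfinite(x) else repr(float(x)) for x in row))
            fh.write("\n")


def _read_dense(path) -> Graph:
    directed = False
    meta: dict = {}
    rows = []
    n = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("nodes="):
                    n = int(body[6:])
                elif body.startswith("directed="):
                    directed = body[9:].strip().lower() == "true"
                elif body.startswith("meta="):
                    meta = json.loads(body[5:])
                continue
            rows.append([np.inf if tok in ("+inf", "inf") else float(tok) for tok in line.split()])
    if not rows:
        raise GraphFormatError(f"{path}: no matrix rows")
    w = np.array(rows, dtype=float)
    if n is not None and w.shape[0] != n:
        raise GraphFormatError(f"{path}: header says {n} nodes, matrix has {w.shape[0]} rows")
    return Graph(w, directed=directed, meta=meta)
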