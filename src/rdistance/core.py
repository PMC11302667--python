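"""The R-distance: graph distances from the resolvent of the adjacency.

For a graph with adjacency A (``A[i, j] = 1`` for an edge j -> i) and a gain
``0 < gamma < 1``, the resolvent

    Y(gamma) = (I - gamma*A)**-1 = sum_k gamma**k * A**k

accumulates gamma-discounted walk counts, so its leading term for a pair
(i, j) is ``S_ij * gamma**D_ij`` where D_ij is the shortest-path distance
and S_ij the number of distinct shortest paths.  Taking the base-gamma log,

    R_ij(gamma) = log_gamma Y_ij(gamma)  ->  D_ij   as gamma -> 0,

and for a suitable finite gamma the rounded-up R-distance equals the exact
distance for every pair.  Weighted graphs with positive weights W use the
elementwise substitution ``X(gamma) = gamma**W`` (absent edges contribute 0)
and ``Y = (I - X)**-1``; the unweighted case is X = gamma*A.

This module computes Y and R by a dense linear solve, validates them against
a truncated power series with an analytic tail bound, and handles the
finite-precision edge cases (underflowed entries, tiny negative solver
residue, gains at or beyond the convergence radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import BeyondCriticalGainError
from .graphs import Graph, spectral_radius

__all__ = [
    "RDistanceResult",
    "WalkCountSeries",
    "resolvent",
    "rdistance",
    "rdistance_highprec",
    "power_series_oracle",
    "discretize_weights",
    "MASK_OK",
    "MASK_UNREACHABLE",
    "MASK_CLAMPED",
    "ROUNDING_GUARD",
]

# mask codes for entries where Y <= 0
MASK_OK = 0
MASK_UNREACHABLE = 1  # exact zero: no walk of any length
MASK_CLAMPED = 2      # tiny negative from the solve, clamped to 0

#: rounded distances use ceil(R - ROUNDING_GUARD): with a unique shortest
#: path and negligible tail, R sits exactly at the integer D and a bare ceil
#: would be fragile to upward floating-point drift.
ROUNDING_GUARD = 1e-9

#: entries of Y below this are close enough to the subnormal range that the
#: log may be unreliable; they are flagged, not invalidated.
UNDERFLOW_THRESHOLD = 4 * np.finfo(float).tiny


def discount_matrix(g: Graph, gamma: float) -> np.ndarray:
    """X(gamma) = gamma**W elementwise, with absent edges (W = +inf)
    contributing exactly 0.  For an unweighted graph this equals gamma*A
    bitwise, since gamma**1 == gamma."""
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")
    with np.errstate(under="ignore"):
        return gamma ** g.weights


def resolvent(g: Graph, gamma: float) -> tuple[np.ndarray, bool]:
    """Solve (I - X(gamma)) Y = I for the resolvent Y.

    Returns ``(Y, series_valid)`` with ``series_valid = (rho(X) < 1)``.
    Raises :class:`BeyondCriticalGainError` when the gain is at or beyond
    the convergence radius, where the solve no longer represents walk
    counts.
    """
    x = discount_matrix(g, gamma)
    rho = spectral_radius(x)
    if rho >= 1.0:
        raise BeyondCriticalGainError(
            f"gamma={gamma} is at/beyond the convergence radius: rho(X(gamma))={rho:.6g} >= 1"
        )
    with np.errstate(under="ignore"):
        y = scipy.linalg.solve(np.eye(g.n) - x, np.eye(g.n))
    return y, True


@dataclass
class RDistanceResult:
    """Resolvent, R-distances, and rounded integer distances at one gain.

    ``R = log_gamma(Y)`` where ``Y > 0`` and ``+inf`` elsewhere (the map is
    monotone *decreasing* in Y since the base is below 1).  ``rounded`` is
    ``ceil(R - guard)`` clamped below at 0, stored as floats so ``+inf``
    can mark unreachable pairs.  ``mask`` distinguishes exact zeros
    (unreachable) from solver negatives clamped to zero;
    ``underflow_mask`` flags positive entries near the subnormal range.
    """

    gamma: float
    Y: np.ndarray
    R: np.ndarray
    rounded: np.ndarray
    series_valid: bool
    mask: np.ndarray
    underflow_mask: np.ndarray
    meta: dict = field(default_factory=dict)


def rdistance(g: Graph, gamma: float) -> RDistanceResult:
    """Compute the R-distance matrix R = log_gamma (I - X(gamma))**-1."""
    y, series_valid = resolvent(g, gamma)
    return _finish(g, gamma, y, series_valid)


def _finish(g: Graph, gamma: float, y: np.ndarray, series_valid: bool) -> RDistanceResult:
    mask = np.full(y.shape, MASK_OK, dtype=np.int8)
    mask[y == 0.0] = MASK_UNREACHABLE
    neg = y < 0.0
    mask[neg] = MASK_CLAMPED
    y = np.where(neg, 0.0, y)
    underflow = (y > 0.0) & (y < UNDERFLOW_THRESHOLD)
    r = np.full(y.shape, np.inf)
    pos = y > 0.0
    with np.errstate(divide="ignore", under="ignore"):
        r[pos] = np.log(y[pos]) / np.log(gamma)
    rounded = np.where(np.isfinite(r), np.maximum(np.ceil(r - ROUNDING_GUARD), 0.0), np.inf)
    return RDistanceResult(
        gamma=float(gamma),
        Y=y,
        R=r,
        rounded=rounded,
        series_valid=series_valid,
        mask=mask,
        underflow_mask=underflow,
        meta={"n": g.n, "directed": g.directed, "unweighted": g.unweighted},
    )


def rdistance_highprec(g: Graph, gamma: float, dps: int = 60) -> RDistanceResult:
    """R-distance with ``dps`` decimal digits of working precision (mpmath).

    Trades speed for dynamic range: long-diameter graphs whose Y entries
    underflow in double precision stay representable here.  Intended for
    small graphs (the solve is dense O(n^3) in software floats).
    """
    import mpmath as mp

    if not 0 < gamma < 1:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")
    n = g.n
    with mp.workdps(dps):
        gam = mp.mpf(gamma)
        m = mp.zeros(n, n)
        for i in range(n):
            for j in range(n):
                w = g.weights[i, j]
                xij = gam ** mp.mpf(w) if np.isfinite(w) else mp.mpf(0)
                m[i, j] = (1 if i == j else 0) - xij
        yinv = m**-1
        logg = mp.log(gam)
        y = np.zeros((n, n))
        r = np.full((n, n), np.inf)
        mask = np.full((n, n), MASK_OK, dtype=np.int8)
        for i in range(n):
            for j in range(n):
                val = yinv[i, j]
                if val > 0:
                    r[i, j] = float(mp.log(val) / logg)
                    y[i, j] = float(val)  # may underflow to 0 on conversion
                elif val < 0:
                    mask[i, j] = MASK_CLAMPED
                else:
                    mask[i, j] = MASK_UNREACHABLE
    rounded = np.where(np.isfinite(r), np.maximum(np.ceil(r - ROUNDING_GUARD), 0.0), np.inf)
    underflow = (y > 0.0) & (y < UNDERFLOW_THRESHOLD)
    return RDistanceResult(
        gamma=float(gamma), Y=y, R=r, rounded=rounded, series_valid=True,
        mask=mask, underflow_mask=underflow,
        meta={"n": n, "directed": g.directed, "unweighted": g.unweighted, "dps": dps},
    )


@dataclass
class WalkCountSeries:
    """Truncated power series sum_k X(gamma)**k with exact walk counts.

    For unweighted graphs ``counts[k]`` is the arbitrary-precision integer
    matrix of k-step walk counts (``counts[0] = I``, ``counts[k] =
    A @ counts[k-1]``); for weighted graphs exact counts are not tracked and
    ``counts`` is None.  ``tail_bound`` bounds the elementwise truncation
    error |partial_sum - Y| via the geometric out-degree argument
    (walks of length k number at most Delta**(k-1) per pair)."""

    kmax: int
    counts: list[np.ndarray] | None
    partial_sum: np.ndarray
    tail_bound: float


def power_series_oracle(g: Graph, gamma: float, kmax: int) -> WalkCountSeries:
    """Evaluate I + X + X**2 + ... + X**kmax directly.

    Serves as an independent check of :func:`resolvent`: when the series
    converges the partial sum approaches Y from below, within
    ``tail_bound``.
    """
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    n = g.n
    if g.unweighted:
        a_int = np.isfinite(g.weights).astype(object)
        counts: list[np.ndarray] | None = [np.eye(n, dtype=int).astype(object)]
        for _ in range(kmax):
            counts.append(a_int @ counts[-1])
        with np.errstate(under="ignore"):
            partial = sum(
                (gamma**k) * nk.astype(float) for k, nk in enumerate(counts)
            )
        delta = float(g.out_degrees().max(initial=0))
        q = gamma * delta
        tail = (gamma ** (kmax + 1) * delta**kmax / (1 - q)) if q < 1 else np.inf
    else:
        counts = None
        x = discount_matrix(g, gamma)
        term = np.eye(n)
        partial = np.eye(n)
        with np.errstate(under="ignore"):
            for _ in range(kmax):
                term = x @ term
                partial = partial + term
        # max column sum bounds every entry of X**k by q**k
        q = float(x.sum(axis=0).max(initial=0))
        tail = q ** (kmax + 1) / (1 - q) if q < 1 else np.inf
    return WalkCountSeries(kmax=kmax, counts=counts, partial_sum=np.asarray(partial, dtype=float), tail_bound=float(tail))


def discretize_weights(g: Graph, delta_w: float) -> Graph:
    """Replace each finite weight by ``round(W / delta_w)`` as an integer
    multiple of ``delta_w`` units (minimum 1 unit; rounding a weight to 0 is
    an error because zero weights are forbidden).  The returned graph stores
    the integer unit counts; ``meta['delta_w']`` records the increment so
    distances can be rescaled back by multiplication."""
    if delta_w <= 0:
        raise ValueError("delta_w must be positive")
    w = np.array(g.weights)
    mask = np.isfinite(w)
    units = np.round(w[mask] / delta_w)
    if np.any(units < 1):
        bad = float(w[mask][units < 1].min())
        raise ValueError(
            f"delta_w={delta_w} is too coarse: weight {bad} rounds to 0 (zero weights forbidden)"
        )
    w[mask] = units
    meta = dict(g.meta, delta_w=delta_w)
    return Graph(w, directed=g.directed, meta=meta)
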