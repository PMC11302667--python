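"""Recurrent linear circuit whose steady state computes the resolvent.

One linear unit per graph node: unit i outputs ``v_i = gamma * w_i`` where
its input ``w_i = u_i + sum_j A[i, j] * v_j`` combines an external drive
with feedback through the adjacency.  The fixed point is

    v = gamma * (I - gamma*A)**-1 u = gamma * Y u,

so driving a single unit (one-hot u at a source node) makes the settled
outputs read out a column of the resolvent — and hence the R-distances
from the source to every node — without any explicit matrix inversion.

The continuous analog dynamics are modeled by synchronous discrete-time
settling ``v <- gamma * (u + A v)`` from v = 0; the contract is the fixed
point, which the iteration reaches whenever ``rho(gamma*A) < 1``.  An
optional multiplicative Gaussian perturbation per unit per step models
finite analog precision (relative noise sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError
from .graphs import Graph

__all__ = ["CircuitState", "settle", "query_distance"]


@dataclass
class CircuitState:
    v: np.ndarray
    u: np.ndarray
    gamma: float
    iterations: int
    converged: bool
    residual: float


def settle(
    g: Graph,
    gamma: float,
    u: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
    noise_sigma: float | None = None,
    seed: int | None = None,
    v0: np.ndarray | None = None,
) -> CircuitState:
    """Iterate ``v <- gamma * (u + A v)`` until the max-norm update falls
    below ``tol`` (noiseless) or stops improving (noisy).

    ``v0`` warm-starts the iteration, e.g. to re-settle after editing an
    edge — the "always on" mode where the circuit tracks changes to the
    map.  Divergence (residual growth over a 20-step window) raises
    :class:`DivergenceError`, which happens exactly when
    ``rho(gamma*A) >= 1``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if tol <= 0:
        raise ValueError("tol must be positive")
    a = g.adjacency
    u = np.asarray(u, dtype=float)
    if u.shape != (g.n,):
        raise ValueError(f"input vector must have shape ({g.n},)")
    rng = np.random.default_rng(seed)
    v = np.zeros(g.n) if v0 is None else np.array(v0, dtype=float)
    window: list[float] = []
    residual = np.inf
    with np.errstate(under="ignore"):
        for it in range(1, max_iter + 1):
            v_new = gamma * (u + a @ v)
            if noise_sigma:
                v_new = v_new * (1.0 + noise_sigma * rng.standard_normal(g.n))
            residual = float(np.max(np.abs(v_new - v)))
            v = v_new
            if residual <= tol * max(1.0, float(np.max(np.abs(v)))):
                return CircuitState(v=v, u=u, gamma=gamma, iterations=it, converged=True, residual=residual)
            window.append(residual)
            if len(window) > 40:
                window.pop(0)
                # geometric growth dominates noise jitter: compare medians of
                # the two halves of the window rather than single residuals
                recent = float(np.median(window[20:]))
                older = float(np.median(window[:20]))
                if not np.isfinite(residual) or recent > 4.0 * older > 0:
                    raise DivergenceError(
                        f"circuit iteration diverges at gamma={gamma}: "
                        "rho(gamma*A) >= 1 (residual grows geometrically)"
                    )
            if noise_sigma and it >= 200 and residual <= 10 * noise_sigma * float(np.max(np.abs(v))):
                # noise floor reached; further iterations only bounce around it
                return CircuitState(v=v, u=u, gamma=gamma, iterations=it, converged=True, residual=residual)
    return CircuitState(v=v, u=u, gamma=gamma, iterations=max_iter, converged=False, residual=residual)


def query_distance(
    g: Graph,
    gamma: float,
    source: int,
    tol: float = 1e-12,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """R-distances from ``source`` to every node, read off the circuit.

    Drives the source unit with a unit input; the settled outputs are
    ``v = gamma * Y[:, source]``, so ``log_gamma(v / gamma)`` recovers the
    R-distance column (``+inf`` where the output vanishes).
    """
    u = np.zeros(g.n)
    u[source] = 1.0
    state = settle(g, gamma, u, tol=tol, noise_sigma=noise_sigma, seed=seed)
    y_col = state.v / gamma
    r = np.full(g.n, np.inf)
    pos = y_col > 0
    with np.errstate(divide="ignore"):
        r[pos] = np.log(y_col[pos]) / np.log(gamma)
    return r
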