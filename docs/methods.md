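# Methods

## Model

A directed graph on `n` nodes is stored as a dense weight matrix with the
column-to-row convention `W[i, j] = weight of the edge j → i` (`+inf` for
absent edges); the 0/1 adjacency `A` marks the finite entries. Under this
orientation the out-degree of `j` is the `j`-th column sum, and
`[A^k][i, j]` counts k-step walks from `j` to `i`. File I/O uses the
ubiquitous `source target [weight]` edge-list convention and transposes at
the boundary; everything downstream — resolvent, bounds, navigation —
depends on the internal orientation, which is why it is fixed in one place
(`rdistance.graphs`) and asserted in tests.

For a gain `0 < γ < 1` the discount matrix is `X(γ) = γ^W` elementwise
(absent edges contribute exactly 0; for unit weights this is bitwise equal
to `γA`). When `ρ(X) < 1` the resolvent `Y = (I − X)⁻¹ = Σₖ Xᵏ` sums
discounted walk counts, and the R-distance `R = log_γ Y` approaches the
true distance matrix as `γ → 0`: the leading term of `Y_ij` is
`S_ij γ^{D_ij}` with `S_ij ≥ 1` the shortest-path multiplicity, so
`R_ij = D_ij + log_γ(S_ij + C)` where `C` collects longer walks. Since
`log_γ S ≤ 0` and `C → 0`, rounding *up* recovers `D_ij` whenever γ is
small enough that the tail cannot cross an integer boundary and large
enough that `γ^d` stays representable.

Requesting a gain at or beyond `1/ρ(X)` raises an explicit error rather
than returning a matrix that no longer represents walk counts.

## Gain bounds

All bounds are computed from `GraphStats` (max out-degree Δ, diameter d
over *reachable* ordered pairs, spectral radius, max multiplicity):

* `critical = 1/ρ(A)` (∞ for nilpotent adjacency — on a DAG the series
  always terminates);
* `redundant_path_upper = 1 / max S_ij` — necessary: a multiplicity S
  inflates `Y` by S, which crosses the rounding boundary once `γ ≥ 1/S`;
* `sufficient_upper = 1/(Δ + Δ^{d−1})` — bounding the tail by the
  geometric out-degree series;
* `tree_upper = (−1+√(1+4Δ(d+2)))/(2Δ(d+2))` for undirected trees, with a
  diameter-free variant replacing d by n when only the adjacency is known;
* `precision_lower = δ^{1/d}`, where δ defaults to the smallest positive
  subnormal double (≈5×10⁻³²⁴) and can be set to model analog
  signal-to-noise (e.g. δ = 0.01). Combined with the critical gain this
  caps the workable diameter at `max_distance = ⌊log δ / log γ_c⌋`.

The diameter is taken over reachable pairs only, so disconnected graphs do
not produce an infinite diameter; the bounds only ever constrain reachable
pairs, and unreachable pairs are exact zeros of `Y` that map to `+inf`
distances regardless of γ.

`recommend_gamma` is this package's own policy (no canonical choice
exists): in *global* mode, the log-scale midpoint of
`(precision_lower, min(upper bounds))` — correctness is flat across the
window, so the midpoint maximizes margin to both cliffs; in *local* mode,
`0.9 · min(γ_c, 1/Δ)`, honoring the greedy-descent guarantee below.

## Rounding and finite precision

Rounded distances are `ceil(R − ε)` with `ε = 1e−9`, clamped below at 0.
When `S_ij = 1` and the tail is negligible, `R_ij` sits exactly at the
integer `D_ij`, and a bare ceil would flip on upward floating-point drift
of order 1e−15; the guard absorbs that while being far smaller than any
legitimate sub-integer signal. Entries with `Y ≤ 0` map to `R = +inf` with
distinct mask codes for exact zeros (unreachable) and tiny solver
negatives clamped to zero; positive entries within 4× the smallest normal
number are flagged as near-underflow but not invalidated — subnormal
arithmetic keeps `log` usable almost to δ, which is exactly what makes the
measured low edge of the correct window track `δ^{1/d}`.

The solve is one dense LAPACK factorization of `(I − X)` applied to the
identity. An opt-in high-precision path (`rdistance_highprec`, mpmath,
configurable decimal digits) trades time for dynamic range on
long-diameter graphs — the explicit time-for-space exchange that the
precision cap otherwise forbids. The spectral radius uses a full
(symmetric-aware) eigendecomposition below n = 500 and power iteration
with 1e−10 relative tolerance above.

A truncated power series `Σ_{k≤kmax} Xᵏ` with exact integer walk counts
(arbitrary precision; grid multiplicities `C(2M−2, M−1)` overflow 64-bit
by M ≈ 18) serves as an independent oracle for the solve, with the
analytic elementwise tail bound `γ^{kmax+1} Δ^{kmax} / (1 − γΔ)`.

## Navigation and correctness scoring

Greedy descent moves from `i` to the successor `j` minimizing
`R[goal, j]`; comparisons use `Y[goal, j]` directly (same ordering,
since `log_γ` is strictly decreasing, without log-of-underflow
artifacts), ties break to the smallest node id for reproducibility. For
`γ < 1/Δ` every non-goal node has a successor with strictly larger
`Y[goal, ·]`, so the trace reaches the goal without revisiting a node;
on trees the unique cycle-free route is the shortest path.

*Global correctness* is the fraction of all n² ordered pairs (diagonal and
unreachable pairs included — both are predictions the method makes) with
`rounded == exact`. *Local correctness* scores, over ordered (start, goal)
pairs with `start ≠ goal` and the goal reachable, whether the greedy
choice agrees with the same rule run on the exact distances, i.e. whether
the chosen successor attains `min_j D[goal, j]`. On unweighted graphs this
is equivalent to the chosen successor lying on a shortest path (the
minimizing successor always sits at distance `D[goal, start] − 1`). On
real-weighted graphs the two notions genuinely differ — the successor
nearest the goal need not start a cheapest route once its own edge cost is
counted — and the rule-agreement reading is the one under which a dense
1000-node log-uniform-weighted graph scores every one of its ~10⁶
successor choices correct at γ = 10⁻⁸; equality of distances is tested at
1e−9 relative tolerance so exact ties are accepted. Real-weighted graphs
are never scored by integer rounding: `weighted_eval` reports the squared
Pearson correlation between R and the exact distance over finite
off-diagonal pairs, plus the local fraction; integer rounding of weighted
graphs requires discretizing first (`discretize_weights`, which records
the increment ΔW so distances rescale back, with a per-edge error of at
most ΔW/2).

## Analog circuit

The recurrent circuit (one linear unit per node, gain γ, feedback through
A) is simulated by synchronous settling `v ← γ(u + A v)` from `v = 0`.
Only the fixed point `v = γYu` is contractual — the continuous dynamics
are not modeled. Convergence is geometric at rate `ρ(γA)`; divergence is
detected from median residual growth over a 40-step window and reported
as an error naming the cause. Warm-starting from a previous state after
an edge edit re-settles onto the new fixed point (the "always on" use).
Finite analog precision is modeled as i.i.d. multiplicative Gaussian
noise per unit per step with σ = relative precision; mapping σ to the
precision parameter δ one-to-one is this package's choice, meant for
qualitative exploration (majority-vote successor reliability versus
distance), not as a circuit-level noise model.

## Synthetic graphs and what they do (not) show

The generators reproduce the families used to map the gain regimes:
square grids (4-neighbor lattices, the extreme case of redundant shortest
paths — corner multiplicity `C(2M−2, M−1)`), complete binary trees (no
redundancy, logarithmic diameter), Towers-of-Hanoi state graphs (3^disks
states, diameter 2^disks − 1 — long diameters that probe the precision
floor), dense Erdős–Rényi graphs at p = 0.5 (directed or undirected),
and configuration-model power-law graphs (exponent 3, self-loops and
multi-edges collapsed — so realized degree sequences deviate slightly
from the drawn ones). Weighted experiments use independent log-uniform
weights on [1, 100]. These are idealized topologies: real road networks,
mazes, or cognitive task graphs mix degree heterogeneity, weight
correlations, and locality in ways none of these families capture, so
passing regime tests here demonstrates the theory's predictions on clean
exemplars, not performance on any particular application graph.

Default problem sizes in the test harnesses are desk-scale choices:
regime sweeps use grids up to M = 8, binary trees to 7 levels, Hanoi with
5 disks (243 nodes, diameter 31), theorem-guarantee batches of ~100
graphs up to a few hundred nodes each — sized so that `γ^d` stays
representable at the Theorem-guarantee gains (the sufficient bound decays
like `Δ^{-(d−1)}`, so `γ^d` underflows once `d(d−1)·log₂Δ` exceeds 1074;
e.g. path graphs are used up to n = 33). The weighted local-correctness
experiment runs at its full published scale (V = 1000).

## Known limitations

* The global window on trees ends well below the critical gain: for the
  3-node path the exact failure onset is γ = 1/2 ≈ 0.707 γ_c, and for
  complete binary trees the measured edge drifts from 0.69 γ_c (4 levels)
  to 0.55 γ_c (10 levels). Trees still have by far the widest global
  window of any family; "up to the critical gain" is only a log-scale
  approximation.
* With redundant shortest paths, `R − D → 0` only like `ln S / ln γ`, so
  on dense graphs the raw (unrounded) R-distance retains an
  S-dependent offset at any practical gain; rounding absorbs it inside
  the valid window, and correlation-based scoring absorbs it for weighted
  graphs.
* On real-weighted graphs, successors whose best and second-best
  distances differ by less than roughly `ln(multiplicity)/|ln γ|` can be
  mis-ranked at any representable γ; such near-ties are rare in the
  dense log-uniform ensemble but exist.
* Everything is dense O(n²) memory and O(n³) time; that is the method's
  nature, not an implementation shortcut. No fast-matrix-multiplication
  tricks are attempted.
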