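# Methods

## Model

`N` nodes sit at ring positions `0 .. N−1` (node id = position).  Every
unordered pair `(i, j)` is connected independently with probability `p_S`
if its ring distance `d(i,j) = min(|j−i|, N−|j−i|)` is at most `k/2`, and
`p_L = β p_S` otherwise.  Fixing the mean degree at `k` for every `β`
gives `p_S = 1/(1 + β(N−1−k)/k)`.  Admissible parameters: `N ≥ 5`, `k`
even with `2 ≤ k ≤ N−3` (both distance regimes non-empty), `β ∈ [0, 1]`;
`β > 1` (which would make long-range pairs more likely than short-range
ones) is rejected rather than extrapolated, and odd `k` is rejected with
an explicit error.  `k = 2` is allowed; the clustering coefficient is then
0, not an error.

Indexing is 0-based throughout.  All probabilities are evaluated in double
precision; no rational arithmetic is used.

## Samplers

**Two-phase sampler** (`sample_small_world`). Phase one: each node
connects to each of its `k/2` rightmost short-range neighbours with
probability `p_S` (each short pair considered exactly once).  Phase two:
the number of long-range edges is drawn exactly as
`m_L ~ Binomial(N(N−1−k)/2, p_L)` (no Poisson approximation); each edge
picks a source `u` uniformly and a target `v = (u + k/2 + z) mod N` with
`z` uniform on `[1, N−k−1]`.  Every unordered long-range pair is reachable
from either endpoint, so the placement is uniform over long-range pairs.
On a collision with an existing edge the *whole* `(u, z)` draw is
repeated; the loop terminates because `m_L` never exceeds the number of
long-range slots.  The short-range pass consumes the random stream before
the long-range pass, so one integer seed fixes the graph bit-exactly.
Complexity `O(Nk + E[m_L])`.

**Dense oracle** (`sample_small_world_dense`). One Bernoulli trial per
pair, `O(N²)`.  Same law as the fast sampler; kept as the reference
implementation and validated against it by two-sample tests on the
edge-count law and per-distance-class inclusion frequencies.

**Watts–Strogatz comparator** (`sample_watts_strogatz`). Lap-by-lap over
ring offsets `1 .. k/2` (the original ordering): node `u`'s lattice edge
at the current offset is, with probability `p_r`, replaced by an edge from
`u` to a uniform node that is neither `u` nor a current neighbour of `u`
(redraw on conflict; skip if `u` is connected to everyone).  The edge
count is conserved exactly at `Nk/2` and every node keeps its `k/2`
"owned" edges, hence minimum degree `k/2`.  The mapping from the
distance-based model is `p_r = (1−p_S)/(1−p_ER)` with `p_ER = k/(N−1)`,
which matches `1−p_r ≈ p_S` at small `β` and reaches `p_r = 1` at `β = 1`.

Note one property of this dialect: at `p_r = 1` an original lattice edge
survives with probability `≈ (k/2)/(N−1)`, not `1/(N−1)` — after the edge
is removed, each endpoint still has of order `k/2` later rewiring events,
each of which can re-create the pair with probability `~1/(N−1)`.
Measured: 0.00992 ± 0.00008 at `N=512, k=10` over 500 realizations,
against `(k/2)/(N−1) = 0.00979`.  A sometimes-quoted `1/(N−1)` value
counts only a single re-creation chance.

**ER sampler** (`sample_gnp`): one Bernoulli trial per pair.

Antipodal pairs at even `N` (distance exactly `N/2`) are ordinary
long-range pairs whenever `N/2 > k/2`, counted once.

## Triangle summation areas — a correction

Writing the expected triangles per node as
`Δ = F p_S³ + G p_S² p_L + H p_S p_L² + I p_L³`, the coefficients count
the unordered pairs `(u, v)` of the remaining `N−1` nodes by how many of
the three ring distances (u–focal, v–focal, u–v) fall in the short range.
For odd `N > 3k/2` we find

```
F = (3k/8)(k−2)          G = (3k/8)(k+2)
H = (k/8)(12N − 18 − 15k)
I = (1/8)[9k² − k(12N−18) + 4(N²−3N+2)]
```

with `F+G+H+I = (N−1)(N−2)/2` and all four non-negative.  A published
variant gives `H = (k/8)(12N−26−11k)` and
`I = (1/8)[5k² − k(12N−26) + 4(N²−3N+2)]`, i.e. shifts `k(k−2)/2` pairs
from `I` to `H`.  That variant fails two independent checks: exhaustive
classification of all pairs (it miscounts already at `N=11, k=4`, where
the true split is `H=27, I=6`, not `31, 2`) and Monte-Carlo triangle
counts on sampled graphs (2·10⁵ realizations at `N=11, k=4, β=0.5` give
2.7998 ± 0.0034 triangles per node, matching the classification value
960/343 = 2.7988 and excluding the variant's 992/343 = 2.8921 by ~27
standard errors); it also yields a negative `I` at `N=7, k=4`.  The
closed forms above were verified to agree exactly with the exhaustive
classification for every even `k ≤ 20` and odd `N ≤ 401`, plus spot
checks to `N = 2001`.

For odd `N ≤ 3k/2` additional wrap-around interactions among short-range
pairs appear and `summation_areas` transparently falls back to the `O(N²)`
exhaustive classification.  The closed forms are restricted to odd `N`;
even `N` always uses the classification path (`expected_triangles` does
this automatically).  The classification also serves as the test oracle.

**Shape of Δ(β).**  `dΔ/dβ` vanishes identically at `β = 1` (the
`p_S³`-factor decay rate and the polynomial growth rate cancel exactly
there), so Δ is not strictly decreasing: it falls steeply at small `β`,
passes through a shallow minimum below the ER value, and rises by less
than 0.1% of `Δ(1)` (0.07% at `N=101, k=4`; ~10⁻⁶ relative at `N=1001`).
At plotting resolution the curve simply decreases.

## Degree distribution

The convolution of `Binomial(k, p_S)` and `Binomial(N−1−k, p_L)` pmfs,
computed with scipy and `np.convolve` over the full support `0 .. N−1`.
Linear-space convolution of finite pmfs is exact to double precision for
the `N` used here (≲10⁴); probabilities below the underflow threshold are
numerically zero in any representation.  Consistency checks: sum 1, mean
`k`, variance equal to the closed form, collapse to `Binomial(N−1, p)`
at `β = 1` and to a point mass at `β = 0`.

## Average-medium walk

Replacing each edge indicator by its expectation gives the circulant
column-stochastic operator `W_vu = p_{d(v,u)}/k` with first column
`w = (0, p_S…p_S, p_L…p_L, p_S…p_S)/k`.  Its eigenvalues are the DFT of
`w`; the second-largest is `ω₁ = p_S Γ/k − p_L(1+Γ)/k` with
`Γ = 2 Σ_{j=1}^{k/2} cos(2πj/N)`, and `t_mix = 1/(1−ω₁)`.

`ω₁` is the second-largest eigenvalue **by signed value**, not by
magnitude.  At `β = 1` all off-diagonal weights are equal and
`ω₁ = −1/(N−1)`, giving `t_mix = (1 + 1/(N−1))⁻¹ = 1 − 1/N < 1`.  (A
displayed intermediate form `[1 − 1/(N−1)]⁻¹` circulating for this limit
is sign-inconsistent with the final value; the closed form here follows
the spectral-gap definition consistently.)  Standard mixing-time
definitions use `max |ω| ≠ 1`; for small `β` the most negative eigenvalue
can exceed `ω₁` in magnitude only when the spectrum is nearly uniform, and
the signed convention is kept because it is what the closed-form limit
expressions describe.  The master-equation propagator
(`evolve_distribution`) accepts either the circulant weight vector
(evolution by FFT circular convolution) or a sampled graph (explicit
column-stochastic operator); it preserves the L1 norm exactly and warns on
disconnected graphs.

Small-β rates: the clustering ratio is summarized by its dominant factor
`C(β≪1)/C(0) ≈ p_S³ = 1 − 3β(N−k−1)/k + O(β²)` (the exact Δ/∧ ratio has
the same `O(N)` leading rate with an additional `O(N/k²)` correction from
the two-star denominator), while the mixing-time ratio decays as
`1 − β[3N³/(π²(k/2+1)(k+1)k) − N/k + 1/k] + O(β²)`.  The ratio of the two
rates grows as `N²`.

## Mean first passage times

For a connected graph, the MFPT matrix solves the first-step equations
`τ_vu = 1 + Σ_w (A_wu/k_u) τ_vw`, `τ_vv = 0`.  It is computed from the
fundamental matrix `Z = (I − P + 1π)⁻¹` of the walk's Markov chain
(`P` row-stochastic, `π ∝ degree`) as `τ_vu = (Z_vv − Z_uv)/π_v`: one
`O(n³)` factorization yields all `n²` pairs, which the all-pairs PAFPT
needs anyway.  The formula requires only irreducibility, so periodic
(bipartite) graphs are handled.  Validated against hand closed forms
(`τ = d(N−d)` on cycles, `τ = N−1` on complete graphs), the first-step
equations directly, and vectorized Monte-Carlo walkers (10⁵ walks, 3-SE
agreement).

The PAFPT of a disconnected sample is defined on its largest component,
with that component's size in the normalizer; ties between equal-size
components go to the one containing the smallest node id.  Walkers choose
uniformly among neighbours; no lazy steps.

## Ensemble experiment

`run_pafpt_experiment` compares mean PAFPTs of the distance-based model,
the WS comparator at the mapped `p_r(β)`, and optionally `G(N, k/(N−1))`,
with per-cell substreams spawned deterministically from one seed
(bit-exact replay; the metadata sidecar records parameters, seed, the
`p_r` values actually used, and the package version).  The signed relative
difference column is `(mean_WS − mean_modified)/mean_modified`; at
`β = 1, N = 512, k = 10` it is ≈ −6.7% (the distance-based/ER ensembles
have *larger* PAFPT than WS, whose minimum degree `k/2` removes the
low-degree nodes that dominate passage times).  The acceptance script
reports the magnitude of this quantity in percent.

Default scale is 200 realizations per cell — enough to separate the two
models by dozens of standard errors and to give the relative difference a
standard error of ~0.15 percentage points — with `reps` exposed for larger
ensembles.  The default β grid is log-spaced with the `β = 0` endpoint
added, since all the structure is at small β.

## What the validation shows (and does not)

The samplers are validated against the model's own closed forms (moments,
distance-class frequencies, edge-count laws, goodness-of-fit and
two-sample tests at α = 0.001, 4-SE moment bands with a known-mean
variance estimator to avoid the `O(1/N)` bias of the per-graph variance).
This demonstrates internal consistency of sampler and theory under the
model's assumptions — independent pairs, exact ring symmetry, two-level
distance kernel.  Real networks have degree correlations, community
structure and non-uniform spatial embedding that this generator
deliberately does not emulate; conclusions about real systems require the
model only as a null reference.

## Known limitations

* Closed-form areas require odd `N`; even `N` silently uses the `O(N²)`
  classification (slower above `N ~ 10⁴`).
* The mixing time uses the signed-`ω₁` convention (see above); for
  near-ER parameters the magnitude-based mixing time differs at `O(1/N)`.
* `mean_first_passage_times` builds a dense `n × n` inverse: memory
  `O(n²)`, time `O(n³)`; practical to a few thousand nodes.
* The WS sampler is a Python loop over `Nk/2` rewiring events; fine at
  `N = 512`, not tuned for `N ≫ 10⁴`.
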