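"""Closed-form ensemble observables of the distance-based model.

Because every pair is connected independently with a probability that
depends only on its ring distance, the usual network statistics have exact
ensemble expressions:

* degree: the sum of a short-range ``Binomial(k, p_S)`` and a long-range
  ``Binomial(N-1-k, p_L)`` part, hence variance
  ``Var[k] = k p_S (1-p_S) + (N-1-k) p_L (1-p_L)`` and a degree
  distribution given by the convolution of the two binomials;
* two-stars per node ``wedge = (Var[k] + k(k-1)) / 2``;
* triangles per node ``Delta = F p_S^3 + G p_S^2 p_L + H p_S p_L^2 +
  I p_L^3`` where F, G, H, I count the pairs (u, v) around a focal node by
  how many of the three pair distances are short-range (closed forms exist
  for odd N; even N falls back to direct O(N^2) enumeration);
* global clustering ``C = Delta / wedge``, the conditional probability that
  two neighbours of a node are themselves connected.

Empirical per-graph counters (:func:`count_triangles_per_node`,
:func:`count_two_stars_per_node`) provide the Monte-Carlo counterparts used
for validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.stats import binom

from .params import ModelParams, connection_probabilities


def degree_variance(params: ModelParams) -> float:
    """Ensemble degree variance k p_S(1-p_S) + (N-1-k) p_L(1-p_L)."""
    n, k = params.n, params.k
    p = connection_probabilities(params)
    return k * p.p_s * (1 - p.p_s) + (n - 1 - k) * p.p_l * (1 - p.p_l)


def degree_distribution(params: ModelParams) -> np.ndarray:
    """Degree probability vector over degrees 0 .. N-1.

    The convolution of the short-range Binomial(k, p_S) with the long-range
    Binomial(N-1-k, p_L); collapses to a single Binomial(N-1, p) at beta=1
    and to a point mass at k for beta=0.
    """
    n, k = params.n, params.k
    p = connection_probabilities(params)
    pmf_short = binom.pmf(np.arange(k + 1), k, p.p_s)
    pmf_long = binom.pmf(np.arange(n - k), n - 1 - k, p.p_l)
    return np.convolve(pmf_short, pmf_long)  # support 0 .. n-1


def expected_two_stars(params: ModelParams) -> float:
    """Expected two-stars per node, (Var[k] + k(k-1)) / 2.

    A node of degree d sits at the centre of d(d-1)/2 two-stars; taking the
    ensemble expectation yields the formula.
    """
    k = params.k
    return 0.5 * (degree_variance(params) + k * (k - 1))


@dataclass(frozen=True)
class TriangleAreas:
    """Pair counts around a focal node, by connection-probability class.

    ``f``, ``g``, ``h``, ``i`` count the unordered pairs (u, v) of the
    remaining N-1 nodes for which exactly 3, 2, 1 or 0 of the three pair
    distances (u to focal, v to focal, u to v) are short-range.  ``t``,
    ``half_span`` (L = (N-1)/2) and ``reach`` (R = k/2) are the geometric
    quantities of the odd-N derivation: T = (R^2 - R)/2 + R is the
    short-short-long triangle unit.
    """

    f: int
    g: int
    h: int
    i: int
    t: int
    half_span: int
    reach: int

    @property
    def total(self) -> int:
        return self.f + self.g + self.h + self.i


def summation_areas(n: int, k: int) -> TriangleAreas:
    """Triangle summation areas F, G, H, I for odd N.

    Shifting the double sum so the focal node sits at distance 0 turns the
    classification into lattice-point counting on the (u, v) triangle of
    side L = (N-1)/2 with short-range reach R = k/2.  With the
    short-short-long triangle unit T = (R^2 - R)/2 + R, the counts are, for
    odd N > 3k/2 (no wrap-around among short-range pairs):

        F = 3(T - R) = (3k/8)(k - 2)
        G = 3T       = (3k/8)(k + 2)
        H = (k/8)(12N - 18 - 15k)
        I = (1/8)[9k^2 - k(12N - 18) + 4(N^2 - 3N + 2)]

    with F + G + H + I = (N-1)(N-2)/2 and all four non-negative.  These
    closed forms were validated against the exhaustive pair classification
    (:func:`triangle_class_counts`) and against Monte-Carlo triangle counts
    on sampled graphs; a published variant of H and I that shifts
    k(k-2)/2 pairs from I to H fails both checks.  For odd N <= 3k/2
    (dense ring regime, wrap-around present) the exhaustive classification
    is used.  Even N must use :func:`triangle_class_counts` directly.
    """
    if n % 2 == 0:
        raise ValueError(
            "closed-form summation areas require odd N; "
            "use triangle_class_counts for even N"
        )
    if n < k + 3:
        raise ValueError(f"require N >= k + 3, got N={n}, k={k}")
    if k % 2 != 0 or k < 2:
        raise ValueError(f"k must be a positive even integer, got {k}")
    half_span = (n - 1) // 2  # L
    reach = k // 2  # R
    t = (reach * reach - reach) // 2 + reach
    if 2 * n > 3 * k:
        f = 3 * (t - reach)
        g = 3 * t
        h = k * (12 * n - 18 - 15 * k) // 8
        i = (9 * k * k - k * (12 * n - 18) + 4 * (n * n - 3 * n + 2)) // 8
    else:
        f, g, h, i = triangle_class_counts(n, k)
    return TriangleAreas(f=f, g=g, h=h, i=i, t=t, half_span=half_span, reach=reach)


def triangle_class_counts(n: int, k: int) -> tuple[int, int, int, int]:
    """Brute-force (F, G, H, I) by O(N^2) classification of all pairs.

    Counts unordered pairs (u, v) of nodes 1 .. N-1 around focal node 0 by
    how many of d(u,0), d(v,0), d(u,v) are <= k/2.  Valid for any N (odd or
    even); serves as the oracle for the odd-N closed forms and as the
    computation path for even N.
    """
    idx = np.arange(1, n)
    d0 = np.minimum(idx, n - idx)
    short0 = d0 <= k // 2
    diff = np.abs(idx[None, :] - idx[:, None])
    duv_short = np.minimum(diff, n - diff) <= k // 2
    n_short = (
        short0[:, None].astype(np.int64)
        + short0[None, :].astype(np.int64)
        + duv_short.astype(np.int64)
    )
    upper = np.triu_indices(n - 1, k=1)
    counts = np.bincount(n_short[upper], minlength=4)
    # counts[s] = number of pairs with s short-range distances
    return int(counts[3]), int(counts[2]), int(counts[1]), int(counts[0])


def expected_triangles(params: ModelParams) -> float:
    """Expected triangles per node, Delta.

    Sum over all pairs (u, v) around a focal node of
    p_{d(u,0)} p_{d(v,0)} p_{d(u,v)}, grouped by distance class:
    Delta = F p_S^3 + G p_S^2 p_L + H p_S p_L^2 + I p_L^3.  Uses the odd-N
    closed forms where they apply and direct enumeration for even N.
    """
    n, k = params.n, params.k
    if n % 2 == 1:
        areas = summation_areas(n, k)
        f, g, h, i = areas.f, areas.g, areas.h, areas.i
    else:
        f, g, h, i = triangle_class_counts(n, k)
    p = connection_probabilities(params)
    return (
        f * p.p_s**3
        + g * p.p_s**2 * p.p_l
        + h * p.p_s * p.p_l**2
        + i * p.p_l**3
    )


def expected_triangles_enumerated(params: ModelParams) -> float:
    """Delta via the O(N^2) enumeration path regardless of parity (oracle)."""
    f, g, h, i = triangle_class_counts(params.n, params.k)
    p = connection_probabilities(params)
    return (
        f * p.p_s**3
        + g * p.p_s**2 * p.p_l
        + h * p.p_s * p.p_l**2
        + i * p.p_l**3
    )


def clustering_coefficient(params: ModelParams) -> float:
    """Global clustering coefficient C = Delta / wedge.

    The ensemble conditional probability that two neighbours of a node are
    connected.  Limits: C(0) = 3(k-2)/(4(k-1)) (ring lattice; 0 for k=2)
    and C(1) = k/(N-1) (Erdos-Renyi).
    """
    return expected_triangles(params) / expected_two_stars(params)


def clustering_small_beta_ratio(params: ModelParams) -> tuple[float, float]:
    """Small-beta clustering decay ratio C(beta << 1)/C(0) ~ p_S^3.

    Returns ``(ratio, linear)`` where ``ratio = p_S(beta)^3`` is the
    dominant factor governing the decay of clustering at small beta and
    ``linear = 1 - 3 beta (N-k-1)/k`` is its first-order expansion; the two
    differ at O(beta^2).
    """
    n, k, beta = params.n, params.k, params.beta
    p = connection_probabilities(params)
    ratio = p.p_s**3
    linear = 1.0 - 3.0 * beta * (n - k - 1) / k
    return ratio, linear


def count_triangles_per_node(graph: nx.Graph) -> float:
    """Mean number of triangles incident to a node (empirical Delta)."""
    tri = nx.triangles(graph)
    return float(np.mean(list(tri.values())))


def count_two_stars_per_node(graph: nx.Graph) -> float:
    """Mean number of two-stars centred on a node (empirical wedge)."""
    deg = np.array([d for _, d in graph.degree()], dtype=np.int64)
    return float(np.mean(deg * (deg - 1) / 2))
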