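"""Random graph samplers.

Four samplers share one convention: graphs are ``networkx.Graph`` objects on
nodes ``0 .. N-1`` (node id = ring position), and every sampler takes either
an integer seed or a ``numpy.random.Generator``; the same seed with the same
parameters reproduces the identical edge set.

* :func:`sample_small_world` -- efficient two-phase sampler of the
  distance-based model: a Bernoulli pass over the ``N*k/2`` short-range
  pairs, then a binomial number of long-range edges placed uniformly among
  the long-range pairs.  Complexity ``O(N*k + E[m_L])``.
* :func:`sample_small_world_dense` -- O(N^2) reference sampler performing
  one Bernoulli trial per pair; used to validate the fast sampler.
* :func:`sample_watts_strogatz` -- the original rewiring model (comparator).
* :func:`sample_gnp` -- plain Erdos-Renyi G(N, p) for limit checks.
"""

from __future__ import annotations

from typing import Union

import networkx as nx
import numpy as np

from .params import ModelParams, connection_probabilities

RandomSource = Union[int, np.random.Generator, None]


def as_rng(seed: RandomSource) -> np.random.Generator:
    """Coerce an integer seed (or None, or a Generator) into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _empty_graph(n: int) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    return g


def ring_lattice(n: int, k: int) -> nx.Graph:
    """Deterministic k-nearest-neighbour ring lattice (the beta=0 state)."""
    g = _empty_graph(n)
    for offset in range(1, k // 2 + 1):
        for u in range(n):
            g.add_edge(u, (u + offset) % n)
    return g


def sample_small_world(params: ModelParams, rng: RandomSource = None) -> nx.Graph:
    """Sample one realization of the distance-based small-world model.

    Phase one connects each node to each of its ``k/2`` rightmost
    short-range neighbours independently with probability ``p_S``.  Phase
    two draws ``m_L ~ Binomial(N(N-1-k)/2, p_L)`` long-range edges; each is
    placed by choosing a source ``u`` uniformly and a target
    ``v = (u + k/2 + z) mod N`` with ``z`` uniform in ``[1, N-k-1]``,
    redrawing the whole ``(u, z)`` pair whenever the edge already exists.
    """
    rng = as_rng(rng)
    n, k = params.n, params.k
    probs = connection_probabilities(params)
    g = _empty_graph(n)

    # short-range pass (consumes the stream first, fixed order)
    u = np.repeat(np.arange(n), k // 2)
    off = np.tile(np.arange(1, k // 2 + 1), n)
    keep = rng.random(u.size) < probs.p_s
    v = (u + off) % n
    g.add_edges_from(zip(u[keep].tolist(), v[keep].tolist()))

    # long-range pass
    m_l = int(rng.binomial(params.n_long_pairs, probs.p_l))
    half_k = k // 2
    for _ in range(m_l):
        while True:
            src = int(rng.integers(n))
            z = int(rng.integers(1, n - k))  # uniform in [1, N-k-1]
            dst = (src + half_k + z) % n
            if not g.has_edge(src, dst):
                g.add_edge(src, dst)
                break
    return g


def sample_small_world_dense(
    params: ModelParams, rng: RandomSource = None
) -> nx.Graph:
    """O(N^2) oracle sampler: one Bernoulli trial per unordered pair.

    Distributionally identical to :func:`sample_small_world` (same per-pair
    inclusion probabilities, independent pairs); kept as the reference
    implementation for validating the efficient sampler.
    """
    rng = as_rng(rng)
    n, k = params.n, params.k
    probs = connection_probabilities(params)
    iu, ju = np.triu_indices(n, k=1)
    diff = ju - iu
    dist = np.minimum(diff, n - diff)
    p = np.where(dist <= k // 2, probs.p_s, probs.p_l)
    keep = rng.random(p.size) < p
    g = _empty_graph(n)
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return g


def sample_watts_strogatz(
    n: int, k: int, p_r: float, rng: RandomSource = None
) -> nx.Graph:
    """Original Watts-Strogatz rewiring model.

    Starting from the ring lattice, rewiring proceeds lap-by-lap over ring
    offsets ``1 .. k/2``: node ``u``'s lattice edge to its offset-``j``
    rightmost neighbour is, with probability ``p_r``, replaced by an edge
    from ``u`` to a uniformly chosen node that is neither ``u`` nor a
    current neighbour of ``u`` (redraw on conflict).  The edge count stays
    exactly ``N*k/2`` and every node keeps degree at least ``k/2``.
    """
    if k % 2 != 0 or not 2 <= k <= n - 2:
        raise ValueError(f"k must be even with 2 <= k <= n - 2, got k={k}, n={n}")
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"p_r must lie in [0, 1], got {p_r!r}")
    rng = as_rng(rng)
    g = ring_lattice(n, k)
    for offset in range(1, k // 2 + 1):
        for u in range(n):
            if rng.random() >= p_r:
                continue
            if g.degree(u) >= n - 1:
                continue  # no admissible new endpoint
            while True:
                w = int(rng.integers(n))
                if w != u and not g.has_edge(u, w):
                    break
            g.remove_edge(u, (u + offset) % n)
            g.add_edge(u, w)
    return g


def sample_gnp(n: int, p: float, rng: RandomSource = None) -> nx.Graph:
    """Erdos-Renyi G(N, p): each pair present independently with prob. p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    rng = as_rng(rng)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(iu.size) < p
    g = _empty_graph(n)
    g.add_edges_from(zip(iu[keep].tolist(), ju[keep].tolist()))
    return g
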