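"""Parameter algebra of the distance-based small-world model.

The model places ``N`` nodes on a ring and connects every unordered pair
independently with a probability that depends only on the pair's ring
(lattice) distance: short-range pairs (distance ``<= k/2``) connect with
probability ``p_S``, long-range pairs with ``p_L = beta * p_S``.  Requiring
the mean degree to equal ``k`` for every ``beta`` fixes both probabilities:

    p_S * k + p_L * (N - 1 - k) = k
    p_S = 1 / (1 + beta * (N - 1 - k) / k),   p_L = beta * p_S

``beta = 0`` gives the deterministic k-nearest-neighbour ring lattice
(``p_S = 1``, ``p_L = 0``); ``beta = 1`` gives the Erdos-Renyi graph
``G(N, k/(N-1))``.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ModelParams:
    """Parameter triple (N, k, beta) defining one model instance.

    Parameters
    ----------
    n : int
        Number of nodes, at least 5.  Node ids are 0-based and equal to the
        ring positions.
    k : int
        Target mean degree.  Must be even with ``2 <= k <= n - 3`` so that
        both the short-range and the long-range regime are non-empty.
    beta : float
        Long-range redistribution parameter in [0, 1].
    """

    n: int
    k: int
    beta: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 5:
            raise ValueError(f"n must be an integer >= 5, got {self.n!r}")
        if int(self.k) != self.k or self.k % 2 != 0:
            raise ValueError(f"k must be an even integer, got {self.k!r}")
        if not 2 <= self.k <= self.n - 3:
            raise ValueError(
                f"k must satisfy 2 <= k <= n - 3, got k={self.k}, n={self.n}"
            )
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta!r}")

    @property
    def n_short_pairs(self) -> int:
        """Number of short-range unordered pairs, N*k/2."""
        return self.n * self.k // 2

    @property
    def n_long_pairs(self) -> int:
        """Number of long-range unordered pairs, N*(N-1-k)/2."""
        return self.n * (self.n - 1 - self.k) // 2


@dataclass(frozen=True)
class ConnectionProbs:
    """Connection probabilities of one model instance.

    ``p_s`` and ``p_l`` are the short- and long-range edge probabilities;
    ``p_er = k/(N-1)`` is the Erdos-Renyi reference probability reached by
    both at ``beta = 1``.
    """

    p_s: float
    p_l: float
    p_er: float


def lattice_distance(i: int, j: int, n: int) -> int:
    """Ring distance ``d(i, j) = min(|j - i|, N - |j - i|)``.

    A metric on the ring: symmetric, zero iff ``i == j``, bounded by
    ``floor(N / 2)``.
    """
    if not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"node ids must lie in [0, {n}), got ({i}, {j})")
    diff = abs(j - i)
    return min(diff, n - diff)


def connection_probabilities(params: ModelParams) -> ConnectionProbs:
    """Short- and long-range probabilities under mean-degree conservation."""
    n, k, beta = params.n, params.k, params.beta
    p_s = 1.0 / (1.0 + beta * (n - 1 - k) / k)
    return ConnectionProbs(p_s=p_s, p_l=beta * p_s, p_er=k / (n - 1))


def edge_probability(i: int, j: int, params: ModelParams) -> float:
    """Probability that the pair (i, j) is connected: p_S if short-range,
    p_L otherwise."""
    if i == j:
        raise ValueError("self-loops are not part of the model (i == j)")
    probs = connection_probabilities(params)
    if lattice_distance(i, j, params.n) <= params.k // 2:
        return probs.p_s
    return probs.p_l


def ws_rewiring_probability(params: ModelParams) -> float:
    """Map beta to the Watts-Strogatz rewiring probability p_r.

    For small beta the probability that an edge has *not* been rewired,
    ``1 - p_r``, should match the short-range probability ``p_S``; requiring
    ``p_r = 1`` at ``beta = 1`` (where ``p_S = p_ER``) gives

        p_r = (1 - p_S) / (1 - p_ER).
    """
    probs = connection_probabilities(params)
    return (1.0 - probs.p_s) / (1.0 - probs.p_er)
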