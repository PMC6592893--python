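"""Random-walk observables: average-medium spectrum, mixing time, MFPTs.

The discrete-time walk jumps from node ``u`` to a uniformly chosen
neighbour at every step; its distribution obeys the master equation
``phi_v(t) = sum_u (A_vu / k_u) phi_u(t-1)``.  In the *average-medium*
approximation every edge indicator is replaced by its expectation, so the
transition matrix becomes ``W^avg_vu = p_{d(v,u)} / k`` -- a circulant whose
eigenvalues are the DFT of its first column.  The second-largest eigenvalue

    omega_1 = p_S Gamma / k - p_L (1 + Gamma) / k,
    Gamma   = 2 sum_{j=1}^{k/2} cos(2 pi j / N)

gives the mixing time ``t_mix = 1 / (1 - omega_1)``.  omega_1 is taken as
the second largest eigenvalue by *signed* value, so at beta=1 (uniform
off-diagonal weights) omega_1 = -1/(N-1) and t_mix = 1 - 1/N, matching the
average-medium Erdos-Renyi limit.

On sampled graphs, exact mean first passage times tau_vu (expected steps to
first reach v from u) are obtained from the fundamental matrix of the
walk's Markov chain -- one matrix factorization yields all N^2 pairs -- and
averaged into the pair-averaged first passage time (PAFPT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import networkx as nx
import numpy as np
import scipy.linalg

from .params import ModelParams, connection_probabilities


def gamma_factor(n: int, k: int) -> float:
    """Trigonometric sum Gamma = 2 sum_{j=1}^{k/2} cos(2 pi j / N).

    Approaches k - (pi/N)^2 k (k/2+1)(k+1)/3 + O(N^-4) for large N.
    """
    if k % 2 != 0 or not 0 < k < n:
        raise ValueError(f"k must be even with 0 < k < n, got k={k}, n={n}")
    j = np.arange(1, k // 2 + 1)
    return float(2.0 * np.cos(2.0 * np.pi * j / n).sum())


def circulant_weights(params: ModelParams) -> np.ndarray:
    """First column w of the average-medium transition circulant.

    ``w[0] = 0``; offsets at lattice distance <= k/2 carry p_S/k, the rest
    p_L/k.  Entries sum to 1 by mean-degree conservation.
    """
    n, k = params.n, params.k
    p = connection_probabilities(params)
    offs = np.arange(n)
    dist = np.minimum(offs, n - offs)
    w = np.where(dist <= k // 2, p.p_s / k, p.p_l / k)
    w[0] = 0.0
    return w


def average_medium_matrix(params: ModelParams) -> np.ndarray:
    """Explicit N x N circulant W^avg with W[v, u] = p_{d(v,u)} / k."""
    return scipy.linalg.circulant(circulant_weights(params))


def second_eigenvalue(params: ModelParams) -> float:
    """Second-largest (signed) eigenvalue of the average-medium circulant,

    omega_1 = p_S Gamma/k - p_L (1 + Gamma)/k
            = [Gamma - beta (1 + Gamma)] / [k + beta (N - 1 - k)].
    """
    n, k = params.n, params.k
    p = connection_probabilities(params)
    gamma = gamma_factor(n, k)
    return p.p_s * gamma / k - p.p_l * (1.0 + gamma) / k


def mixing_time(params: ModelParams) -> float:
    """Average-medium mixing time t_mix = 1 / (1 - omega_1).

    Limits: t_mix(beta=1) = 1 - 1/N (uniform circulant) and
    t_mix(beta=0) -> 3 N^2 / (pi^2 (k/2+1)(k+1)) for N >> k/2.
    """
    return 1.0 / (1.0 - second_eigenvalue(params))


def mixing_time_small_beta_ratio(params: ModelParams) -> tuple[float, float]:
    """Relative mixing time t_mix(beta)/t_mix(0) at small beta.

    Returns ``(exact, linear)``: the exact ratio from the closed-form
    mixing time, and the first-order expansion

        1 - beta (3 N^3 / (pi^2 (k/2+1)(k+1) k) - N/k + 1/k).

    The linear decay coefficient is O(N^3), two powers of N faster than the
    O(N) decay of the clustering ratio -- the random-search form of the
    small-world effect.
    """
    n, k, beta = params.n, params.k, params.beta
    exact = mixing_time(params) / mixing_time(ModelParams(n, k, 0.0))
    coeff = (
        3.0 * n**3 / (np.pi**2 * (k / 2 + 1) * (k + 1) * k) - n / k + 1.0 / k
    )
    return exact, 1.0 - beta * coeff


@dataclass(frozen=True)
class SpectralSummary:
    """Gamma, omega_1 and t_mix of one average-medium walk."""

    gamma: float
    omega_1: float
    t_mix: float


def spectral_summary(params: ModelParams) -> SpectralSummary:
    return SpectralSummary(
        gamma=gamma_factor(params.n, params.k),
        omega_1=second_eigenvalue(params),
        t_mix=mixing_time(params),
    )


def transition_matrix(graph: nx.Graph, nodelist: Sequence[int] | None = None) -> np.ndarray:
    """Column-stochastic walk operator W[v, u] = A_vu / k_u of a graph."""
    if nodelist is None:
        nodelist = sorted(graph.nodes)
    a = nx.to_numpy_array(graph, nodelist=nodelist)
    deg = a.sum(axis=0)
    if np.any(deg == 0):
        raise ValueError("graph has isolated nodes; the walk is undefined there")
    return a / deg[np.newaxis, :]


def evolve_distribution(
    operator: Union[np.ndarray, nx.Graph],
    phi0: np.ndarray,
    steps: int,
) -> np.ndarray:
    """Propagate a probability vector through the master equation.

    ``operator`` is either a circulant weight vector (as from
    :func:`circulant_weights`; evolution is then a circular convolution per
    step) or a graph (uniform-neighbour walk).  The L1 norm is preserved at
    every step; the stationary law is uniform for the circulant and
    degree-proportional for a graph.
    """
    phi = np.asarray(phi0, dtype=float)
    if not np.isclose(phi.sum(), 1.0, atol=1e-9):
        raise ValueError("phi0 must sum to 1")
    if isinstance(operator, nx.Graph):
        if not nx.is_connected(operator):
            warnings.warn(
                "graph is disconnected; the walk cannot leave the support's "
                "component",
                stacklevel=2,
            )
        w = transition_matrix(operator)
        for _ in range(steps):
            phi = w @ phi
        return phi
    w = np.asarray(operator, dtype=float)
    fw = np.fft.fft(w)
    fphi = np.fft.fft(phi)
    for _ in range(steps):
        fphi = fw * fphi
    return np.real(np.fft.ifft(fphi))


@dataclass(frozen=True)
class PassageTimes:
    """All-pairs mean first passage times of one connected graph.

    ``tau[v_idx, u_idx]`` is the expected number of steps to first reach
    target ``component_nodes[v_idx]`` starting from ``component_nodes[u_idx]``;
    the diagonal is zero.
    """

    component_nodes: tuple[int, ...]
    tau: np.ndarray

    def pair_average(self) -> float:
        """PAFPT: tau averaged over all ordered pairs of distinct nodes."""
        n = len(self.component_nodes)
        if n < 2:
            raise ValueError("pair-averaged FPT needs at least 2 nodes")
        return float(self.tau.sum() / (n * (n - 1)))


def mean_first_passage_times(graph: nx.Graph) -> PassageTimes:
    """Exact MFPT matrix via the fundamental matrix of the walk.

    With row-stochastic ``P[u, v] = A_uv / k_u`` and stationary law
    ``pi_v = k_v / (2m)``, the fundamental matrix ``Z = (I - P + 1 pi)^-1``
    yields ``tau_vu = (Z_vv - Z_uv) / pi_v`` -- the unique solution of the
    first-step equations tau_vu = 1 + sum_w (A_wu/k_u) tau_vw.  One
    factorization serves all pairs.  The chain need not be aperiodic, only
    irreducible, so bipartite graphs are fine.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("MFPT needs at least 2 nodes")
    if not nx.is_connected(graph):
        raise ValueError(
            "graph is disconnected; extract a component first "
            "(see largest_component)"
        )
    nodes = tuple(sorted(graph.nodes))
    a = nx.to_numpy_array(graph, nodelist=nodes)
    deg = a.sum(axis=1)
    p = a / deg[:, np.newaxis]
    pi = deg / deg.sum()
    n = len(nodes)
    z = np.linalg.inv(np.eye(n) - p + np.outer(np.ones(n), pi))
    # tau[v, u] = (Z[v, v] - Z[u, v]) / pi[v]
    tau = (np.diag(z)[:, np.newaxis] - z.T) / pi[:, np.newaxis]
    np.fill_diagonal(tau, 0.0)
    return PassageTimes(component_nodes=nodes, tau=tau)


def pair_averaged_fpt(graph: nx.Graph) -> float:
    """PAFPT of a connected graph: MFPT averaged over ordered pairs."""
    return mean_first_passage_times(graph).pair_average()


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected node set.

    Ties are broken in favour of the component containing the smallest
    node id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = sorted(nx.connected_components(graph), key=lambda c: (-len(c), min(c)))
    return graph.subgraph(comps[0]).copy()
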