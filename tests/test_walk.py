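"""Random-walk observables: spectrum, mixing time, master equation, MFPT."""

import networkx as nx
import numpy as np
import pytest

from conftest import mc_hitting_time
from swring import (
    ModelParams,
    average_medium_matrix,
    circulant_weights,
    evolve_distribution,
    gamma_factor,
    largest_component,
    mean_first_passage_times,
    mixing_time,
    mixing_time_small_beta_ratio,
    pair_averaged_fpt,
    ring_lattice,
    sample_small_world,
    second_eigenvalue,
    transition_matrix,
)


def test_gamma_factor_values():
    assert gamma_factor(4, 2) == pytest.approx(0.0, abs=1e-12)
    assert gamma_factor(6, 4) == pytest.approx(0.0, abs=1e-12)  # cos60 + cos120
    n, k = 1001, 4
    expansion = k - (np.pi / n) ** 2 * k * (k / 2 + 1) * (k + 1) / 3
    # next term of the cosine expansion is (2 pi)^4 sum(j^4) / (12 N^4)
    assert gamma_factor(n, k) == pytest.approx(expansion, abs=5e3 / n**4)
    assert gamma_factor(n, k) < k


def test_circulant_weights_structure():
    params = ModelParams(101, 4, 0.5)
    w = circulant_weights(params)
    assert w[0] == 0.0
    assert w.sum() == pytest.approx(1.0, rel=1e-12)
    assert w[1] == w[2] == w[-1] == w[-2]  # short-range offsets
    assert w[3] == w[50]  # long-range offsets
    assert w[1] > w[3]


def test_second_eigenvalue_limits():
    n, k = 101, 4
    assert second_eigenvalue(ModelParams(n, k, 0.0)) == pytest.approx(
        gamma_factor(n, k) / k, rel=1e-12
    )
    assert second_eigenvalue(ModelParams(n, k, 1.0)) == pytest.approx(
        -1 / (n - 1), rel=1e-12
    )


@pytest.mark.parametrize("n, k, beta", [(101, 4, 0.3), (50, 6, 0.8), (31, 2, 0.1)])
def test_second_eigenvalue_matches_eigensolver(n, k, beta):
    """Closed-form omega_1 equals the numerically diagonalized circulant's
    second-largest (signed) eigenvalue."""
    params = ModelParams(n, k, beta)
    w = average_medium_matrix(params)
    eig = np.sort(np.linalg.eigvalsh(w))[::-1]
    assert eig[0] == pytest.approx(1.0, abs=1e-10)
    assert second_eigenvalue(params) == pytest.approx(eig[1], abs=1e-10)


def test_mixing_time_values_and_monotonicity():
    n, k = 1001, 4
    assert mixing_time(ModelParams(n, k, 1.0)) == pytest.approx(1 - 1 / n, rel=1e-12)
    limit = 3 * n**2 / (np.pi**2 * (k / 2 + 1) * (k + 1))
    assert mixing_time(ModelParams(n, k, 0.0)) == pytest.approx(limit, rel=0.01)
    betas = np.linspace(0, 1, 21)
    tmix = [mixing_time(ModelParams(n, k, b)) for b in betas]
    assert np.all(np.diff(tmix) < 0)


def test_mixing_time_small_beta_ratio_slope():
    n, k, beta = 1001, 4, 1e-11
    exact, linear = mixing_time_small_beta_ratio(ModelParams(n, k, beta))
    coeff = 3 * n**3 / (np.pi**2 * (k / 2 + 1) * (k + 1) * k) - n / k + 1 / k
    assert (1 - linear) / beta == pytest.approx(coeff, rel=1e-12)
    assert (1 - exact) / beta == pytest.approx(coeff, rel=1e-3)


def test_mixing_vs_clustering_rate_scales_as_n_squared():
    """The mixing-time decay coefficient is O(N^3) vs O(N) for clustering:
    their ratio grows as N^2."""
    def slope_ratio(n, k=4):
        t_coeff = 3 * n**3 / (np.pi**2 * (k / 2 + 1) * (k + 1) * k) - n / k + 1 / k
        c_coeff = 3 * (n - k - 1) / k
        return t_coeff / c_coeff

    ratio = slope_ratio(2003) / slope_ratio(1001)
    assert ratio == pytest.approx((2003 / 1001) ** 2, rel=0.02)


def test_evolve_distribution_two_node_path():
    g = nx.path_graph(2)
    phi = evolve_distribution(g, np.array([1.0, 0.0]), 1)
    np.testing.assert_allclose(phi, [0.0, 1.0], atol=1e-14)


def test_evolve_distribution_conserves_probability():
    params = ModelParams(101, 4, 0.5)
    w = circulant_weights(params)
    rng = np.random.default_rng(2)
    phi = rng.random(101)
    phi /= phi.sum()
    for steps in (1, 5, 20):
        out = evolve_distribution(w, phi, steps)
        assert out.sum() == pytest.approx(1.0, rel=1e-12)


def test_evolve_distribution_decay_follows_spectrum():
    """On the circulant, the distance to uniform decays geometrically at
    the sub-dominant eigenvalue magnitude, and the FFT evolution matches
    explicit matrix-vector propagation."""
    params = ModelParams(101, 4, 0.01)  # slow spectrum, decay resolvable
    w = circulant_weights(params)
    n = params.n
    phi0 = np.zeros(n)
    phi0[0] = 1.0
    mat = average_medium_matrix(params)
    eig = np.sort(np.abs(np.linalg.eigvalsh(mat)))
    rate = eig[-2]  # largest non-principal magnitude

    phi_mat = phi0.copy()
    for _ in range(10):
        phi_mat = mat @ phi_mat
    np.testing.assert_allclose(evolve_distribution(w, phi0, 10), phi_mat, atol=1e-12)

    dists = {t: np.abs(evolve_distribution(w, phi0, t) - 1 / n).max()
             for t in (40, 60, 80)}
    assert dists[60] / dists[40] == pytest.approx(rate**20, rel=0.25)
    assert dists[80] / dists[60] == pytest.approx(rate**20, rel=0.25)


def test_evolve_warns_on_disconnected_graph():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (2, 3)])
    with pytest.warns(UserWarning):
        evolve_distribution(g, np.array([1.0, 0, 0, 0]), 1)


def test_transition_operators_are_stochastic():
    params = ModelParams(60, 4, 0.5)
    w = average_medium_matrix(params)
    np.testing.assert_allclose(w.sum(axis=0), 1.0, atol=1e-12)
    g = sample_small_world(params, np.random.default_rng(4))
    g = largest_component(g)
    t = transition_matrix(g)
    np.testing.assert_allclose(t.sum(axis=0), 1.0, atol=1e-12)


def test_mfpt_cycle_closed_form():
    """On the N-cycle, tau between nodes at ring distance d is d(N-d)."""
    for n in (5, 8):
        pt = mean_first_passage_times(ring_lattice(n, 2))
        for u in range(n):
            for v in range(n):
                d = min(abs(u - v), n - abs(u - v))
                assert pt.tau[v, u] == pytest.approx(d * (n - d), rel=1e-10)


def test_mfpt_complete_graph_and_single_edge():
    pt = mean_first_passage_times(nx.complete_graph(4))
    off = pt.tau[~np.eye(4, dtype=bool)]
    np.testing.assert_allclose(off, 3.0, atol=1e-10)  # geometric, mean N-1
    pt = mean_first_passage_times(nx.path_graph(2))
    assert pt.tau[1, 0] == pytest.approx(1.0) and pt.tau[0, 1] == pytest.approx(1.0)


def test_mfpt_satisfies_first_step_equations():
    g = largest_component(
        sample_small_world(ModelParams(30, 4, 0.5), np.random.default_rng(9))
    )
    nodes = sorted(g.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    pt = mean_first_passage_times(g)
    for v in nodes:
        for u in nodes:
            if u == v:
                assert pt.tau[index[v], index[u]] == 0.0
                continue
            rhs = 1 + sum(
                pt.tau[index[v], index[w]] for w in g.neighbors(u)
            ) / g.degree(u)
            assert pt.tau[index[v], index[u]] == pytest.approx(rhs, rel=1e-9)


def test_mfpt_monte_carlo_oracle(rng):
    """Exact solver agrees with simulated hitting times (light version)."""
    c5 = ring_lattice(5, 2)
    mean, se = mc_hitting_time(c5, 0, 1, 20000, rng)
    assert abs(mean - 4.0) < 3 * se


def test_pair_averaged_fpt_values():
    assert pair_averaged_fpt(nx.complete_graph(4)) == pytest.approx(3.0)
    assert pair_averaged_fpt(nx.path_graph(2)) == pytest.approx(1.0)
    assert pair_averaged_fpt(ring_lattice(5, 2)) == pytest.approx(5.0)


def test_pafpt_requires_connected_graph():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (2, 3)])
    with pytest.raises(ValueError):
        pair_averaged_fpt(g)
    single = nx.Graph()
    single.add_node(0)
    with pytest.raises(ValueError):
        mean_first_passage_times(single)


def test_largest_component_selection():
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (3, 4)])
    assert set(largest_component(g).nodes) == {0, 1, 2}
    tie = nx.Graph()
    tie.add_edges_from([(2, 3), (0, 1)])
    assert set(largest_component(tie).nodes) == {0, 1}  # tie-break: node 0
    connected = ring_lattice(6, 2)
    assert set(largest_component(connected).nodes) == set(range(6))
    with pytest.raises(ValueError):
        largest_component(nx.Graph())
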