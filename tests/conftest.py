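"""Shared fixtures and Monte-Carlo oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def mc_hitting_time(
    graph: nx.Graph,
    source: int,
    target: int,
    n_walks: int,
    rng: np.random.Generator,
    max_steps: int = 2_000_000,
) -> tuple[float, float]:
    """Monte-Carlo mean hitting time (and its SE) of a uniform random walk.

    Independent oracle for the exact MFPT solver: simulates ``n_walks``
    walkers from ``source`` until each first reaches ``target``, stepping
    all live walkers in lock-step with vectorized neighbour draws.
    """
    nodes = sorted(graph.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    deg = np.array([graph.degree(u) for u in nodes])
    nbrs = np.zeros((len(nodes), deg.max()), dtype=np.int64)
    for u in nodes:
        for slot, v in enumerate(graph.neighbors(u)):
            nbrs[index[u], slot] = index[v]

    pos = np.full(n_walks, index[source], dtype=np.int64)
    steps = np.zeros(n_walks, dtype=np.int64)
    tgt = index[target]
    alive = pos != tgt
    t = 0
    while alive.any():
        t += 1
        if t > max_steps:
            raise RuntimeError("walkers failed to absorb; graph disconnected?")
        cur = pos[alive]
        choice = (rng.random(cur.size) * deg[cur]).astype(np.int64)
        new = nbrs[cur, choice]
        pos[alive] = new
        hit = new == tgt
        idx = np.flatnonzero(alive)
        steps[idx[hit]] = t
        alive[idx[hit]] = False
    return float(steps.mean()), float(steps.std(ddof=1) / np.sqrt(n_walks))
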