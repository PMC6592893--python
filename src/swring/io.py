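"""Graph serialization: plain edge lists and GraphML.

Edge lists are two-column whitespace-separated files with 0-based ids, one
undirected edge per line with ``u < v``, preceded by ``#`` header lines; the
``# nodes: N`` header preserves isolated nodes across round trips.
"""

from __future__ import annotations

import os
from typing import Union

import networkx as nx

PathLike = Union[str, os.PathLike]

EDGELIST = "edgelist"
GRAPHML = "graphml"


def write_edgelist(graph: nx.Graph, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# nodes: {graph.number_of_nodes()}\n")
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{u}\t{v}\n")


def read_edgelist(path: PathLike) -> nx.Graph:
    g = nx.Graph()
    n_nodes = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("nodes:"):
                    n_nodes = int(body.split(":", 1)[1])
                continue
            u, v = map(int, line.split())
            g.add_edge(u, v)
    if n_nodes is not None:
        g.add_nodes_from(range(n_nodes))
    return g


def write_graphml(graph: nx.Graph, path: PathLike) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path: PathLike) -> nx.Graph:
    g = nx.read_graphml(path, node_type=int)
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(g.edges)
    return out


def write_graph(graph: nx.Graph, path: PathLike, format: str = EDGELIST) -> None:
    """Write a graph as an edge list or GraphML file."""
    if format == EDGELIST:
        write_edgelist(graph, path)
    elif format == GRAPHML:
        write_graphml(graph, path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'edgelist' or 'graphml'")


def read_graph(path: PathLike, format: str = EDGELIST) -> nx.Graph:
    """Read a graph written by :func:`write_graph`."""
    if format == EDGELIST:
        return read_edgelist(path)
    if format == GRAPHML:
        return read_graphml(path)
    raise ValueError(f"unknown format {format!r}; use 'edgelist' or 'graphml'")
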