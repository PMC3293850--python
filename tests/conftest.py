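import itertools

import networkx as nx
import numpy as np
import pytest

from netquant import Graph, figure2_graphs


@pytest.fixture(scope="session")
def figs():
    return figure2_graphs()


def relabel(g: Graph, perm: dict[int, int]) -> Graph:
    """Apply a vertex permutation {old: new} to a graph."""
    return Graph(g.n, [(perm[u], perm[v]) for u, v in g.edges])


def random_permutation(g: Graph, rng) -> dict[int, int]:
    p = rng.permutation(g.n) + 1
    return {v: int(p[v - 1]) for v in g.vertices}


def random_connected_graph(n: int, rng) -> Graph:
    """Random connected graph: a random labeled tree plus extra random edges."""
    prufer = rng.integers(1, n + 1, size=max(n - 2, 0))
    G = nx.from_prufer_sequence([int(x) - 1 for x in prufer]) if n > 2 else nx.path_graph(2)
    edges = {(min(u, v) + 1, max(u, v) + 1) for u, v in G.edges()}
    extra = rng.integers(0, n, size=2 * rng.integers(0, n + 1))
    for i in range(0, len(extra) - 1, 2):
        u, v = int(extra[i]) + 1, int(extra[i + 1]) + 1
        if u != v:
            edges.add((min(u, v), max(u, v)))
    return Graph(n, sorted(edges))


def free_trees(n: int):
    """All non-isomorphic trees on n vertices as Graphs labeled 1..n."""
    if n == 2:
        return [Graph(2, [(1, 2)])]
    return [
        Graph(n, [(u + 1, v + 1) for u, v in t.edges()])
        for t in nx.nonisomorphic_trees(n)
    ]


def brute_force_orbits(g: Graph) -> tuple[int, ...]:
    """Orbit class sizes by exhausting all degree-preserving bijections.

    Independent of the package's orbit code: enumerates every candidate
    permutation (automorphisms must preserve degree, so permutations are
    composed blockwise over equal-degree classes, which keeps the
    enumeration exhaustive) and keeps those mapping edges onto edges.
    """
    edges = set(g.edges)
    by_deg: dict[int, list[int]] = {}
    for v in g.vertices:
        by_deg.setdefault(g.degree(v), []).append(v)
    blocks = list(by_deg.values())
    parent = {v: v for v in g.vertices}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for parts in itertools.product(*(itertools.permutations(b) for b in blocks)):
        mapping = {}
        for block, perm in zip(blocks, parts):
            mapping.update(zip(block, perm))
        if all((min(mapping[u], mapping[v]), max(mapping[u], mapping[v])) in edges
               for u, v in edges):
            for v in g.vertices:
                ru, rv = find(v), find(mapping[v])
                if ru != rv:
                    parent[ru] = rv
    classes: dict[int, int] = {}
    for v in g.vertices:
        r = find(v)
        classes[r] = classes.get(r, 0) + 1
    return tuple(sorted(classes.values(), reverse=True))
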