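"""Descriptors based on degrees and adjacency rather than distances."""

from __future__ import annotations

import math

from .graph_core import DistanceMatrix, Graph, _as_distance
from .values import DescriptorValue

__all__ = [
    "total_adjacency",
    "zagreb1",
    "zagreb2",
    "randic",
    "complexity_index_b",
    "normalized_edge_complexity",
]


def total_adjacency(g: Graph) -> DescriptorValue:
    """Index of total adjacency ``A = 1/2 sum_ij a_ij = m``."""
    return DescriptorValue("totalAdjacency", float(g.m))


def zagreb1(g: Graph) -> DescriptorValue:
    """First Zagreb index ``Z1 = sum_v deg(v)^2``."""
    return DescriptorValue("zagreb1", float(sum(d * d for d in g.degrees)))


def zagreb2(g: Graph) -> DescriptorValue:
    """Second Zagreb index ``Z2 = sum_{(u,v) in E} deg(u) deg(v)``."""
    return DescriptorValue(
        "zagreb2", float(sum(g.degree(u) * g.degree(v) for u, v in g.edges))
    )


def randic(g: Graph) -> DescriptorValue:
    """Randic connectivity index ``R = sum_{(u,v) in E} (deg(u) deg(v))^-1/2``.

    Equals ``n/2`` on every regular graph.  Isolated vertices are
    rejected (their degree would make the edge terms meaningless).
    """
    if any(d == 0 for d in g.degrees):
        raise ValueError("randic is undefined on graphs with isolated vertices")
    return DescriptorValue(
        "randic",
        sum(1.0 / math.sqrt(g.degree(u) * g.degree(v)) for u, v in g.edges),
    )


def complexity_index_b(
    g: Graph, dist: DistanceMatrix | None = None
) -> DescriptorValue:
    """Complexity index B: ``B = sum_v deg(v)/s_v`` (degree over distance degree)."""
    dm = _as_distance(g, dist)
    return DescriptorValue(
        "complexityIndexB",
        float(sum(g.degree(v) / dm.s[v - 1] for v in g.vertices)),
    )


def normalized_edge_complexity(g: Graph) -> DescriptorValue:
    """Normalized edge complexity ``E_N = sum_ij a_ij / n^2 = 2m/n^2``."""
    return DescriptorValue("normalizedEdgeComplexity", 2.0 * g.m / (g.n * g.n))
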