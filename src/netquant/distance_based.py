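"""Descriptors computed from the shortest-path distance matrix.

All operations take ``(g, dist=None)``; when ``dist`` is omitted the
distance matrix is computed internally, so results are identical either
way and callers computing several descriptors for one graph can pay for
the BFS once.
"""

from __future__ import annotations

import math

import numpy as np

from .graph_core import DistanceMatrix, Graph, _as_distance
from .values import DescriptorValue

__all__ = [
    "wiener",
    "harary",
    "balaban_j",
    "compactness",
    "product_of_row_sums",
    "hyper_distance_path",
    "dobrynin",
]


def wiener(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Wiener index ``W = 1/2 sum_ij d_ij``, the sum of all distances.

    A classical branching-sensitive index: among trees on n vertices it
    is maximal for the path and minimal for the star.
    """
    dm = _as_distance(g, dist)
    return DescriptorValue("wiener", float(dm.s.sum()) / 2.0)


def harary(
    g: Graph, dist: DistanceMatrix | None = None, exponent: float = 1.0
) -> DescriptorValue:
    """Harary index ``H = 1/2 sum_{i!=j} d_ij^-exponent``.

    The reciprocal-distance sum; ``exponent=1`` is the default
    convention, ``exponent=2`` gives the squared-reciprocal variant.
    """
    dm = _as_distance(g, dist)
    d = dm.d[np.triu_indices(dm.n, k=1)].astype(float)
    return DescriptorValue("harary", float(np.sum(d**-exponent)))


def balaban_j(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Balaban J index: ``J = m/(gamma+1) * sum_{(u,v) in E} (s_u s_v)^-1/2``."""
    dm = _as_distance(g, dist)
    s = dm.s.astype(float)
    total = sum(1.0 / math.sqrt(s[u - 1] * s[v - 1]) for u, v in g.edges)
    return DescriptorValue("balabanJ", g.m / (g.gamma + 1) * total)


def compactness(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Compactness ``C = 4W / (n(n-1))``.

    Twice the mean inter-vertex distance; equals 2 exactly on complete
    graphs.  The normalization is this package's documented convention
    (see the methods note) — the name alone does not pin one down.
    """
    if g.n < 2:
        raise ValueError("compactness requires n >= 2")
    dm = _as_distance(g, dist)
    w = float(dm.s.sum()) / 2.0
    return DescriptorValue("compactness", 4.0 * w / (g.n * (g.n - 1)))


def product_of_row_sums(
    g: Graph, dist: DistanceMatrix | None = None, log_scale: bool = True
) -> DescriptorValue:
    """Product of distance-matrix row sums, ``PRS = prod_i s_i``.

    The raw product overflows quickly (it grows like ``s^n``), so the
    default returns ``log2(PRS)``; pass ``log_scale=False`` for the raw
    product on small graphs.
    """
    if g.n < 2:
        raise ValueError("product_of_row_sums requires n >= 2")
    dm = _as_distance(g, dist)
    log2prs = float(np.sum(np.log2(dm.s.astype(float))))
    if log_scale:
        return DescriptorValue("productOfRowSums_log2", log2prs)
    return DescriptorValue("productOfRowSums", float(np.prod(dm.s.astype(float))))


def hyper_distance_path(
    g: Graph, dist: DistanceMatrix | None = None
) -> DescriptorValue:
    """Hyper-distance-path index ``D_P = sum_{i<j} (d_ij + d_ij^2)/2``.

    Equals ``W + sum_{i<j} C(d_ij, 2)``; coincides with the Wiener index
    exactly on diameter-1 graphs.
    """
    dm = _as_distance(g, dist)
    d = dm.d[np.triu_indices(dm.n, k=1)].astype(float)
    return DescriptorValue("hyperDistancePath", float(np.sum((d + d * d) / 2.0)))


def dobrynin(
    g: Graph, dist: DistanceMatrix | None = None
) -> dict[str, DescriptorValue]:
    """Distance-degree vertex statistics and their graph aggregates.

    Returns the family of basic distance-based descriptors built from
    vertex eccentricities ``e(v) = max_u d(v, u)`` and distance degrees
    ``s_v = sum_u d(v, u)``:

    ``eccentricity.<v>``, ``distance_degree.<v>``
        per-vertex values;
    ``radius``, ``diameter``, ``average_eccentricity``
        min / max / mean eccentricity;
    ``mean_distance``
        ``2W / (n(n-1))``;
    ``unipolarity``
        ``min_v s_v``;
    ``centralization``
        ``2W - n * min_v s_v``;
    ``variation``
        ``max_v (s_v - min_u s_u)``;
    ``mean_distance_deviation``
        ``(1/n) sum_v |s_v - 2W/n|``.
    """
    dm = _as_distance(g, dist)
    ecc = dm.d.max(axis=1).astype(float)
    s = dm.s.astype(float)
    two_w = float(s.sum())
    n = g.n
    out: dict[str, DescriptorValue] = {}
    for v in g.vertices:
        out[f"eccentricity.{v}"] = DescriptorValue(f"eccentricity.{v}", ecc[v - 1])
        out[f"distance_degree.{v}"] = DescriptorValue(f"distance_degree.{v}", s[v - 1])
    smin = float(s.min())

    def put(name: str, value: float) -> None:
        out[name] = DescriptorValue(name, value)

    put("radius", float(ecc.min()))
    put("diameter", float(ecc.max()))
    put("average_eccentricity", float(ecc.mean()))
    put("mean_distance", two_w / (n * (n - 1)) if n > 1 else 0.0)
    put("unipolarity", smin)
    put("centralization", two_w - n * smin)
    put("variation", float(s.max()) - smin)
    put("mean_distance_deviation", float(np.abs(s - two_w / n).mean()))
    return out
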