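"""Shannon-entropy descriptors over vertex and vertex-pair partitions.

A graph invariant together with an equivalence criterion partitions the
vertices (or vertex pairs) into classes; the Shannon entropy (base 2,
with ``0 log 0 := 0``) of the class-size distribution is then a
structural descriptor.  The partitions used here are automorphism
orbits (topological information content — a *symmetry* measure),
eccentricity classes (radial centric index), degree classes, and the
distance-frequency spectrum (Bonchev-Trinajstic indices).

Orbits are computed exactly: vertices are first split by cheap
invariants (degree, eccentricity, sorted distance row) and classes are
then refined by individualization — two vertices share an orbit iff the
graphs with one vertex distinguished are isomorphic, decided by VF2++.
A brute-force oracle over all permutations backs this in the test-suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .graph_core import DistanceMatrix, Graph, _as_distance
from .values import DescriptorValue, DescriptorWarning

__all__ = [
    "Partition",
    "PartitionEntropyResult",
    "shannon_entropy",
    "vertex_orbits",
    "topological_info_content",
    "bonchev1",
    "bonchev2",
    "bertz",
    "radial_centric",
    "vertex_degree_equality",
    "balabanlike1",
    "balabanlike2",
    "graph_vertex_complexity",
    "BALABANLIKE2_TABLE_REFERENCE",
]


@dataclass(frozen=True)
class Partition:
    """Disjoint classes covering a universe of ``universe_size`` elements."""

    classes: tuple[frozenset, ...]
    universe_size: int

    def __post_init__(self):
        total = sum(len(c) for c in self.classes)
        if total != self.universe_size:
            raise ValueError(
                f"classes cover {total} elements, expected {self.universe_size}"
            )
        union = set().union(*self.classes) if self.classes else set()
        if len(union) != total:
            raise ValueError("partition classes are not disjoint")

    @property
    def sizes(self) -> tuple[int, ...]:
        """Class cardinalities, largest first."""
        return tuple(sorted((len(c) for c in self.classes), reverse=True))


@dataclass(frozen=True)
class PartitionEntropyResult:
    """Entropy (bits) of a partition's class-size distribution."""

    entropy: float
    partition: Partition


def shannon_entropy(sizes: Sequence[int], total: int) -> float:
    """Shannon entropy (bits) of the distribution ``sizes/total``.

    ``0 log 0 := 0``; class sizes must be positive and sum to ``total``.
    """
    sizes = list(sizes)
    if any(s <= 0 for s in sizes):
        raise ValueError("class sizes must be positive")
    if sum(sizes) != total or total <= 0:
        raise ValueError(f"class sizes sum to {sum(sizes)}, expected {total}")
    return -sum((s / total) * math.log2(s / total) for s in sizes)


# ---------------------------------------------------------------------------
# Automorphism orbits
# ---------------------------------------------------------------------------


def _marked_copy(g: nx.Graph, certs: dict[int, int], special: int) -> nx.Graph:
    h = g.copy()
    for v in h.nodes():
        h.nodes[v]["c"] = certs[v]
    h.nodes[special]["c"] = -1  # individualized vertex
    return h


def vertex_orbits(g: Graph, max_n: int = 2000) -> Partition:
    """Exact automorphism-group orbits of the vertex set.

    Vertices in one orbit are structurally interchangeable: some
    automorphism maps one to the other.  ``max_n`` bounds the exact
    computation (the pairwise VF2++ checks are worst-case exponential,
    though fast on everything a descriptor study encounters).
    """
    if g.n > max_n:
        raise ValueError(f"exact orbit computation bounded at n <= {max_n}")
    nxg = g.to_networkx()
    # cheap invariant certificates: orbits always refine these classes
    if g.n > 1 and g.is_connected():
        d = _as_distance(g, None).d
        raw = {
            v: (g.degree(v), tuple(sorted(d[v - 1].tolist()))) for v in g.vertices
        }
    else:
        raw = {
            v: (g.degree(v), tuple(sorted(g.degree(u) for u in nxg.neighbors(v))))
            for v in g.vertices
        }
    cert_ids: dict = {}
    certs = {v: cert_ids.setdefault(raw[v], len(cert_ids)) for v in g.vertices}
    groups: dict[int, list[int]] = {}
    for v in g.vertices:
        groups.setdefault(certs[v], []).append(v)

    classes: list[list[int]] = []
    for members in groups.values():
        reps: list[tuple[int, nx.Graph, list[int]]] = []
        for v in members:
            gv = _marked_copy(nxg, certs, v)
            for _, gr, cls in reps:
                if nx.vf2pp_is_isomorphic(gv, gr, node_label="c"):
                    cls.append(v)
                    break
            else:
                reps.append((v, gv, [v]))
        classes.extend(cls for _, _, cls in reps)
    return Partition(tuple(frozenset(c) for c in classes), g.n)


def topological_info_content(
    g: Graph, dist: DistanceMatrix | None = None
) -> PartitionEntropyResult:
    """Topological information content: entropy of the orbit partition.

    ``I_orb = -sum_k (|O_k|/n) log2(|O_k|/n)`` over automorphism orbits
    ``O_k``.  Zero exactly for vertex-transitive graphs; a symmetry
    measure rather than a branching measure.  The result carries the
    orbit partition itself (class sizes are reported alongside the
    entropy, mirroring common usage).
    """
    g.require_connected()
    part = vertex_orbits(g)
    return PartitionEntropyResult(shannon_entropy(part.sizes, g.n), part)


# ---------------------------------------------------------------------------
# Distance-spectrum and degree entropies
# ---------------------------------------------------------------------------


def bonchev1(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Bonchev-Trinajstic information index on distance equality.

    Total form over the ``K = n(n-1)/2`` unordered pairs grouped by
    distance value: ``I_D = K log2 K - sum_k g_k log2 g_k``.
    """
    if g.n < 2:
        raise ValueError("bonchev1 requires n >= 2")
    dm = _as_distance(g, dist)
    k_tot = g.n * (g.n - 1) // 2
    val = k_tot * math.log2(k_tot) - sum(c * math.log2(c) for c in dm.g.values())
    return DescriptorValue("bonchev1", val)


def bonchev2(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Bonchev-Trinajstic information index on distance magnitudes.

    ``I_D^W = W log2 W - sum_k g_k * k * log2 k`` with ``W`` the Wiener
    index and ``g_k`` the number of pairs at distance ``k``.
    """
    if g.n < 2:
        raise ValueError("bonchev2 requires n >= 2")
    dm = _as_distance(g, dist)
    w = float(dm.s.sum()) / 2.0
    val = w * math.log2(w) - sum(c * k * math.log2(k) for k, c in dm.g.items() if k > 1)
    return DescriptorValue("bonchev2", val)


def bertz(g: Graph) -> DescriptorValue:
    """Bertz complexity (degree-based variant): ``2m log2(2m) - sum_v deg(v) log2 deg(v)``."""
    if g.m < 1:
        raise ValueError("bertz requires at least one edge")
    two_m = 2 * g.m
    val = two_m * math.log2(two_m) - sum(
        d * math.log2(d) for d in g.degrees if d > 0
    )
    return DescriptorValue("bertz", val)


def _entropy_of_grouping(values, universe, name: str) -> PartitionEntropyResult:
    groups: dict = {}
    for v, key in zip(universe, values):
        groups.setdefault(key, []).append(v)
    part = Partition(tuple(frozenset(c) for c in groups.values()), len(universe))
    return PartitionEntropyResult(shannon_entropy(part.sizes, len(universe)), part)


def radial_centric(
    g: Graph, dist: DistanceMatrix | None = None
) -> PartitionEntropyResult:
    """Radial centric information index: entropy of eccentricity classes."""
    dm = _as_distance(g, dist)
    ecc = dm.d.max(axis=1)
    return _entropy_of_grouping(ecc.tolist(), list(g.vertices), "radialCentric")


def vertex_degree_equality(g: Graph) -> PartitionEntropyResult:
    """Entropy of equal-degree vertex classes (zero on regular graphs)."""
    return _entropy_of_grouping(g.degrees, list(g.vertices), "vertexDegree")


# ---------------------------------------------------------------------------
# Balaban-like information indices
# ---------------------------------------------------------------------------

#: Published reference values of the Balaban-like index X for the six
#: example trees a..f.  UNVERIFIED: the local invariant x_i used by the
#: original implementation is not stated in any source available to this
#: package, and the shipped default (x_i = u_i) does not reproduce this
#: row.  Kept for documentation; no test asserts it.
BALABANLIKE2_TABLE_REFERENCE: tuple[float, ...] = (
    0.5979,
    0.6932,
    0.8190,
    1.0492,
    1.1452,
    1.8204,
)


def _u_invariant(dm: DistanceMatrix) -> np.ndarray:
    """Local information on distance magnitudes.

    ``u_i = s_i log2 s_i - sum_j d_ij log2 d_ij``; zero when every
    distance from ``i`` equals 1 and ``s_i = 1`` (only on K2).
    """
    d = dm.d.astype(float)
    s = dm.s.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dlogd = np.where(d > 0, d * np.log2(np.where(d > 0, d, 1.0)), 0.0)
    return s * np.log2(s) - dlogd.sum(axis=1)


def _balaban_like(g: Graph, x: np.ndarray, name: str) -> DescriptorValue:
    if np.any(x <= 0):
        warnings.warn(
            f"{name}: graphs with |V| < 3 (or any zero local invariant) "
            "result in: Inf!",
            DescriptorWarning,
            stacklevel=3,
        )
        return DescriptorValue(name, math.inf)
    total = sum(1.0 / math.sqrt(x[u - 1] * x[v - 1]) for u, v in g.edges)
    return DescriptorValue(name, g.m / (g.gamma + 1) * total)


def balabanlike1(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Balaban-like information index U.

    J-type edge sum over the local information invariant ``u_i``:
    ``U = m/(gamma+1) sum_{(i,j) in E} (u_i u_j)^-1/2``.  When any
    ``u_i`` is zero (|V| < 3) the index is infinite; a flagged ``inf``
    is returned together with a warning instead of raising.
    """
    dm = _as_distance(g, dist)
    return _balaban_like(g, _u_invariant(dm), "balabanlike1")


def balabanlike2(g: Graph, dist: DistanceMatrix | None = None) -> DescriptorValue:
    """Balaban-like information index X.

    The construction mirrors :func:`balabanlike1` with a second local
    invariant ``x_i``.  The exact ``x_i`` of the original formulation is
    not recoverable from available sources, so the shipped default uses
    ``x_i = u_i`` and therefore degenerates to the U index; see
    :data:`BALABANLIKE2_TABLE_REFERENCE` and the methods note.  The same
    infinity policy applies.
    """
    dm = _as_distance(g, dist)
    return _balaban_like(g, _u_invariant(dm), "balabanlike2")


def graph_vertex_complexity(
    g: Graph, dist: DistanceMatrix | None = None
) -> DescriptorValue:
    """Graph vertex complexity: mean per-vertex distance-distribution entropy.

    For each vertex ``i`` let ``n_ik`` be the number of vertices at
    distance ``k`` (``n_i0 = 1``); ``v_i`` is the entropy of
    ``n_ik / n`` and ``I_V = (1/n) sum_i v_i``.
    """
    dm = _as_distance(g, dist)
    n = g.n
    total = 0.0
    for i in range(n):
        _, counts = np.unique(dm.d[i], return_counts=True)
        p = counts / n
        total += float(-(p * np.log2(p)).sum())
    return DescriptorValue("graphVertexComplexity", total / n)
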