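"""Graph representation, I/O and shortest-path machinery.

Every descriptor in this package operates on a simple, undirected,
connected graph with contiguous integer vertex labels ``1..n``.  The
:class:`Graph` class enforces those invariants at construction time so the
descriptor modules never have to re-validate their input.  All-pairs
shortest-path (hop-count) distances are exposed through
:class:`DistanceMatrix`, which also carries the derived quantities that
distance-based descriptors share: the per-vertex distance degrees
``s_i = sum_j d_ij``, the diameter ``rho`` and the distance-frequency
spectrum ``g_k`` (number of unordered vertex pairs at distance ``k``).

The module also ships the six seven-vertex example trees used throughout
the documentation and test-suite (:func:`figure2_graphs`), plain-text and
GraphML readers/writers, and seeded generators for standard graph
families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "DistanceMatrix",
    "GraphCollection",
    "GraphValidationError",
    "GraphConnectivityError",
    "build_graph",
    "distance_matrix",
    "figure2_graphs",
    "read_graph",
    "write_graph",
    "path_graph",
    "star_graph",
    "cycle_graph",
    "complete_graph",
    "random_tree",
    "erdos_renyi",
]


class GraphValidationError(ValueError):
    """Raised when an input does not describe a valid simple labeled graph."""


class GraphConnectivityError(ValueError):
    """Raised when a connected graph is required but the input is not."""


class Graph:
    """A simple undirected graph with vertex labels ``1..n``.

    Parameters
    ----------
    n:
        Number of vertices; labels are the integers ``1..n``.
    edges:
        Iterable of unordered label pairs.  Self-loops, duplicate edges
        and out-of-range labels are rejected.

    Attributes
    ----------
    n, m:
        Vertex and edge counts.
    edges:
        Tuple of edges as sorted ``(u, v)`` pairs, in sorted order.
    gamma:
        Cyclomatic number ``m - n + 1`` (number of independent cycles;
        0 exactly for trees).  Only meaningful for connected graphs.
    """

    __slots__ = ("n", "edges", "m", "_degrees", "_nx", "_connected")

    def __init__(self, n: int, edges: Iterable[tuple[int, int]]):
        if n < 1:
            raise GraphValidationError(f"vertex count must be >= 1, got {n}")
        norm: list[tuple[int, int]] = []
        seen: set[tuple[int, int]] = set()
        for e in edges:
            try:
                u, v = e
            except (TypeError, ValueError):
                raise GraphValidationError(f"edge {e!r} is not a pair") from None
            u, v = int(u), int(v)
            if u == v:
                raise GraphValidationError(f"self-loop on vertex {u} is not allowed")
            if not (1 <= u <= n) or not (1 <= v <= n):
                raise GraphValidationError(
                    f"edge ({u}, {v}) has an endpoint outside 1..{n}"
                )
            key = (min(u, v), max(u, v))
            if key in seen:
                raise GraphValidationError(f"duplicate edge ({key[0]}, {key[1]})")
            seen.add(key)
            norm.append(key)
        self.n = n
        self.edges = tuple(sorted(norm))
        self.m = len(self.edges)
        degs = [0] * (n + 1)
        for u, v in self.edges:
            degs[u] += 1
            degs[v] += 1
        self._degrees = tuple(degs[1:])
        self._nx = None
        self._connected = None

    # -- basic accessors -------------------------------------------------

    @property
    def vertices(self) -> range:
        return range(1, self.n + 1)

    def degree(self, v: int) -> int:
        if not 1 <= v <= self.n:
            raise GraphValidationError(f"vertex {v} outside 1..{self.n}")
        return self._degrees[v - 1]

    @property
    def degrees(self) -> tuple[int, ...]:
        """Degree sequence in vertex-label order."""
        return self._degrees

    @property
    def gamma(self) -> int:
        return self.m - self.n + 1

    def to_networkx(self) -> nx.Graph:
        if self._nx is None:
            g = nx.Graph()
            g.add_nodes_from(self.vertices)
            g.add_edges_from(self.edges)
            self._nx = g
        return self._nx

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        """Convert an arbitrary-labeled networkx graph, relabeling to 1..n."""
        if g.is_directed():
            raise GraphValidationError("directed graphs are not supported")
        nodes = sorted(g.nodes(), key=lambda x: (isinstance(x, str), x))
        idx = {v: i + 1 for i, v in enumerate(nodes)}
        return cls(len(nodes), [(idx[u], idx[v]) for u, v in g.edges()])

    def is_connected(self) -> bool:
        if self._connected is None:
            self._connected = self.n == 1 or nx.is_connected(self.to_networkx())
        return self._connected

    def require_connected(self) -> None:
        if not self.is_connected():
            raise GraphConnectivityError("graph must be connected")

    # -- dunder ----------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Graph)
            and self.n == other.n
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.n, self.edges))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, m={self.m})"


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs hop-count distances of a connected graph.

    Attributes
    ----------
    d:
        ``n x n`` symmetric integer array, ``d[i, j]`` the shortest-path
        length between vertices ``i+1`` and ``j+1``.
    s:
        Distance degrees: ``s[i] = sum_j d[i, j]`` (row sums).
    rho:
        Diameter, the largest entry of ``d``.
    g:
        Distance-frequency spectrum ``{k: number of unordered pairs at
        distance k}`` for ``k = 1..rho``; the counts sum to ``n(n-1)/2``.
    """

    d: np.ndarray
    s: np.ndarray = field(init=False, repr=False)
    rho: int = field(init=False)
    g: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self):
        d = np.asarray(self.d)
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "s", d.sum(axis=1))
        object.__setattr__(self, "rho", int(d.max()) if d.size else 0)
        ks, counts = np.unique(d[np.triu_indices(d.shape[0], k=1)], return_counts=True)
        object.__setattr__(
            self, "g", {int(k): int(c) for k, c in zip(ks, counts) if k > 0}
        )

    @property
    def n(self) -> int:
        return self.d.shape[0]

    def row(self, v: int) -> np.ndarray:
        """Distance row of vertex ``v`` (1-based label)."""
        return self.d[v - 1]


def build_graph(n: int, edges: Iterable[tuple[int, int]]) -> Graph:
    """Construct a validated :class:`Graph` (see class docstring)."""
    return Graph(n, edges)


def distance_matrix(g: Graph) -> DistanceMatrix:
    """BFS-exact all-pairs shortest-path distances of a connected graph."""
    g.require_connected()
    n = g.n
    d = np.zeros((n, n), dtype=np.int64)
    lengths = dict(nx.all_pairs_shortest_path_length(g.to_networkx()))
    for u in g.vertices:
        row = lengths[u]
        for v, dist in row.items():
            d[u - 1, v - 1] = dist
    return DistanceMatrix(d)


def _as_distance(g: Graph, dist: DistanceMatrix | None) -> DistanceMatrix:
    """Shared "optional precomputed distance matrix" contract.

    Every descriptor taking ``dist=None`` computes the matrix internally;
    passing a precomputed one must give identical results (and saves the
    repeated BFS when computing many descriptors for one graph).
    """
    if dist is None:
        return distance_matrix(g)
    if dist.n != g.n:
        raise GraphValidationError(
            f"distance matrix is {dist.n}x{dist.n} but the graph has {g.n} vertices"
        )
    return dist


class GraphCollection:
    """An ordered collection of uniquely-identified graphs."""

    def __init__(self, items: Iterable[tuple[str, Graph]] = ()):  # noqa: D107
        self._ids: list[str] = []
        self._graphs: dict[str, Graph] = {}
        for gid, g in items:
            self.add(gid, g)

    def add(self, gid: str, g: Graph) -> None:
        if gid in self._graphs:
            raise GraphValidationError(f"duplicate graph identifier {gid!r}")
        self._ids.append(gid)
        self._graphs[gid] = g

    def __len__(self) -> int:
        return len(self._ids)

    def __iter__(self) -> Iterator[tuple[str, Graph]]:
        return ((gid, self._graphs[gid]) for gid in self._ids)

    def __getitem__(self, gid: str) -> Graph:
        return self._graphs[gid]

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._ids)


# ---------------------------------------------------------------------------
# Example fixtures
# ---------------------------------------------------------------------------

_FIGURE2_EDGES: dict[str, tuple[tuple[int, int], ...]] = {
    # Six trees on 7 vertices, ordered from the path (a) to the star (f);
    # branching (number of terminal vertices) increases along the series.
    "a": ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7)),
    "b": ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (2, 7)),
    "c": ((1, 2), (2, 3), (3, 4), (4, 5), (2, 6), (4, 7)),
    "d": ((1, 2), (2, 3), (1, 4), (4, 5), (1, 6), (1, 7)),
    "e": ((1, 2), (1, 3), (1, 4), (1, 5), (2, 6), (2, 7)),
    "f": ((1, 2), (1, 3), (1, 4), (1, 5), (1, 6), (1, 7)),
}


def figure2_graphs() -> GraphCollection:
    """The six 7-vertex example trees, keyed ``"a"`` .. ``"f"``.

    These are reconstructions from published invariant values (Wiener
    index, orbit entropy, parametric entropy and per-vertex functional
    values), not machine-read drawings; the labeling of each tree was
    chosen to match the published per-vertex output ordering.  The
    test-suite re-derives every one of those invariants from these edge
    lists.
    """
    return GraphCollection(
        (key, Graph(7, edges)) for key, edges in _FIGURE2_EDGES.items()
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _read_edgelist(path: Path) -> Graph:
    n_declared: int | None = None
    edges: list[tuple[int, int]] = []
    labels: set[int] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("n="):
            if edges or n_declared is not None:
                raise GraphValidationError(
                    f"{path}:{lineno}: 'n=' header must be the first record"
                )
            n_declared = int(line[2:])
            continue
        parts = line.split()
        if len(parts) != 2:
            raise GraphValidationError(
                f"{path}:{lineno}: expected two labels, got {line!r}"
            )
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise GraphValidationError(
                f"{path}:{lineno}: non-integer vertex label in {line!r}"
            ) from None
        edges.append((u, v))
        labels.update((u, v))
    if not edges:
        raise GraphValidationError(f"{path}: no edges found")
    n = n_declared if n_declared is not None else max(labels)
    if min(labels) < 1 or max(labels) > n:
        raise GraphValidationError(f"{path}: vertex labels must lie in 1..{n}")
    return Graph(n, edges)


def _read_graphml(path: Path) -> Graph:
    g = nx.read_graphml(path)
    if g.is_directed():
        raise GraphValidationError(f"{path}: directed GraphML is not supported")
    for _, _, attrs in g.edges(data=True):
        if "weight" in attrs:
            raise GraphValidationError(
                f"{path}: weighted edges are not supported; descriptors are "
                "defined on unweighted graphs"
            )
    try:
        mapping = {v: int(v) for v in g.nodes()}
    except (TypeError, ValueError):
        raise GraphValidationError(
            f"{path}: node ids must be integer labels 1..n"
        ) from None
    n = len(mapping)
    if sorted(mapping.values()) != list(range(1, n + 1)):
        raise GraphValidationError(f"{path}: node ids must be contiguous 1..n")
    return Graph(n, [(mapping[u], mapping[v]) for u, v in g.edges()])


def read_graph(path: str | Path, format: str = "edgelist") -> Graph:
    """Read one undirected unweighted graph from ``path``.

    ``format`` is ``"edgelist"`` (whitespace-separated pairs, ``#``
    comments, optional leading ``n=<count>`` line) or ``"graphml"``.
    """
    path = Path(path)
    if format == "edgelist":
        return _read_edgelist(path)
    if format == "graphml":
        return _read_graphml(path)
    raise GraphValidationError(f"unknown graph format {format!r}")


def write_graph(g: Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write ``g`` so that :func:`read_graph` round-trips it identically."""
    path = Path(path)
    if format == "edgelist":
        lines = [f"n={g.n}"] + [f"{u}\t{v}" for u, v in g.edges]
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        h = nx.Graph()
        h.add_nodes_from(str(v) for v in g.vertices)
        h.add_edges_from((str(u), str(v)) for u, v in g.edges)
        nx.write_graphml(h, path)
    else:
        raise GraphValidationError(f"unknown graph format {format!r}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise GraphValidationError(msg)


def path_graph(n: int) -> Graph:
    _require(n >= 2, "path_graph requires n >= 2")
    return Graph(n, [(i, i + 1) for i in range(1, n)])


def star_graph(n: int) -> Graph:
    """Star on ``n`` vertices: center 1, leaves 2..n."""
    _require(n >= 2, "star_graph requires n >= 2")
    return Graph(n, [(1, k) for k in range(2, n + 1)])


def cycle_graph(n: int) -> Graph:
    _require(n >= 3, "cycle_graph requires n >= 3")
    return Graph(n, [(i, i + 1) for i in range(1, n)] + [(n, 1)])


def complete_graph(n: int) -> Graph:
    _require(n >= 2, "complete_graph requires n >= 2")
    return Graph(n, [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)])


def random_tree(n: int, seed: int) -> Graph:
    """Uniform random labeled tree on ``n`` vertices via a Prüfer sequence."""
    _require(n >= 2, "random_tree requires n >= 2")
    if n == 2:
        return Graph(2, [(1, 2)])
    rng = np.random.default_rng(seed)
    prufer = rng.integers(1, n + 1, size=n - 2)
    degree = [1] * (n + 1)
    for x in prufer:
        degree[x] += 1
    edges = []
    # classic decoding: repeatedly join the smallest leaf to the next code entry
    import heapq

    leaves = [v for v in range(1, n + 1) if degree[v] == 1]
    heapq.heapify(leaves)
    for x in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, int(x)))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, int(x))
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return Graph(n, edges)


def erdos_renyi(n: int, p: float, seed: int, max_retries: int = 1000) -> Graph:
    """Connected G(n, p) sample; resamples until connected (bounded retries)."""
    _require(n >= 2, "erdos_renyi requires n >= 2")
    _require(0 < p <= 1, "erdos_renyi requires 0 < p <= 1")
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)]
    for _ in range(max_retries):
        mask = rng.random(len(pairs)) < p
        g = Graph(n, [e for e, keep in zip(pairs, mask) if keep])
        if g.is_connected():
            return g
    raise GraphValidationError(
        f"no connected G({n}, {p}) sample within {max_retries} retries"
    )
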