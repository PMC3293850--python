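import math

import numpy as np
import pytest

from netquant import (
    DescriptorWarning,
    balabanlike1,
    balabanlike2,
    bertz,
    bonchev1,
    bonchev2,
    build_graph,
    complete_graph,
    cycle_graph,
    distance_matrix,
    graph_vertex_complexity,
    path_graph,
    radial_centric,
    shannon_entropy,
    star_graph,
    topological_info_content,
    vertex_degree_equality,
    vertex_orbits,
)

from conftest import (
    brute_force_orbits,
    free_trees,
    random_connected_graph,
    random_permutation,
    relabel,
)

K2 = build_graph(2, [(1, 2)])
P3 = path_graph(3)
P7 = path_graph(7)
S7 = star_graph(7)


class TestShannonEntropy:
    def test_star_orbit_distribution(self):
        assert shannon_entropy([6, 1], 7) == pytest.approx(0.5917, abs=5e-5)

    def test_single_class_is_zero(self):
        assert shannon_entropy([7], 7) == 0.0

    def test_uniform_is_log_n(self):
        assert shannon_entropy([1] * 7, 7) == pytest.approx(math.log2(7))

    def test_size_mismatch(self):
        with pytest.raises(ValueError):
            shannon_entropy([3, 3], 7)


class TestVertexOrbits:
    def test_figure2_c(self, figs):
        assert vertex_orbits(figs["c"]).sizes == (4, 2, 1)

    def test_complete_graph_single_orbit(self):
        assert vertex_orbits(complete_graph(5)).sizes == (5,)

    def test_seven_path(self):
        assert vertex_orbits(P7).sizes == (2, 2, 2, 1)

    def test_against_brute_force_on_free_trees(self):
        for n in range(2, 9):
            for t in free_trees(n):
                assert vertex_orbits(t).sizes == brute_force_orbits(t)

    def test_against_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            g = random_connected_graph(int(rng.integers(4, 8)), rng)
            assert vertex_orbits(g).sizes == brute_force_orbits(g)

    def test_against_igraph_cross_check(self, figs):
        igraph = pytest.importorskip("igraph")
        for _, g in figs:
            ig = igraph.Graph(n=g.n, edges=[(u - 1, v - 1) for u, v in g.edges])
            gens = ig.automorphism_group()
            parent = list(range(g.n))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for perm in gens:
                for i, j in enumerate(perm):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
            sizes: dict[int, int] = {}
            for v in range(g.n):
                r = find(v)
                sizes[r] = sizes.get(r, 0) + 1
            assert vertex_orbits(g).sizes == tuple(
                sorted(sizes.values(), reverse=True)
            )

    def test_orbits_refine_degree_and_eccentricity_partitions(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            g = random_connected_graph(int(rng.integers(4, 9)), rng)
            dm = distance_matrix(g)
            ecc = dm.d.max(axis=1)
            for cls in vertex_orbits(g).classes:
                assert len({g.degree(v) for v in cls}) == 1
                assert len({int(ecc[v - 1]) for v in cls}) == 1


class TestTopologicalInfoContent:
    def test_figure2_c_six_decimals(self, figs):
        res = topological_info_content(figs["c"])
        assert res.entropy == pytest.approx(1.378783, abs=5e-7)
        assert res.partition.sizes == (4, 2, 1)

    def test_star(self, figs):
        assert topological_info_content(figs["f"]).entropy == pytest.approx(
            0.5917, abs=5e-5
        )

    def test_vertex_transitive_is_zero(self):
        assert topological_info_content(complete_graph(6)).entropy == 0.0
        assert topological_info_content(cycle_graph(8)).entropy == 0.0

    def test_isomorphism_invariance(self, figs):
        rng = np.random.default_rng(31)
        for _, g in figs:
            h = relabel(g, random_permutation(g, rng))
            assert topological_info_content(h).entropy == pytest.approx(
                topological_info_content(g).entropy, abs=1e-12
            )


@pytest.mark.parametrize(
    "func, graph, expected",
    [
        (bonchev1, K2, 0.0),
        (bonchev1, P3, 3 * math.log2(3) - 2.0),
        (bonchev1, S7, 21 * math.log2(21) - 6 * math.log2(6) - 15 * math.log2(15)),
        (bonchev2, K2, 0.0),
        (bonchev2, P3, 6.0),
        (bonchev2, S7, 36 * math.log2(36) - 30.0),
        (bertz, K2, 2.0),
        (bertz, S7, 12 * math.log2(12) - 6 * math.log2(6)),
        (bertz, P3, 6.0),
        (graph_vertex_complexity, K2, 1.0),
    ],
)
def test_value_descriptor_examples(func, graph, expected):
    assert float(func(graph)) == pytest.approx(expected, rel=1e-10)


def test_graph_vertex_complexity_star():
    assert float(graph_vertex_complexity(S7)) == pytest.approx(1.0692, abs=5e-5)


def test_bertz_requires_edges():
    with pytest.raises(ValueError):
        bertz(build_graph(1, []))


class TestPartitionDescriptors:
    def test_radial_centric(self, figs):
        assert radial_centric(S7).entropy == pytest.approx(0.5917, abs=5e-5)
        assert radial_centric(P7).entropy == pytest.approx(1.9502, abs=5e-5)
        assert radial_centric(complete_graph(5)).entropy == 0.0

    def test_vertex_degree_equality(self):
        assert vertex_degree_equality(S7).entropy == pytest.approx(0.5917, abs=5e-5)
        assert vertex_degree_equality(P7).entropy == pytest.approx(0.8631, abs=5e-5)
        assert vertex_degree_equality(cycle_graph(6)).entropy == 0.0


class TestBalabanLike:
    def test_k2_infinite_with_warning(self):
        with pytest.warns(DescriptorWarning, match="Inf"):
            v = balabanlike1(K2)
        assert math.isinf(float(v)) and v.flag == "infinite"

    def test_k2_infinite_balabanlike2(self):
        with pytest.warns(DescriptorWarning):
            v = balabanlike2(K2)
        assert math.isinf(float(v))

    def test_star_u_value(self):
        u_center = 6 * math.log2(6)
        u_leaf = 11 * math.log2(11) - 10.0
        expected = 6 * 6 / math.sqrt(u_center * u_leaf)
        assert float(balabanlike1(S7)) == pytest.approx(expected, rel=1e-12)
        assert float(balabanlike1(S7)) == pytest.approx(1.7259, abs=5e-5)

    def test_path_u_value(self):
        assert float(balabanlike1(P7)) == pytest.approx(1.0195, abs=5e-5)

    def test_balabanlike2_default_degenerates_to_u(self):
        assert float(balabanlike2(P7)) == float(balabanlike1(P7))

    def test_vertex_transitive_finite(self):
        v = float(balabanlike2(cycle_graph(6)))
        assert math.isfinite(v) and v > 0


def test_all_partition_entropies_bounded():
    rng = np.random.default_rng(41)
    for _ in range(20):
        g = random_connected_graph(int(rng.integers(3, 10)), rng)
        for h in (
            topological_info_content(g).entropy,
            radial_centric(g).entropy,
            vertex_degree_equality(g).entropy,
        ):
            assert -1e-12 <= h <= math.log2(g.n) + 1e-12
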