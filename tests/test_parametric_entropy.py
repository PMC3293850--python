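import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netquant import (
    CoefficientScheme,
    build_graph,
    coefficients,
    cycle_graph,
    dehmer_entropy,
    distance_matrix,
    functional_degree_degree,
    functional_pathlength,
    functional_sphere,
    functional_vertcent,
    j_spheres,
    kl_divergence,
    path_graph,
    star_graph,
)

from conftest import random_connected_graph, random_permutation, relabel


class TestJSpheres:
    def test_star_center(self):
        assert j_spheres(star_graph(7), 1) == (6, 0)

    def test_figure2_c_center(self, figs):
        assert j_spheres(figs["c"], 3) == (2, 4, 0, 0)

    def test_figure2_c_path_end(self, figs):
        assert j_spheres(figs["c"], 1) == (1, 2, 1, 2)

    def test_counts_sum_to_n_minus_one(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = random_connected_graph(int(rng.integers(3, 12)), rng)
            for v in g.vertices:
                assert sum(j_spheres(g, v)) == g.n - 1

    def test_unknown_vertex(self):
        with pytest.raises(ValueError):
            j_spheres(path_graph(4), 9)


class TestCoefficients:
    def test_exponential_rho4(self):
        # pinned by published per-vertex functional values (six decimals)
        w = coefficients("exponential", 4).weights
        assert w == pytest.approx((4.0, 1.471518, 0.541341, 0.199148), abs=5e-7)

    def test_constant(self):
        assert coefficients("constant", 3).weights == (1.0, 1.0, 1.0)

    def test_linear(self):
        assert coefficients("linear", 2).weights == (2.0, 1.0)

    def test_quadratic(self):
        assert coefficients("quadratic", 3).weights == (9.0, 4.0, 1.0)

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="unknown coefficient scheme"):
            coefficients("cubic", 3)

    def test_custom_validation(self):
        with pytest.raises(ValueError, match="positive"):
            CoefficientScheme("custom", (1.0, -1.0))
        with pytest.raises(ValueError, match="non-increasing"):
            CoefficientScheme("custom", (1.0, 2.0))


class TestFunctionals:
    def test_sphere_reproduces_published_fvis(self, figs):
        g = figs["c"]
        f = functional_sphere(g, coefficients("exp", 4))
        expected = (7.882673, 14.554200, 13.886071, 14.554200,
                    7.882673, 7.882673, 7.882673)
        assert f == pytest.approx(expected, abs=5e-7)

    def test_vertex_transitive_gives_uniform_fvis(self):
        g = cycle_graph(6)
        dm = distance_matrix(g)
        c = coefficients("linear", dm.rho)
        for func in (functional_sphere, functional_pathlength,
                     functional_vertcent, functional_degree_degree):
            f = func(g, c, dm)
            assert np.allclose(f, f[0])

    def test_sphere_linear_in_coefficients(self, figs):
        g = figs["c"]
        c = coefficients("exp", 4)
        c3 = CoefficientScheme("custom", tuple(3.0 * w for w in c.weights))
        assert functional_sphere(g, c3) == pytest.approx(
            3.0 * functional_sphere(g, c)
        )

    def test_pathlength_star_center_constant(self):
        f = functional_pathlength(star_graph(7), coefficients("constant", 2))
        assert f[0] == 6.0  # center: 6 neighbours at path length 1

    def test_degree_degree_k2(self):
        f = functional_degree_degree(
            build_graph(2, [(1, 2)]), coefficients("constant", 1)
        )
        assert f.tolist() == [1.0, 1.0]

    def test_coefficient_length_mismatch(self, figs):
        with pytest.raises(ValueError, match="diameter"):
            functional_sphere(figs["c"], coefficients("constant", 2))


class TestDehmerEntropy:
    def test_worked_example_graph_c(self, figs):
        res = dehmer_entropy(figs["c"], "sphere", "exp", lam=2500)
        assert res.entropy == pytest.approx(2.743221, abs=5e-7)
        assert res.distance == pytest.approx(160.3339, abs=1e-3)
        assert res.pis[:4] == pytest.approx(
            (0.1057720, 0.1952924, 0.1863273, 0.1952924), abs=5e-8
        )
        assert sum(res.pis) == pytest.approx(1.0, abs=1e-9)

    def test_table_row(self, figs):
        expected = {"a": 2.7648, "c": 2.7432, "e": 2.7305, "f": 2.7391}
        for key, want in expected.items():
            assert dehmer_entropy(figs[key]).entropy == pytest.approx(
                want, abs=5e-5
            )

    def test_uniform_on_vertex_transitive(self):
        res = dehmer_entropy(cycle_graph(5), "sphere", "constant")
        assert res.entropy == pytest.approx(math.log2(5), rel=1e-12)
        assert res.distance == pytest.approx(0.0, abs=1e-9)

    def test_lambda_invariance_of_entropy(self, figs):
        r1 = dehmer_entropy(figs["b"], lam=1.0)
        r2 = dehmer_entropy(figs["b"], lam=9999.0)
        assert r1.entropy == r2.entropy

    def test_coefficient_scale_invariance(self, figs):
        g = figs["d"]
        c = coefficients("exp", distance_matrix(g).rho)
        ct = CoefficientScheme("custom", tuple(7.5 * w for w in c.weights))
        assert dehmer_entropy(g, coeff=ct).entropy == pytest.approx(
            dehmer_entropy(g, coeff=c).entropy, abs=1e-12
        )

    def test_entropy_bounds_and_distance_sign(self):
        rng = np.random.default_rng(19)
        for _ in range(15):
            g = random_connected_graph(int(rng.integers(3, 12)), rng)
            for funct in ("sphere", "pathlength", "vertcent", "degree"):
                res = dehmer_entropy(g, funct, "linear")
                assert -1e-12 <= res.entropy <= math.log2(g.n) + 1e-12
                assert res.distance >= -1e-9

    def test_isomorphism_invariance(self, figs):
        rng = np.random.default_rng(29)
        for _, g in figs:
            h = relabel(g, random_permutation(g, rng))
            assert dehmer_entropy(h).entropy == pytest.approx(
                dehmer_entropy(g).entropy, abs=1e-12
            )

    def test_invalid_lambda(self, figs):
        with pytest.raises(ValueError, match="lambda"):
            dehmer_entropy(figs["a"], lam=0.0)


class TestKLDivergence:
    def test_identical_distributions(self):
        assert kl_divergence([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_worked_value(self):
        assert kl_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.2075, abs=5e-5
        )

    def test_support_violation(self):
        with pytest.raises(ValueError, match="positive"):
            kl_divergence([0.5, 0.5], [1.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8),
           st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
    def test_non_negativity(self, a, b):
        k = min(len(a), len(b))
        p = np.array(a[:k]) / sum(a[:k])
        q = np.array(b[:k]) / sum(b[:k])
        assert kl_divergence(p, q) >= -1e-12
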