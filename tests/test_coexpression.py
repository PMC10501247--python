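import networkx as nx
import numpy as np
import pandas as pd
import pytest

from famnet.coexpression import (NullDistribution, binomial_shift_test,
                                 build_network, classify_edges,
                                 coexpression_analysis, empirical_pvalue,
                                 pairwise_correlations,
                                 sample_null_distribution)
from famnet.errors import (InconsistentUniverseError, InvalidInputError,
                           UndefinedCorrelationError)


def _expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(values,
                        index=[f"{prefix}{i}" for i in range(values.shape[0])],
                        columns=[f"s{j}" for j in range(values.shape[1])])


class TestPairwiseCorrelations:
    def test_self_pair_is_one(self, rng):
        expr = _expr(rng.normal(size=(2, 10)))
        out = pairwise_correlations(expr, [("g0", "g0")])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_symmetry(self, rng):
        expr = _expr(rng.normal(size=(2, 10)))
        r_ab = pairwise_correlations(expr, [("g0", "g1")]).loc[0, "r"]
        r_ba = pairwise_correlations(expr, [("g1", "g0")]).loc[0, "r"]
        assert r_ab == pytest.approx(r_ba)

    def test_planted_rho_within_fisher_interval(self, rng):
        # 99% Fisher-z interval for rho=0.9 at n=200 is about [0.80, 0.96]
        from famnet.synthetic import sample_correlated_pair
        x, y = sample_correlated_pair(0.9, 200, np.random.default_rng(7))
        expr = _expr(np.vstack([x, y]))
        r = pairwise_correlations(expr, [("g0", "g1")]).loc[0, "r"]
        assert 0.80 <= r <= 0.96

    def test_constant_gene_rejected(self):
        expr = _expr([[1, 1, 1, 1], [1, 2, 3, 4]])
        with pytest.raises(UndefinedCorrelationError):
            pairwise_correlations(expr, [("g0", "g1")])

    def test_matches_numpy_corrcoef(self, rng):
        expr = _expr(rng.normal(size=(4, 30)))
        pairs = [("g0", "g1"), ("g2", "g3"), ("g1", "g3")]
        out = pairwise_correlations(expr, pairs)
        for k, (a, b) in enumerate(pairs):
            expected = np.corrcoef(expr.loc[a], expr.loc[b])[0, 1]
            assert out.loc[k, "r"] == pytest.approx(expected)


class TestSampleNullDistribution:
    def test_two_gene_pool_forced_pair(self, rng):
        expr = _expr(rng.normal(size=(2, 20)))
        null = sample_null_distribution(expr, ["g0", "g1"], n_pairs=1, seed=0)
        expected = abs(np.corrcoef(expr.loc["g0"], expr.loc["g1"])[0, 1])
        assert null.values[0] == pytest.approx(expected)

    def test_seeded_determinism(self, rng):
        expr = _expr(rng.normal(size=(30, 25)))
        genes = list(expr.index)
        n1 = sample_null_distribution(expr, genes, 100, seed=5)
        n2 = sample_null_distribution(expr, genes, 100, seed=5)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_null_median_matches_theory(self, rng):
        # median |r| under the null ~ 0.6745 / sqrt(n - 1)
        n = 100
        expr = _expr(rng.normal(size=(200, n)))
        null = sample_null_distribution(expr, list(expr.index), 10000, seed=1)
        assert abs(np.median(null.values) - 0.6745 / np.sqrt(n - 1)) < 0.01

    def test_small_pool_rejected(self, rng):
        expr = _expr(rng.normal(size=(1, 10)))
        with pytest.raises(InvalidInputError):
            sample_null_distribution(expr, ["g0"], 10)

    def test_values_sorted_in_unit_interval(self, rng):
        expr = _expr(rng.normal(size=(20, 15)))
        null = sample_null_distribution(expr, list(expr.index), 50, seed=2)
        assert (np.diff(null.values) >= 0).all()
        assert null.values.min() >= 0 and null.values.max() <= 1


class TestEmpiricalPvalue:
    def _null(self):
        return NullDistribution("c", np.arange(1, 11) / 10.0, 10)

    def test_above_all_null_values(self):
        assert empirical_pvalue(1.5, self._null()) == 0.0

    def test_zero_observation(self):
        assert empirical_pvalue(0.0, self._null()) == 1.0

    def test_hand_count(self):
        assert empirical_pvalue(0.55, self._null()) == pytest.approx(0.5)

    def test_tie_counts_toward_numerator(self):
        assert empirical_pvalue(0.5, self._null()) == pytest.approx(0.6)

    def test_sign_ignored(self):
        assert empirical_pvalue(-0.55, self._null()) == pytest.approx(0.5)


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "p_cancer", "p_normal"])


class TestBuildNetwork:
    def test_all_insignificant_empty(self):
        edges = _edges([("a", "b", 0.5, 0.5), ("b", "c", 0.5, 0.5)])
        assert build_network(edges, 0.01, "cancer").number_of_edges() == 0

    def test_boundary_excluded(self):
        edges = _edges([("a", "b", 0.01, 1.0)])
        assert build_network(edges, 0.01, "cancer").number_of_edges() == 0

    def test_handshake_lemma(self):
        edges = _edges([("a", "b", 0.0, 1), ("b", "c", 0.0, 1), ("a", "c", 0.0, 1)])
        net = build_network(edges, 0.01, "cancer")
        assert net.number_of_edges() == 3
        assert sum(dict(net.degree).values()) == 6

    def test_invariant_to_input_order(self):
        rows = [("a", "b", 0.001, 1), ("b", "c", 0.5, 1), ("c", "d", 0.005, 1)]
        net1 = build_network(_edges(rows), 0.01, "cancer")
        net2 = build_network(_edges(rows[::-1]), 0.01, "cancer")
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))


class TestClassifyEdges:
    def test_partition_arithmetic(self):
        universe = [(f"a{i}", f"b{i}") for i in range(10)]
        cancer = nx.Graph([universe[0], universe[1], universe[2], universe[5]])
        normal = nx.Graph([universe[3], universe[4], universe[5]])
        out = classify_edges(cancer, normal, universe)
        counts = out["status"].value_counts()
        assert counts["cancer_only"] == 3
        assert counts["normal_only"] == 2
        assert counts["shared"] == 1
        assert counts["insignificant"] == 4
        assert counts.sum() == len(universe)

    def test_shared_and_insignificant(self):
        universe = [("a", "b"), ("c", "d")]
        both = nx.Graph([("a", "b")])
        out = classify_edges(both, both.copy(), universe)
        assert list(out["status"]) == ["shared", "insignificant"]

    def test_foreign_edge_rejected(self):
        with pytest.raises(InconsistentUniverseError):
            classify_edges(nx.Graph([("x", "y")]), nx.Graph(), [("a", "b")])


class TestBinomialShiftTest:
    def test_eight_vs_two(self):
        p, direction = binomial_shift_test(8, 2)
        assert p == pytest.approx(112 / 1024)
        assert direction == "none"

    def test_symmetric_case(self):
        p, direction = binomial_shift_test(5, 5)
        assert p == pytest.approx(1.0)
        assert direction == "none"

    def test_extreme_increase(self):
        p, direction = binomial_shift_test(20, 0)
        assert p == pytest.approx(2 * 0.5**20)
        assert direction == "increase"

    def test_extreme_decrease(self):
        p, direction = binomial_shift_test(0, 20)
        assert direction == "decrease"

    def test_no_edges_is_no_test(self):
        p, direction = binomial_shift_test(0, 0)
        assert np.isnan(p) and direction == "none"


class TestCoexpressionAnalysis:
    def test_planted_pair_classified_cancer_only(self, rng):
        from famnet.synthetic import sample_correlated_pair
        n = 60
        fam_c = rng.normal(size=(6, n))
        fam_n = rng.normal(size=(6, n))
        fam_c[0], fam_c[1] = sample_correlated_pair(0.95, n, rng)
        bg_c = rng.normal(size=(100, n))
        bg_n = rng.normal(size=(100, n))
        fam = [f"FAM{i}" for i in range(6)]
        bg = [f"BG{i}" for i in range(100)]
        expr_c = pd.DataFrame(np.vstack([fam_c, bg_c]), index=fam + bg,
                              columns=[f"c{j}" for j in range(n)])
        expr_n = pd.DataFrame(np.vstack([fam_n, bg_n]), index=fam + bg,
                              columns=[f"n{j}" for j in range(n)])
        edges, comp = coexpression_analysis(expr_c, expr_n, fam, bg,
                                            n_null_pairs=2000, seed=3)
        row = edges[(edges["gene_a"] == "FAM0") & (edges["gene_b"] == "FAM1")]
        assert row["status"].iloc[0] == "cancer_only"
        assert comp.n_shared <= min(comp.n_cancer_edges, comp.n_normal_edges)
        counts = edges["status"].value_counts()
        assert counts.sum() == len(edges) == 15
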