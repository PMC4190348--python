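"""Co-expression network, connectivity permutation, temporal clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from _oracles import complete_linkage_heights_naive, pearson_hand
from rxnet.coexpression import (
    UndefinedVarianceError,
    build_network,
    complete_linkage_heights,
    connectivity_score,
    correlation_matrix,
    degree_fc_correlation,
    hierarchical_cluster,
    permutation_connectivity,
    write_edge_table,
    write_graphml,
    write_sif,
)
from rxnet.expression import ExpressionMatrix, InvalidInputError, zscore_rows
from rxnet.synthetic import make_timecourse


def logmat(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.DataFrame(rows, dtype=float).T,
                            units="log2rpkm")


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        m = logmat({"a": [1, 2, 3, 5], "b": [2, 2, 4, 6], "c": [9, 1, 4, 4]})
        corr = correlation_matrix(m)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr.values, corr.values.T)

    def test_perfect_antilinear_pair(self):
        x = [1.0, 2.0, 3.0, 4.0]
        m = logmat({"x": x, "y": [-2 * v + 7 for v in x]})
        corr = correlation_matrix(m)
        assert corr.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_pearson_value(self):
        m = logmat({"a": [1, 2, 3, 5], "b": [2, 2, 4, 6]})
        corr = correlation_matrix(m)
        expected = pearson_hand([1, 2, 3, 5], [2, 2, 4, 6])  # 0.96833
        assert corr.loc["a", "b"] == pytest.approx(expected, abs=1e-9)
        assert corr.loc["a", "b"] == pytest.approx(0.96833, abs=5e-6)

    def test_constant_row_recorded_as_zero_with_warning(self):
        m = logmat({"a": [1, 2, 3], "flat": [4, 4, 4]})
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(m)
        assert corr.loc["a", "flat"] == 0.0
        assert corr.loc["flat", "flat"] == 1.0

    def test_too_few_stages_rejected(self):
        with pytest.raises(InvalidInputError):
            correlation_matrix(logmat({"a": [1, 2], "b": [2, 1]}))


def toy_corr(r_ab):
    genes = ["a", "b", "c"]
    R = np.eye(3)
    R[0, 1] = R[1, 0] = r_ab
    R[0, 2] = R[2, 0] = 0.1
    R[1, 2] = R[2, 1] = -0.2
    return pd.DataFrame(R, index=genes, columns=genes)


class TestBuildNetwork:
    @pytest.mark.parametrize(
        "r,has_edge,sign",
        [(0.95, True, 1), (-0.951, True, -1), (0.9499, False, 0)],
    )
    def test_inclusive_threshold_and_sign(self, r, has_edge, sign):
        net = build_network(toy_corr(r))
        assert net.has_edge("a", "b") is has_edge
        if has_edge:
            assert net.edges["a", "b"]["sign"] == sign
            assert net.edges["a", "b"]["r"] == pytest.approx(r)

    def test_isolated_genes_excluded(self):
        net = build_network(toy_corr(0.96))
        assert set(net.nodes) == {"a", "b"}  # c never reaches the threshold

    def test_gene_reordering_leaves_edges_unchanged(self):
        corr = toy_corr(0.97)
        net1 = build_network(corr, genes=["a", "b", "c"])
        net2 = build_network(corr, genes=["c", "b", "a"])
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))


class TestConnectivityScore:
    def test_identical_profiles_score_one(self):
        m = logmat({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4], "c": [1, 2, 3, 4]})
        corr = correlation_matrix(m)
        assert connectivity_score(["a", "b", "c"], corr) == pytest.approx(1.0)

    def test_absolute_value_of_negative_correlation(self):
        corr = toy_corr(-0.95)
        assert connectivity_score(["a", "b"], corr) == pytest.approx(0.95)

    def test_four_gene_toy_mean_over_six_pairs(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 6))
        m = ExpressionMatrix(
            values=pd.DataFrame(X, index=list("abcd")), units="log2rpkm")
        corr = correlation_matrix(m)
        genes = list("abcd")
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        expected = np.mean([abs(corr.iloc[i, j]) for i, j in pairs])
        assert connectivity_score(genes, corr) == pytest.approx(expected)

    def test_singleton_rejected(self):
        with pytest.raises(InvalidInputError):
            connectivity_score(["a"], toy_corr(0.5))


class TestPermutationConnectivity:
    @pytest.fixture(scope="class")
    def sim_corr(self):
        sim = make_timecourse(220, module_sizes=(20, 0, 0),
                              within_module_corr=0.97, seed=2)
        corr = correlation_matrix(sim.matrix)
        labels = pd.Series(sim.truth.module_labels)
        module = sorted(labels.index[labels == "group1"])
        return corr, module

    def test_whole_background_geneset_gives_p_one(self, sim_corr):
        corr, _ = sim_corr
        genes = list(corr.index)
        res = permutation_connectivity(genes, genes, corr, n_perm=50, seed=1)
        assert res.p == 1.0

    def test_planted_module_beats_every_null_draw(self, sim_corr):
        corr, module = sim_corr
        res = permutation_connectivity(module, list(corr.index), corr,
                                       n_perm=200, seed=4)
        assert res.observed > res.null_values.max()
        assert res.p == 0.0  # count/n convention

    def test_add_one_estimator_never_returns_zero(self, sim_corr):
        corr, module = sim_corr
        res = permutation_connectivity(module, list(corr.index), corr,
                                       n_perm=200, seed=4,
                                       estimator="add_one")
        assert res.p == pytest.approx(1 / 201)

    def test_identical_seed_identical_null(self, sim_corr):
        corr, module = sim_corr
        a = permutation_connectivity(module, list(corr.index), corr,
                                     n_perm=100, seed=7)
        b = permutation_connectivity(module, list(corr.index), corr,
                                     n_perm=100, seed=7)
        assert np.array_equal(a.null_values, b.null_values)
        assert a.p == b.p

    def test_null_p_values_are_uniform(self):
        # random gene sets from a structureless background: empirical p
        # should be uniform on {0, 1/n, ..., 1}
        sim = make_timecourse(150, module_sizes=(0, 0, 0), seed=11)
        corr = correlation_matrix(sim.matrix)
        genes = list(corr.index)
        rng = np.random.default_rng(13)
        ps = []
        for rep in range(200):
            pick = list(rng.choice(genes, size=8, replace=False))
            res = permutation_connectivity(pick, genes, corr, n_perm=200,
                                           seed=int(rng.integers(2**31)))
            ps.append(res.p)
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.12  # 1% critical value for n = 200 is ~0.116


class TestDegreeFoldChange:
    def test_equal_degrees_are_undefined(self):
        net = build_network(toy_corr(0.99))
        with pytest.raises(UndefinedVarianceError):
            degree_fc_correlation(net, {"a": 1.0, "b": 2.0})

    def test_linear_relation_gives_r_one(self):
        import networkx as nx

        net = nx.Graph()
        net.add_edges_from([("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")])
        fc = {n: 0.5 * net.degree[n] + 1 for n in net.nodes}
        r, slope, intercept = degree_fc_correlation(net, fc)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(1.0)

    def test_five_node_toy_matches_hand_formula(self):
        import networkx as nx

        net = nx.Graph()
        net.add_edges_from(
            [("a", "b"), ("a", "c"), ("a", "d"), ("a", "e"), ("b", "c")]
        )
        fc = {"a": 3.1, "b": 1.4, "c": 2.0, "d": 0.3, "e": 0.9}
        nodes = sorted(net.nodes)
        deg = [net.degree[n] for n in nodes]
        expected = pearson_hand(deg, [fc[n] for n in nodes])
        r, _, _ = degree_fc_correlation(net, fc)
        assert r == pytest.approx(expected, abs=1e-12)


class TestHierarchicalClustering:
    def _z(self, X, ids=None):
        ids = ids or [f"g{i}" for i in range(len(X))]
        m = ExpressionMatrix(values=pd.DataFrame(X, index=ids),
                             units="log2rpkm")
        return zscore_rows(m)

    def test_duplicate_rows_merge_at_height_zero(self):
        X = [[0, 1, 2, 3], [0, 1, 2, 3], [9, 1, 0, 2]]
        heights = complete_linkage_heights(self._z(X))
        assert heights[0] == pytest.approx(0.0)

    def test_k_equals_n_gives_singletons(self):
        X = [[0, 1, 2, 3], [5, 1, 2, 0], [9, 1, 0, 2]]
        groups = hierarchical_cluster(self._z(X), k=3)
        assert groups.nunique() == 3

    def test_merge_heights_match_bruteforce_on_five_points(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(5, 4))
        z = self._z(X.tolist())
        got = sorted(complete_linkage_heights(z))
        expected = sorted(
            complete_linkage_heights_naive(z.values.to_numpy()))
        assert np.allclose(got, expected)

    def test_recovers_planted_temporal_groups(self):
        from sklearn.metrics import adjusted_rand_score

        sim = make_timecourse(70, module_sizes=(20, 25, 25),
                              within_module_corr=0.97, seed=17)
        labels = pd.Series(sim.truth.module_labels)
        z = zscore_rows(sim.matrix)
        groups = hierarchical_cluster(z, k=3)
        assert adjusted_rand_score(labels, groups) >= 0.9

    def test_groups_ordered_by_peak_time(self):
        sim = make_timecourse(60, module_sizes=(20, 20, 20),
                              within_module_corr=1.0, noise_sd=0.0, seed=1)
        z = zscore_rows(sim.matrix)
        groups = hierarchical_cluster(z, k=3)
        labels = pd.Series(sim.truth.module_labels)
        # group2 (mid-course pulse) peaks before group1 (late ramp-up)
        X = z.values.to_numpy()
        peak = {}
        for g in [1, 2, 3]:
            peak[g] = np.mean(np.argmax(X[(groups == g).to_numpy()], axis=1))
        assert peak[1] <= peak[2] <= peak[3]

    def test_invalid_k_rejected(self):
        z = self._z([[0, 1, 2], [3, 1, 0]], ids=["a", "b"])
        with pytest.raises(InvalidInputError):
            hierarchical_cluster(z, k=0)


def test_network_exports_round_trip(tmp_path):
    import networkx as nx

    net = build_network(toy_corr(0.99))
    write_sif(net, tmp_path / "n.sif")
    write_edge_table(net, tmp_path / "n.tsv")
    write_graphml(net, tmp_path / "n.graphml")
    sif = (tmp_path / "n.sif").read_text().strip().split("\n")
    assert sif == ["a\tpos\tb"]
    edges = pd.read_csv(tmp_path / "n.tsv", sep="\t")
    assert edges.shape[0] == 1 and edges["sign"].iloc[0] == 1
    back = nx.read_graphml(tmp_path / "n.graphml")
    assert set(back.nodes) == set(net.nodes)
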