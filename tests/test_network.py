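"""Network metrics against hand enumeration and independent oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import colonynet as cn
from colonynet.datamodel import ValidationError
from colonynet.network import _closeness, holm_adjust

from conftest import freq_from_array, transitive_tournament


def random_binary(seed, n=6, p=0.4):
    rng = np.random.default_rng(seed)
    b = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(b, 0)
    b[np.tril_indices(n)] *= 1 - b.T[np.tril_indices(n)]  # keep antisymmetric
    return freq_from_array(b)


class TestDensity:
    def test_empty(self):
        assert cn.density(freq_from_array(np.zeros((4, 4)))) == 0.0

    def test_linear_tournament(self):
        assert cn.density(transitive_tournament(4)) == pytest.approx(0.5)


class TestAveragePathLength:
    def test_complete_digraph(self):
        b = freq_from_array(1 - np.eye(3))
        assert cn.average_path_length(b) == 1.0

    def test_path_with_diameter_substitution(self):
        b = freq_from_array([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
        assert cn.average_path_length(b) == pytest.approx(5 / 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_strongly_connected_matches_plain_mean(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        b = (rng.random((n, n)) < 0.6).astype(int)
        np.fill_diagonal(b, 0)
        g = nx.from_numpy_array(b, create_using=nx.DiGraph)
        if not nx.is_strongly_connected(g):
            return
        assert cn.average_path_length(freq_from_array(b)) == pytest.approx(
            nx.average_shortest_path_length(g)
        )


class TestCentralization:
    def test_out_star_degree(self):
        n = 5
        b = np.zeros((n, n), dtype=int)
        b[0, 1:] = 1
        assert cn.degree_centralization(freq_from_array(b), "out") == 1.0

    def test_regular_tournament_zero(self):
        # 3-cycle: every out-degree 1
        b = freq_from_array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        assert cn.degree_centralization(b, "out") == 0.0
        assert cn.closeness_centralization(b, "out") == 0.0

    def test_degree_matches_brute_force(self):
        b = random_binary(3, n=4)
        deg = b.to_numpy().sum(axis=1)
        expect = (deg.max() - deg).sum() / 9
        assert cn.degree_centralization(b, "out") == pytest.approx(expect)

    def test_out_star_closeness(self):
        n = 6
        b = np.zeros((n, n), dtype=int)
        b[0, 1:] = 1
        assert cn.closeness_centralization(freq_from_array(b), "out") == (
            pytest.approx(1.0)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_closeness_matches_brute_force(self, seed):
        b = random_binary(seed, n=5)
        c = _closeness(b.to_numpy().astype(float), "out")
        n = 5
        expect = (c.max() - c).sum() / ((n - 1) ** 2 / n)
        assert cn.closeness_centralization(b, "out") == pytest.approx(expect)


class TestNodeMetrics:
    def test_single_source_hub(self):
        n = 5
        b = np.zeros((n, n), dtype=int)
        b[0, 1:] = 1
        h = cn.hub_scores(freq_from_array(b))
        assert h[0] == 1.0 and h[1:] == pytest.approx(np.zeros(n - 1), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_hub_matches_eigendecomposition(self, seed):
        b = random_binary(seed, n=5, p=0.5)
        a = b.to_numpy().astype(float)
        if a.sum() == 0:
            return
        vals, vecs = np.linalg.eigh(a @ a.T)
        if np.sort(vals)[-1] - np.sort(vals)[-2] < 1e-8:
            return  # degenerate leading eigenvalue: eigenvector not unique
        h = cn.hub_scores(b)
        lead = np.abs(vecs[:, np.argmax(vals)])
        assert h == pytest.approx(lead / lead.max(), abs=1e-8)

    def test_transitive_tournament_structure(self):
        nm = cn.node_metrics(transitive_tournament(6))
        assert (np.diff(nm["out_degree"].to_numpy()) < 0).all()
        assert (nm["out_degree"] + nm["in_degree"] <= 5).all()
        assert nm["hub_score"].max() == 1.0

    def test_permutation_equivariance(self, colony_binary):
        rng = np.random.default_rng(0)
        roster = list(colony_binary.index)
        perm = rng.permutation(roster).tolist()
        nm1 = cn.node_metrics(colony_binary)
        nm2 = cn.node_metrics(colony_binary.loc[perm, perm])
        pd.testing.assert_frame_equal(nm1.loc[perm], nm2)


class TestAssortativity:
    def test_regular_tournament_undefined(self):
        b = freq_from_array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        r, p = cn.degree_assortativity(b, "out", n_rand=10, seed=0)
        assert np.isnan(r) and np.isnan(p)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_networkx(self, seed):
        b = random_binary(seed, n=8, p=0.4)
        a = b.to_numpy()
        if a.sum() < 2:
            return
        r, _ = cn.degree_assortativity(b, "out", n_rand=5, seed=0)
        if np.isnan(r):
            return
        g = nx.from_numpy_array(a, create_using=nx.DiGraph)
        expect = nx.degree_pearson_correlation_coefficient(g, x="out", y="out")
        assert r == pytest.approx(expect, abs=1e-10)

    def test_assorted_graph_positive(self):
        # two high-out-degree nodes feed each other's targets; low-degree
        # nodes point only at low-degree nodes
        b = np.zeros((6, 6), dtype=int)
        b[0, [1, 2, 3]] = 1
        b[1, [0, 2, 3]] = 1
        b[4, 5] = 1
        r, _ = cn.degree_assortativity(freq_from_array(b), "out", n_rand=5, seed=0)
        assert r > 0


class TestExtremeDegree:
    def test_star_is_extreme(self):
        n = 10
        b = np.zeros((n, n), dtype=int)
        b[0, 1:] = 1  # max out-degree N-1 at density 0.1
        res = cn.extreme_degree_test(freq_from_array(b), 2000, 3, seed=0)
        assert res["p_max_out_mean"] < 0.01

    def test_calibrated_against_own_null(self):
        # graph drawn from the Bernoulli null itself: p should be moderate
        rng = np.random.default_rng(5)
        b = (rng.random((12, 12)) < 0.4).astype(int)
        np.fill_diagonal(b, 0)
        res = cn.extreme_degree_test(freq_from_array(b), 1000, 3, seed=1)
        assert 0.01 < res["p_max_out_mean"] <= 1.0


class TestCorrelations:
    def test_holm_hand_example(self):
        adj = holm_adjust([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    def test_self_correlation_and_structure(self):
        nm = cn.node_metrics(transitive_tournament(6))
        out = cn.correlate_node_measures(nm)
        row = out[(out.var1 == "out_degree") & (out.var2 == "in_degree")]
        assert row["rho"].iloc[0] == pytest.approx(-1.0)

    def test_constant_column_excluded(self):
        nm = cn.node_metrics(transitive_tournament(5))
        cov = pd.DataFrame({"flat": np.ones(5)}, index=nm.index)
        out = cn.correlate_node_measures(nm, cov)
        assert "flat" in out.attrs["excluded_constant"]
        assert not ((out.var1 == "flat") | (out.var2 == "flat")).any()


def test_dominants_occupy_powerful_positions():
    """With steep contests, planted rank aligns with out-style power metrics."""
    from scipy.stats import spearmanr

    ds = cn.simulate_colony(cn.SimConfig(beta=6.0, seed=13))
    nm = cn.node_metrics(cn.binarize(cn.build_frequency_matrix(ds.events)))
    planted = {ind: k + 1 for k, ind in enumerate(ds.true_order)}
    rank = np.array([planted[i] for i in nm.index])
    assert spearmanr(rank, nm["hub_score"]).statistic < -0.9
    assert spearmanr(rank, nm["out_closeness"]).statistic < -0.9
    assert spearmanr(rank, nm["in_closeness"]).statistic > 0.9


def test_summary_ranges(colony_binary):
    s = cn.network_summary(colony_binary, n_rand=50, n_random_graphs=100,
                           replicates=2, seed=0)
    assert 0 <= s.density <= 1
    assert s.average_path_length >= 1
    assert 0 <= s.out_degree_centralization <= 1
    assert 0 <= s.out_closeness_centralization <= 1
    assert -1 <= s.r_out <= 1
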