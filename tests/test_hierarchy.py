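"""Hierarchy statistics against hand calculations and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import colonynet as cn
from colonynet.datamodel import ValidationError
from colonynet.hierarchy import isi_score

from conftest import freq_from_array, transitive_tournament


def brute_force_h_prime(freq):
    """Mean Landau h over every fair-coin imputation of the undirected dyads
    (never-interacting pairs and pairs tied on wins)."""
    m = np.asarray(freq, dtype=float)
    n = m.shape[0]
    iu, ju = np.triu_indices(n, 1)
    up, lo = m[iu, ju], m[ju, iu]
    undirected = list(np.flatnonzero(up == lo))
    hs = []
    for bits in itertools.product([0, 1], repeat=len(undirected)):
        v = np.zeros(n)
        for k in range(len(iu)):
            i, j = iu[k], ju[k]
            if up[k] == lo[k]:
                who = i if bits[undirected.index(k)] else j
                v[who] += 1
            elif up[k] > lo[k]:
                v[i] += 1
            else:
                v[j] += 1
        hs.append(12 / (n**3 - n) * ((v - (n - 1) / 2) ** 2).sum())
    return float(np.mean(hs))


def brute_force_isi(binary):
    """Lexicographic minimum of (I, SI) over every ordering."""
    b, _ = cn.datamodel.as_matrix(binary)
    n = b.shape[0]
    best = None
    for perm in itertools.permutations(range(n)):
        score = isi_score(binary, np.array(perm))
        if best is None or score < best:
            best = score
    return best


class TestDirectionalConsistency:
    def test_one_directional(self):
        dc, _ = cn.directional_consistency(freq_from_array([[0, 4], [0, 0]]), 50, 0)
        assert dc == 1.0

    def test_even_split(self):
        dc, _ = cn.directional_consistency(freq_from_array([[0, 3], [3, 0]]), 50, 0)
        assert dc == 0.0

    def test_hand_value(self):
        # dyads (3,1) and (5,0): DC = (2 + 5) / (4 + 5) = 7/9
        m = freq_from_array([[0, 3, 5], [1, 0, 0], [0, 0, 0]])
        dc, _ = cn.directional_consistency(m, 50, 0)
        assert dc == pytest.approx(7 / 9, abs=1e-12)

    def test_no_interactions_errors(self):
        with pytest.raises(ValidationError, match="no interactions"):
            cn.directional_consistency(freq_from_array(np.zeros((3, 3))), 10, 0)


class TestLandauHPrime:
    def test_perfect_linear_order(self):
        hp, _ = cn.landau_h_prime(transitive_tournament(4), n_rand=100, seed=0)
        assert hp == pytest.approx(1.0, abs=1e-12)

    def test_one_unknown_dyad_matches_enumeration(self):
        m = transitive_tournament(4).to_numpy().astype(float)
        m[2, 3] = 0  # C-D never interact
        hp, _ = cn.landau_h_prime(freq_from_array(m), n_rand=100, seed=0)
        assert hp == pytest.approx(brute_force_h_prime(m), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_estimate_matches_exhaustive_imputation(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 3, size=(5, 5)).astype(float)
        np.fill_diagonal(m, 0)
        hp, _ = cn.landau_h_prime(freq_from_array(m), n_rand=20, seed=0)
        assert hp == pytest.approx(brute_force_h_prime(m), abs=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            cn.landau_h_prime(freq_from_array([[0, 1], [0, 0]]))


class TestDavidScores:
    def test_linear_three(self):
        ds = cn.david_scores(transitive_tournament(3))
        assert ds.table["DS"].tolist() == pytest.approx([3, 0, -3])
        assert ds.table["NormDS"].tolist() == pytest.approx([2, 1, 0])

    def test_even_dyads_all_zero(self):
        m = freq_from_array(2 * (1 - np.eye(4)))
        assert cn.david_scores(m).table["DS"].to_numpy() == pytest.approx(
            np.zeros(4)
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_scores_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 6, size=(6, 6)).astype(float)
        np.fill_diagonal(m, 0)
        for dyadic in ("Pij", "Dij"):
            assert cn.david_scores(freq_from_array(m), dyadic).table[
                "DS"
            ].sum() == pytest.approx(0.0, abs=1e-9)


class TestSteepness:
    def test_perfect_linear(self):
        s, _ = cn.steepness(transitive_tournament(3), n_rand=50, seed=0)
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_all_tied_flat(self):
        m = freq_from_array(3 * (1 - np.eye(4)))
        s, _ = cn.steepness(m, n_rand=50, seed=0)
        assert s == pytest.approx(0.0, abs=1e-12)


class TestTriangleTransitivity:
    def test_transitive_tournament(self):
        tri = cn.triangle_transitivity(transitive_tournament(5), 50, 0)
        assert tri.pt == 1.0 and tri.t_tri == 1.0

    def test_three_cycle(self):
        b = freq_from_array([[0, 1, 0], [0, 0, 1], [1, 0, 0]])
        tri = cn.triangle_transitivity(b, 50, 0)
        assert tri.pt == 0.0 and tri.t_tri == -3.0

    def test_rescaling_of_reported_proportion(self):
        assert cn.scale_transitivity(0.94) == pytest.approx(0.76, abs=1e-12)

    def test_no_complete_triads_errors(self):
        b = freq_from_array([[0, 1, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValidationError, match="triads"):
            cn.triangle_transitivity(b, 10, 0)

    def test_counts_match_enumeration(self, colony_binary):
        b = colony_binary.to_numpy()
        n = b.shape[0]
        complete = transitive = 0
        for i, j, k in itertools.combinations(range(n), 3):
            rel = [b[i, j] + b[j, i], b[i, k] + b[k, i], b[j, k] + b[k, j]]
            if all(r == 1 for r in rel):
                complete += 1
                sub = b[np.ix_([i, j, k], [i, j, k])]
                if sorted(sub.sum(axis=1)) == [0, 1, 2]:
                    transitive += 1
        tri = cn.triangle_transitivity(colony_binary, 10, 0)
        assert tri.n_complete_triads == complete
        assert tri.pt == pytest.approx(transitive / complete)


class TestISIRank:
    def test_transitive_tournament_recovers_order(self):
        b = transitive_tournament(6)
        res = cn.isi_rank(b, seed=0)
        assert res.inconsistencies == 0 and res.strength == 0
        assert res.ordering == list("ABCDEF")

    def test_planted_reversal_matches_exhaustive(self):
        b = transitive_tournament(5).to_numpy()
        b[4, 0], b[0, 4] = 1, 0  # bottom animal beats the top one
        b = freq_from_array(b)
        res = cn.isi_rank(b, seed=0)
        assert (res.inconsistencies, res.strength) == brute_force_isi(b)

    def test_all_zero_matrix_flagged(self):
        res = cn.isi_rank(freq_from_array(np.zeros((4, 4))), seed=0)
        assert res.inconsistencies == 0 and res.note == "no relations"

    def test_never_worse_than_david_score_start(self, colony_binary):
        res = cn.isi_rank(colony_binary, n_restarts=3, seed=1)
        ds = cn.david_scores(colony_binary).table["DS"].to_numpy()
        start = np.lexsort((np.arange(len(ds)), -ds))
        assert (res.inconsistencies, res.strength) <= isi_score(
            colony_binary, start
        )


def test_pt_range_and_scaling_consistency(colony_binary):
    tri = cn.triangle_transitivity(colony_binary, 100, 0)
    assert 0 <= tri.pt <= 1
    assert tri.t_tri == pytest.approx(4 * (tri.pt - 0.75), abs=1e-12)
    assert 0 < tri.p <= 1
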