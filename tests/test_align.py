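import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import factalign as fa
from factalign.align import (AlignParams, AlignmentResult,
                             eval_alignment_score, smith_waterman_matrix)

from .oracles import best_local_alignment_score

GAPS = AlignParams(gap_open=1.0, gap_extend=0.5)
M2 = np.array([[2.0, -1.0], [-1.0, 1.5]])  # 2-letter single-feature scores


class TestSmithWaterman:
    def test_identical_sequences_full_diagonal(self):
        q = np.array([0, 1, 0, 1, 1])
        S = M2[np.ix_(q, q)]
        res = smith_waterman_matrix(S, GAPS)
        assert res.columns == [(i, i) for i in range(5)]
        assert np.isclose(res.score, np.diag(S).sum())

    def test_all_negative_scores_empty_alignment(self):
        S = np.full((4, 6), -1.0)
        res = smith_waterman_matrix(S, GAPS)
        assert res.columns == [] and res.score == 0.0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
    def test_matches_enumeration_on_random_pairs(self, n, m, seed):
        rng = np.random.default_rng(seed)
        q = rng.integers(0, 2, size=n)
        t = rng.integers(0, 2, size=m)
        S = M2[np.ix_(q, t)]
        got = smith_waterman_matrix(S, GAPS).score
        expect = best_local_alignment_score(S, GAPS.gap_open, GAPS.gap_extend)
        assert abs(got - expect) < 1e-9

    def test_score_symmetry(self, toy_tables, toy_db):
        db, _ = toy_db
        from factalign.alphabets import discretize_chain
        d0 = discretize_chain(fa.extract_features(db[0]),
                              toy_tables.alphabets)
        d1 = discretize_chain(fa.extract_features(db[4]),
                              toy_tables.alphabets)
        a = fa.smith_waterman(d0, d1, toy_tables.matrices)
        b = fa.smith_waterman(d1, d0, toy_tables.matrices)
        assert np.isclose(a.score, b.score)

    def test_gap_open_monotonicity(self):
        rng = np.random.default_rng(5)
        q = rng.integers(0, 2, size=12)
        t = rng.integers(0, 2, size=14)
        S = M2[np.ix_(q, t)]
        prev = np.inf
        for go in (0.5, 1.0, 2.0, 4.0, 8.0):
            s = smith_waterman_matrix(S, AlignParams(go, 0.5)).score
            assert s <= prev + 1e-12
            prev = s

    def test_dp_score_equals_reevaluation_on_simulated_pairs(
            self, toy_tables, toy_db):
        from factalign.alphabets import discretize_chain
        db, _ = toy_db
        rng = np.random.default_rng(6)
        dfvs = [discretize_chain(fa.extract_features(c),
                                 toy_tables.alphabets) for c in db[:8]]
        from factalign.scoring import score_profile
        checked = 0
        for _ in range(40):
            i, j = rng.integers(0, len(dfvs), size=2)
            S = score_profile(dfvs[i], dfvs[j], toy_tables.matrices)
            res = smith_waterman_matrix(S, toy_tables.align_params)
            if res.columns:
                assert abs(eval_alignment_score(
                    res, S, toy_tables.align_params) - res.score) < 1e-6
                checked += 1
        assert checked > 10


class TestEvalAlignmentScore:
    def test_hand_worked_gap_example(self):
        # 3 columns scoring 1.0, 2.0, 0.5 with one internal gap of length 2
        S = np.zeros((3, 6))
        S[0, 0], S[1, 1], S[2, 4] = 1.0, 2.0, 0.5
        a = AlignmentResult(columns=[(0, 0), (1, 1), (2, 4)], score=2.0)
        got = eval_alignment_score(a, S, AlignParams(1.0, 0.5))
        assert np.isclose(got, 3.5 - (1.0 + 0.5))

    def test_ungapped_is_sum_of_pair_scores(self):
        S = np.diag([1.0, 2.0, 3.0])
        a = AlignmentResult(columns=[(0, 0), (1, 1), (2, 2)], score=6.0)
        assert np.isclose(eval_alignment_score(a, S, GAPS), 6.0)

    def test_length_one_gap_costs_open_only(self):
        S = np.zeros((2, 3))
        S[0, 0] = 2.0
        S[1, 2] = 2.0
        a = AlignmentResult(columns=[(0, 0), (1, 2)], score=0.0)
        got = eval_alignment_score(a, S, AlignParams(1.25, 0.5))
        assert np.isclose(got, 4.0 - 1.25)

    def test_crossing_columns_rejected(self):
        with pytest.raises(ValueError):
            AlignmentResult(columns=[(0, 1), (1, 0)], score=0.0)


class TestReversedScore:
    def test_nonnegative_and_deterministic(self, toy_tables, helix30):
        from factalign.alphabets import discretize_chain
        dfv = discretize_chain(fa.extract_features(helix30),
                               toy_tables.alphabets)
        s1 = fa.reversed_score(helix30, dfv, toy_tables.alphabets,
                               toy_tables.matrices)
        s2 = fa.reversed_score(helix30, dfv, toy_tables.alphabets,
                               toy_tables.matrices)
        assert s1 >= 0 and s1 == s2

    def test_palindromic_chain_reversal_is_symmetry(self, toy_tables):
        # collinear equally-spaced chain: reversal preserves all geometry
        n = 20
        coords = np.column_stack([3.8 * np.arange(n), np.zeros(n),
                                  np.zeros(n)])
        aa = "ACDEFGHIKLLKIHGFEDCA"  # palindromic letters
        s = fa.ChainStructure(id="pal", aa=aa, coords=coords)
        from factalign.alphabets import discretize_chain
        dfv = discretize_chain(fa.extract_features(s), toy_tables.alphabets)
        self_score = fa.smith_waterman(dfv, dfv, toy_tables.matrices,
                                       toy_tables.align_params).score
        s_rev = fa.reversed_score(s, dfv, toy_tables.alphabets,
                                  toy_tables.matrices,
                                  ap=toy_tables.align_params)
        assert abs(s_rev - self_score) < 1e-6


class TestKabsch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(10, 3)) * 5
        sup = fa.kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-9
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_exact_recovery_of_known_transform(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(12, 3)) * 8
        ang = 1.1
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = pts @ R.T + np.array([3.0, -2.0, 7.0])
        sup = fa.kabsch_superpose(pts, moved)
        assert sup.rmsd < 1e-6
        np.testing.assert_allclose(sup.rotation @ R, np.eye(3), atol=1e-6)

    def test_beats_random_rotation_grid(self):
        rng = np.random.default_rng(9)
        P = rng.normal(size=(10, 3)) * 4
        Q = rng.normal(size=(10, 3)) * 4
        opt = fa.kabsch_superpose(P, Q).rmsd
        best_grid = np.inf
        for _ in range(10_000):
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, [0, 1]] = q[:, [1, 0]]
            moved = Q @ q.T
            moved = moved - moved.mean(0) + P.mean(0)
            best_grid = min(best_grid,
                            np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
        assert opt <= best_grid + 1e-9

    def test_reflection_guard_on_near_planar_points(self):
        rng = np.random.default_rng(10)
        P = rng.normal(size=(8, 3))
        P[:, 2] *= 1e-4  # nearly planar
        Q = -P  # improper "match" tempting a reflection
        sup = fa.kabsch_superpose(P, Q)
        assert abs(np.linalg.det(sup.rotation) - 1.0) < 1e-6

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fa.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            fa.kabsch_superpose(line, line + 1.0)
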