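"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming and
nearest-centroid code paths: alignments are scored by exhaustive
enumeration of column sets, neighbours by exhaustive distance scans.
"""

from itertools import combinations

import numpy as np


def gap_penalty(indices, gap_open, gap_extend):
    """Affine penalty of the internal gaps implied by an increasing index set."""
    pen = 0.0
    for a, b in zip(indices, indices[1:]):
        g = b - a - 1
        if g > 0:
            pen += gap_open + (g - 1) * gap_extend
    return pen


def best_local_alignment_score(S, gap_open, gap_extend):
    """Exhaustive maximum over all local alignments of a score matrix.

    Enumerates every pair of equal-size strictly increasing index subsets
    of the two sequences; the empty alignment scores 0.
    """
    n, m = S.shape
    best = 0.0
    for k in range(1, min(n, m) + 1):
        for qi in combinations(range(n), k):
            pq = gap_penalty(qi, gap_open, gap_extend)
            for tj in combinations(range(m), k):
                sc = S[list(qi), list(tj)].sum() - pq \
                    - gap_penalty(tj, gap_open, gap_extend)
                if sc > best:
                    best = sc
    return best


def all_pairs_oracle_vs_dp(M, gap_open, gap_extend, max_len, dp_fn):
    """Compare exhaustive enumeration with a DP implementation on every
    sequence pair up to ``max_len`` over a 2-letter alphabet.

    Returns the number of pairs checked; raises AssertionError on the
    first disagreement.
    """
    seqs = []
    for n in range(1, max_len + 1):
        for code in range(2 ** n):
            seqs.append(np.array([(code >> i) & 1 for i in range(n)]))
    checked = 0
    for q in seqs:
        for t in seqs:
            S = M[np.ix_(q, t)]
            expect = best_local_alignment_score(S, gap_open, gap_extend)
            got = dp_fn(S)
            assert abs(got - expect) < 1e-9, (
                f"DP {got} != oracle {expect} for q={q.tolist()} t={t.tolist()}")
            checked += 1
    return checked


def oracle_scores_all_seq_pairs(M, gap_open, gap_extend, n, m):
    """Exhaustive local-alignment scores for every pair of a length-n and a
    length-m sequence over a 2-letter alphabet, vectorised over sequences.

    Returns (Q, T, best) where Q is the (2^n, n) array of query sequences,
    T the (2^m, m) targets and best the (2^n, 2^m) oracle score matrix.
    """
    Q = np.array([[(c >> i) & 1 for i in range(n)] for c in range(2 ** n)])
    T = np.array([[(c >> i) & 1 for i in range(m)] for c in range(2 ** m)])
    best = np.zeros((2 ** n, 2 ** m))
    for k in range(1, min(n, m) + 1):
        for qi in combinations(range(n), k):
            pq = gap_penalty(qi, gap_open, gap_extend)
            Qs = Q[:, qi]  # (2^n, k)
            for tj in combinations(range(m), k):
                pen = pq + gap_penalty(tj, gap_open, gap_extend)
                sc = M[Qs[:, None, :], T[:, tj][None, :, :]].sum(-1) - pen
                np.maximum(best, sc, out=best)
    return Q, T, best


def nearest_neighbor_scan(coords, i, min_sep, tol=1e-6):
    """Exhaustive NEN scan: smallest eligible distance; near-ties (within
    ``tol``) resolve to the smaller index."""
    best_j, best_d = None, np.inf
    for j in range(len(coords)):
        if abs(j - i) < min_sep:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < best_d - tol:
            best_j, best_d = j, d
    return best_j
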