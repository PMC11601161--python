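"""Gapped local alignment of discretised chains and rigid superposition.

The optimal local alignment maximises the summed pair scores minus affine
gap penalties ``G_open + (len−1)·G_ext``, computed with the three-state
Gotoh recurrence (full O(nm) dynamic programming, no banding).  Traceback
ties prefer diagonal, then gap-in-target, then gap-in-query, so paths are
reproducible.  The rigid-body superposition implied by an alignment is the
Kabsch least-squares rotation with the usual reflection guard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .chain import ChainStructure, reverse_chain
from .features import FeatureParams, extract_features
from .scoring import ScoreMatrixSet, score_profile


@dataclass(frozen=True)
class AlignParams:
    """Affine gap penalties in bits; local alignment only."""

    gap_open: float = 3.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("need gap_open >= gap_extend >= 0")


@dataclass
class AlignmentResult:
    """Local alignment as strictly increasing (q_pos, t_pos) columns."""

    columns: list[tuple[int, int]]
    score: float

    def __post_init__(self) -> None:
        cols = self.columns
        for (q1, t1), (q2, t2) in zip(cols, cols[1:]):
            if q2 <= q1 or t2 <= t1:
                raise ValueError("alignment columns must strictly increase "
                                 "in both coordinates")

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Internal gaps as (column index before the gap, length)."""
        out = []
        for k, ((q1, t1), (q2, t2)) in enumerate(
                zip(self.columns, self.columns[1:])):
            if q2 - q1 - 1 > 0:
                out.append((k, q2 - q1 - 1))
            if t2 - t1 - 1 > 0:
                out.append((k, t2 - t1 - 1))
        return out

    def __len__(self) -> int:
        return len(self.columns)


@njit(cache=False)
def _gotoh_local(S, gap_open, gap_extend):  # pragma: no cover - numba kernel
    n, m = S.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e30)  # gap in query (consumes target)
    F = np.full((n + 1, m + 1), -1e30)  # gap in target (consumes query)
    # traceback: 0 stop, 1 diag, 2 from F (gap in target), 3 from E (gap in query)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    pe = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 if E extends E
    pf = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open
            e_ext = E[i, j - 1] - gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] - gap_open
            f_ext = F[i - 1, j] - gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            # tie order: diag > gap-in-target (F) > gap-in-query (E) > stop
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            if h <= 0.0:
                h = 0.0
                p = 0
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptr, pe, pf, best, bi, bj


def smith_waterman_matrix(
    S: np.ndarray, p: AlignParams = AlignParams()
) -> AlignmentResult:
    """Optimal local alignment given a precomputed pair-score matrix."""
    S = np.ascontiguousarray(S, dtype=float)
    if S.size == 0:
        return AlignmentResult(columns=[], score=0.0)
    H, ptr, pe, pf, best, i, j = _gotoh_local(S, p.gap_open, p.gap_extend)
    if best <= 0:
        return AlignmentResult(columns=[], score=0.0)
    cols: list[tuple[int, int]] = []
    state = 0  # 0 in H, 2 in F, 3 in E
    while i > 0 and j > 0:
        if state == 0:
            move = ptr[i, j]
            if move == 0:
                break
            if move == 1:
                cols.append((i - 1, j - 1))
                i -= 1
                j -= 1
            else:
                state = move
        elif state == 2:  # F: gap in target, consume query
            nxt = 2 if pf[i, j] else 0
            i -= 1
            state = nxt
        else:  # E: gap in query, consume target
            nxt = 3 if pe[i, j] else 0
            j -= 1
            state = nxt
    cols.reverse()
    return AlignmentResult(columns=cols, score=float(best))


def smith_waterman(
    dfv_q: np.ndarray, dfv_t: np.ndarray,
    matrices: ScoreMatrixSet, p: AlignParams = AlignParams(),
) -> AlignmentResult:
    """Optimal gapped local alignment of two discretised chains."""
    if dfv_q.shape[0] == 0 or dfv_t.shape[0] == 0:
        raise ValueError("sequences must be non-empty")
    S = score_profile(dfv_q, dfv_t, matrices)
    return smith_waterman_matrix(S, p)


def eval_alignment_score(
    a: AlignmentResult, S: np.ndarray, p: AlignParams = AlignParams()
) -> float:
    """Independent re-evaluation of the alignment objective from columns:
    sum of pair scores minus ``G_open + (len−1)·G_ext`` per internal gap."""
    total = 0.0
    prev = None
    for q, t in a.columns:
        if not (0 <= q < S.shape[0] and 0 <= t < S.shape[1]):
            raise ValueError("column index out of range")
        if prev is not None:
            if q <= prev[0] or t <= prev[1]:
                raise ValueError("crossing or repeated alignment columns")
            for gap_len in (q - prev[0] - 1, t - prev[1] - 1):
                if gap_len > 0:
                    total -= p.gap_open + (gap_len - 1) * p.gap_extend
        total += S[q, t]
        prev = (q, t)
    return total


def reversed_score(
    q_chain: ChainStructure,
    dfv_q: np.ndarray,
    alphabets,
    matrices: ScoreMatrixSet,
    fp: FeatureParams = FeatureParams(),
    ap: AlignParams = AlignParams(),
) -> float:
    """Optimal local alignment score of Q against its own coordinate-reversed
    copy, with features recomputed from the reversed coordinates."""
    from .alphabets import discretize_chain
    rev = reverse_chain(q_chain)
    dfv_rev = discretize_chain(extract_features(rev, fp), alphabets)
    return smith_waterman(dfv_q, dfv_rev, matrices, ap).score


@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation determinant not +1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be >= 0")


def kabsch_superpose(coords_q: np.ndarray, coords_t: np.ndarray) -> Superposition:
    """Least-squares rigid transform mapping ``coords_t`` onto ``coords_q``.

    Returns rotation R and translation t minimising RMSD of
    ``R·x_t + t`` to ``x_q`` (SVD solution with reflection guard)."""
    P = np.asarray(coords_q, dtype=float)
    Q = np.asarray(coords_t, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("need matching (n, 3) coordinate arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 aligned positions to superpose")
    pc = P - P.mean(axis=0)
    qc = Q - Q.mean(axis=0)
    Hm = qc.T @ pc
    U, sv, Vt = np.linalg.svd(Hm)
    if sv[1] < 1e-9:
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - R @ Q.mean(axis=0)
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)
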