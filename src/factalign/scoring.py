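"""Log-odds substitution matrices over discrete features.

For each feature, the score of aligning letter i to letter j is
``M_ij = log2(P_ij / (p_i p_j))`` where ``P_ij`` is the frequency of the
(i, j) pair among aligned columns of a training set (counted in both
orders so the matrix is symmetric) and ``p_i`` the marginal letter
frequency — the BLOSUM construction applied feature by feature.  The score
of an aligned residue pair is the weighted sum of per-feature log-odds
(the factored estimate of the mega-letter log-odds); the mega-alphabet has
``h = prod_f A_f`` states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import FEATURE_NAMES


@dataclass
class PairCounts:
    """Symmetrised joint letter counts for one feature."""

    feature_name: str
    joint: np.ndarray  # (L, L)
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.joint = np.asarray(self.joint, dtype=float)
        if self.joint.ndim != 2 or self.joint.shape[0] != self.joint.shape[1]:
            raise ValueError("joint counts must be square")
        if np.any(self.joint < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> float:
        return float(self.joint.sum())


@dataclass
class ScoreMatrix:
    """Symmetric per-feature log-odds matrix, in bits, with its weight."""

    feature_name: str
    matrix: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError(f"{self.feature_name}: matrix must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.feature_name}: non-finite entries")
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def accumulate_counts(
    alignments,
    feature: str,
    alphabet_size: int,
    pseudocount: float = 0.5,
) -> PairCounts:
    """Count aligned letter pairs for one feature.

    ``alignments`` is an iterable of ``(dfv_q, dfv_t, columns)`` where the
    DFVs are (n, n_features) integer arrays and ``columns`` is a list of
    aligned (q_pos, t_pos) index pairs; gap columns are simply absent.
    Counts are symmetrised: each column contributes to both (i, j) and (j, i).
    """
    f = FEATURE_NAMES.index(feature)
    joint = np.zeros((alphabet_size, alphabet_size), dtype=float)
    n_pairs = 0
    for dfv_q, dfv_t, columns in alignments:
        for qi, ti in columns:
            i, j = int(dfv_q[qi, f]), int(dfv_t[ti, f])
            if not (0 <= i < alphabet_size and 0 <= j < alphabet_size):
                raise ValueError(
                    f"letter out of range for feature {feature!r}: ({i}, {j})")
            joint[i, j] += 1
            joint[j, i] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError(f"no aligned columns to count for feature {feature!r}")
    return PairCounts(feature_name=feature, joint=joint, pseudocount=pseudocount)


def train_logodds(c: PairCounts, weight: float = 1.0) -> ScoreMatrix:
    """Eq.-style log-odds in bits from pseudocount-smoothed frequencies."""
    joint = c.joint + c.pseudocount
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty counts")
    P = joint / total
    p = P.sum(axis=1)
    M = np.log2(P / np.outer(p, p))
    M = 0.5 * (M + M.T)  # symmetric up to rounding already
    return ScoreMatrix(feature_name=c.feature_name, matrix=M, weight=weight)


@dataclass
class ScoreMatrixSet:
    """Per-feature matrices in canonical feature order."""

    matrices: dict[str, ScoreMatrix]

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.matrices]
        if missing:
            raise KeyError(f"missing score matrices for features {missing}")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.matrices[n].weight for n in FEATURE_NAMES])

    def stacked(self) -> list[np.ndarray]:
        return [self.matrices[n].matrix * self.matrices[n].weight
                for n in FEATURE_NAMES]

    def to_dict(self) -> dict:
        return {
            "feature_order": list(FEATURE_NAMES),
            "matrices": {n: {"weight": m.weight, "matrix": m.matrix.tolist()}
                         for n, m in self.matrices.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreMatrixSet":
        return cls(matrices={
            n: ScoreMatrix(n, np.asarray(v["matrix"]), v["weight"])
            for n, v in d["matrices"].items()
        })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreMatrixSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def pair_score(u: np.ndarray, v: np.ndarray, matrices: ScoreMatrixSet) -> float:
    """Weighted per-feature log-odds score of one aligned residue pair.

    ``u`` and ``v`` are per-residue letter tuples (one letter per feature in
    canonical order)."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != (len(FEATURE_NAMES),) or v.shape != (len(FEATURE_NAMES),):
        raise ValueError("DFVs must have one letter per configured feature")
    total = 0.0
    for f, name in enumerate(FEATURE_NAMES):
        m = matrices.matrices[name]
        if not (0 <= u[f] < m.size and 0 <= v[f] < m.size):
            raise ValueError(f"letter out of range for feature {name!r}")
        total += m.weight * m.matrix[u[f], v[f]]
    return float(total)


def score_profile(dfv_q: np.ndarray, dfv_t: np.ndarray,
                  matrices: ScoreMatrixSet) -> np.ndarray:
    """(n, m) matrix of pair scores for all residue pairs of two chains."""
    n, m = dfv_q.shape[0], dfv_t.shape[0]
    S = np.zeros((n, m))
    for f, name in enumerate(FEATURE_NAMES):
        sm = matrices.matrices[name]
        if sm.weight == 0.0:
            continue
        S += sm.weight * sm.matrix[np.ix_(dfv_q[:, f], dfv_t[:, f])]
    return S


def mega_alphabet_size(alphabet_sizes) -> int:
    """Exact product of per-feature alphabet sizes (number of mega-letters)."""
    sizes = list(alphabet_sizes)
    if not sizes:
        raise ValueError("no alphabet sizes given")
    if any(s < 1 for s in sizes):
        raise ValueError("alphabet sizes must be >= 1")
    return math.prod(int(s) for s in sizes)
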