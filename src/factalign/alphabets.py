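"""Discretisation of real-valued features into letters.

Scalar features use equal-frequency (maximum-entropy) binning: the sorted
training values are split into L contiguous bins of (as near as possible)
equal size and each threshold is the mean of the last value of one bin and
the first value of the next.  Vector features (the Conf windows) use
K-means centroids; a letter is the index of the nearest centroid.  The
per-residue tuple of letters over all configured features is the discrete
feature vector (DFV) — one "mega-letter" from the Cartesian product of the
per-feature alphabets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .chain import AA_INDEX
from .features import (FEATURE_NAMES, SCALAR_FEATURES, VECTOR_FEATURES,
                       FeatureVector)

logger = logging.getLogger(__name__)

DEFAULT_STRUCT_ALPHABET_SIZE = 16


class DegenerateAlphabetError(ValueError):
    """Too few distinct training values for the requested alphabet size."""


@dataclass
class ScalarAlphabet:
    feature_name: str
    thresholds: np.ndarray  # L-1 strictly increasing values

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.size < 1 or np.any(np.diff(self.thresholds) <= 0):
            raise DegenerateAlphabetError(
                f"{self.feature_name}: thresholds must be strictly increasing"
            )

    @property
    def size(self) -> int:
        return self.thresholds.size + 1


@dataclass
class VectorAlphabet:
    feature_name: str
    centroids: np.ndarray  # (K, d)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.centroids.ndim != 2 or self.centroids.shape[0] < 2:
            raise ValueError(f"{self.feature_name}: need >= 2 centroids")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError(f"{self.feature_name}: non-finite centroids")

    @property
    def size(self) -> int:
        return self.centroids.shape[0]


def train_scalar_alphabet(values, L: int,
                          feature_name: str = "scalar") -> ScalarAlphabet:
    """Equal-frequency thresholds: sort, split into L contiguous bins whose
    sizes differ by at most one, threshold = mean(max of bin B, min of bin B+1)."""
    x = np.sort(np.asarray(values, dtype=float))
    if x.size < L:
        raise DegenerateAlphabetError(
            f"{feature_name}: {x.size} values < L={L}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{feature_name}: non-finite training values")
    if np.unique(x).size < L:
        raise DegenerateAlphabetError(
            f"{feature_name}: fewer than L={L} distinct values")
    bins = np.array_split(x, L)
    thresholds = np.array([
        0.5 * (bins[b][-1] + bins[b + 1][0]) for b in range(L - 1)
    ])
    if np.any(np.diff(thresholds) <= 0):
        raise DegenerateAlphabetError(
            f"{feature_name}: duplicate values collapse thresholds")
    return ScalarAlphabet(feature_name=feature_name, thresholds=thresholds)


def assign_scalar_letter(x: float, a: ScalarAlphabet) -> int:
    """Number of thresholds strictly below x (x equal to a threshold falls
    in the lower bin)."""
    if not np.isfinite(x):
        raise ValueError(f"{a.feature_name}: non-finite value {x!r}")
    return int(np.sum(a.thresholds < x))


def assign_scalar_letters(x: np.ndarray, a: ScalarAlphabet) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{a.feature_name}: non-finite values")
    return np.sum(a.thresholds[None, :] < x[:, None], axis=1).astype(np.intp)


def train_vector_alphabet(vectors, K: int, seed: int,
                          feature_name: str = "vector") -> VectorAlphabet:
    """K-means centroids (k-means++ init, 10 restarts, tol 1e-6)."""
    arr = np.asarray(vectors, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{feature_name}: training vectors must share one dimension")
    if arr.shape[0] < K:
        raise ValueError(f"{feature_name}: {arr.shape[0]} vectors < K={K}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=10, tol=1e-6,
                max_iter=300, random_state=seed)
    km.fit(arr)
    return VectorAlphabet(feature_name=feature_name,
                          centroids=km.cluster_centers_)


def assign_vector_letter(v: np.ndarray, a: VectorAlphabet) -> int:
    """Index of the nearest centroid (Euclidean); ties take the smallest index."""
    v = np.asarray(v, dtype=float)
    if v.shape != (a.centroids.shape[1],):
        raise ValueError(
            f"{a.feature_name}: dimension {v.shape} != {a.centroids.shape[1]}")
    d2 = np.sum((a.centroids - v) ** 2, axis=1)
    return int(np.argmin(d2))


def assign_vector_letters(vs: np.ndarray, a: VectorAlphabet) -> np.ndarray:
    vs = np.asarray(vs, dtype=float)
    if vs.shape[1] != a.centroids.shape[1]:
        raise ValueError(f"{a.feature_name}: dimension mismatch")
    d2 = ((vs[:, None, :] - a.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1).astype(np.intp)


@dataclass
class AlphabetSet:
    """All trained per-feature alphabets, in canonical feature order."""

    scalar: dict[str, ScalarAlphabet]
    vector: dict[str, VectorAlphabet]

    @property
    def sizes(self) -> list[int]:
        out = []
        for name in FEATURE_NAMES:
            if name == "aa":
                out.append(20)
            elif name in self.vector:
                out.append(self.vector[name].size)
            else:
                out.append(self.scalar[name].size)
        return out

    def to_dict(self) -> dict:
        return {
            "feature_order": list(FEATURE_NAMES),
            "scalar": {n: {"size": a.size, "thresholds": a.thresholds.tolist()}
                       for n, a in self.scalar.items()},
            "vector": {n: {"size": a.size, "centroids": a.centroids.tolist()}
                       for n, a in self.vector.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlphabetSet":
        return cls(
            scalar={n: ScalarAlphabet(n, np.asarray(v["thresholds"]))
                    for n, v in d["scalar"].items()},
            vector={n: VectorAlphabet(n, np.asarray(v["centroids"]))
                    for n, v in d["vector"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AlphabetSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_alphabets(
    feature_lists: list[list[FeatureVector]],
    L: int = DEFAULT_STRUCT_ALPHABET_SIZE,
    seed: int = 0,
) -> AlphabetSet:
    """Train all structural alphabets from extracted features of a training
    set of chains.  Sentinel values for missing neighbours participate in
    training, so their bin is part of the alphabet."""
    scalar: dict[str, ScalarAlphabet] = {}
    vector: dict[str, VectorAlphabet] = {}
    rng = np.random.default_rng(seed)
    for name in SCALAR_FEATURES:
        vals = np.array([getattr(fv, name) for fvs in feature_lists for fv in fvs],
                        dtype=float)
        if np.unique(vals).size < vals.size:
            # repeated values (integer offsets, sentinel distances) would
            # collapse equal-frequency thresholds; break ties with a tiny
            # deterministic jitter before binning
            eps = 1e-4 * max(1.0, float(np.ptp(vals)))
            vals = vals + rng.uniform(-eps, eps, size=vals.size)
        scalar[name] = train_scalar_alphabet(vals, L, feature_name=name)
    for k, name in enumerate(VECTOR_FEATURES):
        arr = np.vstack([getattr(fv, name) for fvs in feature_lists for fv in fvs])
        vector[name] = train_vector_alphabet(arr, L, seed=seed + k,
                                             feature_name=name)
    return AlphabetSet(scalar=scalar, vector=vector)


_warned_x = False


def discretize_chain(
    features: list[FeatureVector], alphabet_set: AlphabetSet
) -> np.ndarray:
    """Discrete feature vectors for a chain: an (n_residues, n_features)
    integer array in canonical feature order.  'X' amino acids map to
    letter 0 with a one-time warning."""
    global _warned_x
    n = len(features)
    out = np.zeros((n, len(FEATURE_NAMES)), dtype=np.intp)
    for f, name in enumerate(FEATURE_NAMES):
        if name == "aa":
            col = []
            for fv in features:
                if fv.aa == "X":
                    if not _warned_x:
                        logger.warning("amino acid 'X' mapped to letter 0 ('A')")
                        _warned_x = True
                    col.append(0)
                else:
                    col.append(AA_INDEX[fv.aa])
            out[:, f] = col
        elif name in VECTOR_FEATURES:
            if name not in alphabet_set.vector:
                raise KeyError(f"no trained alphabet for feature {name!r}")
            arr = np.vstack([getattr(fv, name) for fv in features])
            out[:, f] = assign_vector_letters(arr, alphabet_set.vector[name])
        else:
            if name not in alphabet_set.scalar:
                raise KeyError(f"no trained alphabet for feature {name!r}")
            vals = np.array([getattr(fv, name) for fv in features], dtype=float)
            out[:, f] = assign_scalar_letters(vals, alphabet_set.scalar[name])
    return out
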