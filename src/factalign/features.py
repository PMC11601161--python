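"""Per-residue structural feature vectors.

Each Cα is described by its amino acid plus rotation/translation-invariant
geometry: the distance and signed chain offset to its nearest Euclidean
neighbour (NEN, subject to a minimum chain separation) and to the reverse
Euclidean neighbour (REN, the nearest neighbour on the opposite chain side
of the position from the NEN); the distance to the second-nearest
neighbour; and local-conformation windows ("Conf") of all-vs-all pairwise
Cα distances among the 2κ+1 positions centred at the residue, its NEN and
its REN, with the 2κ chain-adjacent pairs excluded because their distance
is fixed by the virtual bond length.  κ = 3 by default.

Termini are mirror-padded so Conf vectors have the same dimension
d(κ) = C(2κ+1, 2) − 2κ at every position.  When no eligible NEN or REN
exists, the residue's own window is reused and a bounded sentinel distance
(20 Å) and offset (the clip value) are recorded, which keeps the
downstream binning stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import ChainStructure

SENTINEL_DIST = 20.0  # Å, recorded when no eligible neighbour exists
TIE_TOL = 1e-6  # Å; distances closer than this are treated as tied

#: Canonical feature order of the discrete feature vector.
FEATURE_NAMES = (
    "aa", "conf_self", "conf_nen", "conf_ren",
    "dist_nen", "dist_ren", "nen_offset", "ren_offset", "dist_n2",
)
VECTOR_FEATURES = ("conf_self", "conf_nen", "conf_ren")
SCALAR_FEATURES = ("dist_nen", "dist_ren", "nen_offset", "ren_offset", "dist_n2")


@dataclass(frozen=True)
class FeatureParams:
    kappa: int = 3
    min_chain_sep: int = 2
    offset_clip: int = 32

    def __post_init__(self) -> None:
        if self.kappa < 1 or self.min_chain_sep < 1:
            raise ValueError("kappa and min_chain_sep must be >= 1")

    @property
    def conf_dim(self) -> int:
        """d(κ) = C(2κ+1, 2) − 2κ."""
        w = 2 * self.kappa + 1
        return w * (w - 1) // 2 - 2 * self.kappa


@dataclass
class FeatureVector:
    """Real-valued features of one residue (pre-discretisation)."""

    aa: str
    nen_index: int | None
    ren_index: int | None
    dist_nen: float
    dist_ren: float
    dist_n2: float
    nen_offset: int
    ren_offset: int
    conf_self: np.ndarray
    conf_nen: np.ndarray
    conf_ren: np.ndarray


def _dist_matrix(s: ChainStructure) -> np.ndarray:
    d = s.coords[:, None, :] - s.coords[None, :, :]
    return np.linalg.norm(d, axis=-1)


def _eligible(n: int, i: int, min_sep: int) -> np.ndarray:
    j = np.arange(n)
    return np.abs(j - i) >= min_sep


def find_nen(s: ChainStructure, i: int, p: FeatureParams = FeatureParams(),
             dmat: np.ndarray | None = None) -> int | None:
    """Nearest Euclidean neighbour of residue ``i`` with |i−j| ≥ min_chain_sep;
    ties broken toward smaller index."""
    n = len(s)
    if not 0 <= i < n:
        raise IndexError(f"residue index {i} out of range for length {n}")
    dm = _dist_matrix(s) if dmat is None else dmat
    mask = _eligible(n, i, p.min_chain_sep)
    if not mask.any():
        return None
    d = np.where(mask, dm[i], np.inf)
    return _argmin_tied(d)


def find_ren(s: ChainStructure, i: int, nen: int,
             p: FeatureParams = FeatureParams(),
             dmat: np.ndarray | None = None) -> int | None:
    """Nearest eligible neighbour on the opposite chain side of ``i`` from
    its NEN."""
    n = len(s)
    if not 0 <= i < n:
        raise IndexError(f"residue index {i} out of range for length {n}")
    dm = _dist_matrix(s) if dmat is None else dmat
    j = np.arange(n)
    if nen > i:
        side = j <= i - p.min_chain_sep
    else:
        side = j >= i + p.min_chain_sep
    if not side.any():
        return None
    d = np.where(side, dm[i], np.inf)
    return _argmin_tied(d)


def _argmin_tied(d: np.ndarray) -> int:
    """Smallest index among distances within TIE_TOL of the minimum.

    Symmetric backbones (idealised helices, collinear traces) produce
    exactly tied neighbour distances up to float rounding; a hard argmin
    would break rotation invariance of the tie direction."""
    m = d.min()
    return int(np.flatnonzero(d <= m + TIE_TOL)[0])


def _reflect(idx: int, n: int) -> int:
    # mirror across the termini until the index is in range
    while idx < 0 or idx >= n:
        if idx < 0:
            idx = -idx
        else:
            idx = 2 * (n - 1) - idx
    return idx


def conf_window(s: ChainStructure, i: int, kappa: int = 3,
                dmat: np.ndarray | None = None) -> np.ndarray:
    """Pairwise distances among window positions i−κ..i+κ (mirror-padded),
    excluding the 2κ chain-adjacent pairs."""
    n = len(s)
    if not 0 <= i < n:
        raise IndexError(f"residue index {i} out of range for length {n}")
    dm = _dist_matrix(s) if dmat is None else dmat
    win = [_reflect(i + k, n) for k in range(-kappa, kappa + 1)]
    out = []
    w = len(win)
    for a in range(w):
        for b in range(a + 1, w):
            if b == a + 1:
                continue  # adjacent pair, effectively constant distance
            out.append(dm[win[a], win[b]])
    return np.asarray(out)


def extract_features(
    s: ChainStructure, p: FeatureParams = FeatureParams()
) -> list[FeatureVector]:
    """One :class:`FeatureVector` per residue of ``s``."""
    n = len(s)
    if n < 2:
        raise ValueError(f"{s.id}: need at least 2 residues to extract features")
    dm = _dist_matrix(s)
    clip = p.offset_clip
    conf_cache: dict[int, np.ndarray] = {}

    def conf(i: int) -> np.ndarray:
        if i not in conf_cache:
            conf_cache[i] = conf_window(s, i, p.kappa, dmat=dm)
        return conf_cache[i]

    out: list[FeatureVector] = []
    for i in range(n):
        nen = find_nen(s, i, p, dmat=dm)
        if nen is None:
            fv = FeatureVector(
                aa=s.aa[i], nen_index=None, ren_index=None,
                dist_nen=SENTINEL_DIST, dist_ren=SENTINEL_DIST,
                dist_n2=SENTINEL_DIST, nen_offset=clip, ren_offset=clip,
                conf_self=conf(i), conf_nen=conf(i), conf_ren=conf(i),
            )
            out.append(fv)
            continue
        ren = find_ren(s, i, nen, p, dmat=dm)
        # second-nearest eligible neighbour
        mask = _eligible(n, i, p.min_chain_sep)
        d = np.where(mask, dm[i], np.inf)
        order = np.argsort(d, kind="stable")
        dist_n2 = float(d[order[1]]) if mask.sum() >= 2 else SENTINEL_DIST
        if not np.isfinite(dist_n2):
            dist_n2 = SENTINEL_DIST
        if ren is None:
            dist_ren, ren_off, conf_ren = SENTINEL_DIST, clip, conf(i)
        else:
            dist_ren = float(dm[i, ren])
            ren_off = int(np.clip(ren - i, -clip, clip))
            conf_ren = conf(ren)
        out.append(FeatureVector(
            aa=s.aa[i], nen_index=nen, ren_index=ren,
            dist_nen=float(dm[i, nen]), dist_ren=dist_ren, dist_n2=dist_n2,
            nen_offset=int(np.clip(nen - i, -clip, clip)), ren_offset=ren_off,
            conf_self=conf(i), conf_nen=conf(nen), conf_ren=conf_ren,
        ))
    return out
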