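"""Alignment-quality statistic and empirical E-values.

The test statistic combines a superposition-free distance-preservation
score (LDDT-mu, symmetrised over both structures as reference), the local
alignment score ``s``, and the reversed-query score ``s_rev`` used as a
null-like correction:

    t  = δ·Δ + (α·s − β·s_rev) / (L + λ),      L = (|Q| + |T|) / 2
    AQ = 1 / (1 + ½·10^((a + b·t)/10)),         b < 0

AQ lies in (0, 1), is symmetric in Q and T, and AQ < 0.5 suggests a
spurious alignment.  E-values come from an empirical null: decoy AQ values
(alignments to coordinate-reversed database chains) are fitted with a
linear model of log10 exceedance versus AQ over the upper half of the
decoy distribution, and E(aq) = db_size · P_null(AQ ≥ aq).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import AlignmentResult
from .chain import ChainStructure

LDDT_R0 = 15.0  # Å inclusion radius for reference pairs
LDDT_MIN_SEP = 2  # minimum chain separation of reference pairs
LDDT_TOLERANCES = (0.5, 1.0, 2.0, 4.0)  # Å


@dataclass(frozen=True)
class QualityParams:
    """Constants of the AQ statistic.

    Defaults were fixed by a coarse grid search maximising the separation
    of simulated homologs from decoys (see :func:`tune_quality_params`);
    ``a``/``b`` centre AQ = 0.5 at the homolog/decoy boundary t = a/−b.
    """

    alpha: float = 2.0
    beta: float = 1.0
    delta: float = 1.0
    lam: float = 10.0
    a: float = 8.0
    b: float = -2.0

    def __post_init__(self) -> None:
        if self.b >= 0:
            raise ValueError("b must be negative so larger t gives larger AQ")
        if min(self.alpha, self.beta, self.delta, self.lam) < 0:
            raise ValueError("alpha, beta, delta, lambda must be nonnegative")


@dataclass
class QualityResult:
    delta_lddt: float
    s: float
    s_rev: float
    mean_length: float
    t: float
    aq: float
    evalue: float | None = None


def lddt_mu(a: AlignmentResult, q: ChainStructure, t: ChainStructure) -> float:
    """Symmetrised local-distance-difference score of an alignment.

    Reference pairs are aligned-column pairs within 15 Å in the reference
    structure with chain separation ≥ 2; preservation is tested at
    tolerances 0.5/1/2/4 Å, averaged, then averaged per column, over both
    choices of reference, and over columns.  Empty alignments (or columns
    with no reference pairs) score 0.
    """
    if len(a.columns) == 0:
        return 0.0
    qi = np.array([c[0] for c in a.columns])
    ti = np.array([c[1] for c in a.columns])
    if qi.max() >= len(q) or ti.max() >= len(t):
        raise IndexError("alignment column index out of range")
    qc = q.coords[qi]
    tc = t.coords[ti]
    dq = np.linalg.norm(qc[:, None] - qc[None, :], axis=-1)
    dt = np.linalg.norm(tc[:, None] - tc[None, :], axis=-1)
    diff = np.abs(dq - dt)
    # mean preserved fraction over tolerance ladder
    pres = np.mean([diff < tau for tau in LDDT_TOLERANCES], axis=0)
    k = len(a.columns)
    off = ~np.eye(k, dtype=bool)
    per_col = np.zeros(k)
    for idx, dref in ((qi, dq), (ti, dt)):
        sep = np.abs(idx[:, None] - idx[None, :]) >= LDDT_MIN_SEP
        mask = (dref <= LDDT_R0) & sep & off
        counts = mask.sum(axis=1)
        score = np.where(counts > 0, (pres * mask).sum(axis=1)
                         / np.maximum(counts, 1), 0.0)
        per_col += 0.5 * score
    return float(per_col.mean())


def aq_statistic(
    delta_lddt: float, s: float, s_rev: float,
    len_q: int, len_t: int, p: QualityParams = QualityParams(),
) -> QualityResult:
    """AQ from its components; symmetric under swapping Q and T lengths."""
    if len_q < 1 or len_t < 1:
        raise ValueError("chain lengths must be >= 1")
    L = 0.5 * (len_q + len_t)
    t = p.delta * delta_lddt + (p.alpha * s - p.beta * s_rev) / (L + p.lam)
    # overflow-safe sigmoid: exponent clipped far beyond float range
    x = np.clip((p.a + p.b * t) / 10.0, -320.0, 320.0)
    with np.errstate(over="ignore"):
        aq = float(1.0 / (1.0 + 0.5 * np.power(10.0, x)))
    return QualityResult(delta_lddt=delta_lddt, s=s, s_rev=s_rev,
                         mean_length=L, t=t, aq=aq)


class CalibrationError(RuntimeError):
    """Too few decoys, or a degenerate decoy distribution."""


@dataclass
class EvalueCalibration:
    """Linear tail model log10 P(AQ' >= aq) = intercept + slope·aq."""

    intercept: float
    slope: float
    n_ref: int  # database size used during calibration
    n_decoys: int
    aq_median: float  # exceedance is floored at 0.5 below this point

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError("tail slope must be negative")
        if self.n_decoys < 100:
            raise CalibrationError("need >= 100 decoy AQ values")

    def null_exceedance(self, aq: float) -> float:
        p = 10.0 ** (self.intercept + self.slope * aq)
        if aq <= self.aq_median:
            p = max(p, 0.5)
        return float(min(p, 1.0))

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "slope": self.slope,
                "n_ref": self.n_ref, "n_decoys": self.n_decoys,
                "aq_median": self.aq_median}

    @classmethod
    def from_dict(cls, d: dict) -> "EvalueCalibration":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "EvalueCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_evalue(decoy_aqs, n_decoy_comparisons: int) -> EvalueCalibration:
    """Fit the null tail from decoy AQ values.

    Least-squares line through (aq, log10 empirical exceedance) over the
    upper half of the decoy distribution (at least 50 points)."""
    aqs = np.sort(np.asarray(decoy_aqs, dtype=float))
    n = aqs.size
    if n < 100:
        raise CalibrationError(f"need >= 100 decoy AQ values, got {n}")
    # exceedance of the k-th sorted value: fraction of decoys >= it
    exceed = (n - np.arange(n)) / n
    upper = aqs >= np.median(aqs)
    if upper.sum() < 50:
        raise CalibrationError("fewer than 50 points in the upper tail")
    x = aqs[upper]
    y = np.log10(exceed[upper])
    if np.ptp(x) <= 0:
        raise CalibrationError("degenerate decoy distribution")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise CalibrationError("non-decreasing null tail")
    return EvalueCalibration(intercept=float(intercept), slope=float(slope),
                             n_ref=int(n_decoy_comparisons), n_decoys=n,
                             aq_median=float(np.median(aqs)))


def tune_quality_params(
    components: np.ndarray, is_homolog: np.ndarray,
    deltas=(0.0, 1.0, 2.0, 5.0, 10.0),
    alphas=(0.2, 0.5, 1.0, 2.0),
    beta_fracs=(0.0, 0.1, 0.25, 0.5, 1.0),
    lam: float = 10.0, b: float = -2.0,
) -> QualityParams:
    """Grid-search the AQ constants on a labelled benchmark.

    ``components`` has one row (Δ, s, s_rev, L) per scored pair.  The
    selected (δ, α, β) maximise the spread-normalised margin between the
    1st-percentile homolog t and the 99th-percentile decoy t; ``a`` is set
    so AQ = 0.5 falls midway between those two percentiles.
    """
    comp = np.asarray(components, dtype=float)
    is_h = np.asarray(is_homolog, dtype=bool)
    if comp.ndim != 2 or comp.shape[1] != 4:
        raise ValueError("components must be (n, 4): delta, s, s_rev, L")
    if not (is_h.any() and (~is_h).any()):
        raise ValueError("need both homolog and decoy pairs")
    d, s, srev, L = comp.T
    best = None
    for delta in deltas:
        for alpha in alphas:
            for bf in beta_fracs:
                t = delta * d + (alpha * s - bf * alpha * srev) / (L + lam)
                hp = np.percentile(t[is_h], 1)
                dp = np.percentile(t[~is_h], 99)
                spread = t[is_h].std() + t[~is_h].std()
                margin = (hp - dp) / max(spread, 1e-12)
                if best is None or margin > best[0]:
                    best = (margin, delta, alpha, bf, 0.5 * (hp + dp))
    _, delta, alpha, bf, t_mid = best
    return QualityParams(alpha=alpha, beta=bf * alpha, delta=delta,
                         lam=lam, a=-b * t_mid, b=b)


def evalue_of(aq: float, cal: EvalueCalibration, db_size: int) -> float:
    """Expected false positives at score threshold ``aq`` in a database of
    ``db_size`` comparisons: E = db_size · P_null(AQ ≥ aq), clamped."""
    e = db_size * cal.null_exceedance(aq)
    return float(min(max(e, 0.0), db_size))
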