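"""End-to-end wiring: train alphabets and matrices, calibrate E-values,
score structure pairs.

A :class:`Tables` bundle holds everything a search needs — trained
alphabets, per-feature log-odds matrices, alignment/quality parameters and
the E-value calibration — and round-trips through a directory of JSON
files so trained tables can be shipped and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align import AlignParams, AlignmentResult, smith_waterman
from .alphabets import (AlphabetSet, DEFAULT_STRUCT_ALPHABET_SIZE,
                        discretize_chain, train_alphabets)
from .chain import ChainStructure, reverse_chain
from .features import FEATURE_NAMES, FeatureParams, extract_features
from .quality import (EvalueCalibration, QualityParams, aq_statistic,
                      evalue_of, fit_evalue, lddt_mu)
from .scoring import ScoreMatrixSet, accumulate_counts, train_logodds


@dataclass
class Tables:
    """Trained tables bundle: everything needed to align and score."""

    alphabets: AlphabetSet
    matrices: ScoreMatrixSet
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    align_params: AlignParams = field(default_factory=AlignParams)
    quality_params: QualityParams = field(default_factory=QualityParams)
    calibration: EvalueCalibration | None = None

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.alphabets.save(d / "alphabets.json")
        self.matrices.save(d / "matrices.json")
        if self.calibration is not None:
            self.calibration.save(d / "calibration.json")
        import json
        params = {
            "feature_params": {"kappa": self.feature_params.kappa,
                               "min_chain_sep": self.feature_params.min_chain_sep,
                               "offset_clip": self.feature_params.offset_clip},
            "align_params": {"gap_open": self.align_params.gap_open,
                             "gap_extend": self.align_params.gap_extend},
            "quality_params": {"alpha": self.quality_params.alpha,
                               "beta": self.quality_params.beta,
                               "delta": self.quality_params.delta,
                               "lam": self.quality_params.lam,
                               "a": self.quality_params.a,
                               "b": self.quality_params.b},
        }
        (d / "params.json").write_text(json.dumps(params, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "Tables":
        import json
        d = Path(directory)
        params = json.loads((d / "params.json").read_text())
        cal = None
        if (d / "calibration.json").exists():
            cal = EvalueCalibration.load(d / "calibration.json")
        return cls(
            alphabets=AlphabetSet.load(d / "alphabets.json"),
            matrices=ScoreMatrixSet.load(d / "matrices.json"),
            feature_params=FeatureParams(**params["feature_params"]),
            align_params=AlignParams(**params["align_params"]),
            quality_params=QualityParams(**params["quality_params"]),
            calibration=cal,
        )


@dataclass
class ChainProfile:
    """Cached per-structure data reused across pairwise comparisons."""

    chain: ChainStructure
    dfv: np.ndarray
    s_rev: float


def train_tables(
    chains: list[ChainStructure],
    aligned_pairs: list[tuple[ChainStructure, ChainStructure,
                              list[tuple[int, int]]]],
    L: int = DEFAULT_STRUCT_ALPHABET_SIZE,
    seed: int = 0,
    feature_params: FeatureParams | None = None,
    align_params: AlignParams | None = None,
    quality_params: QualityParams | None = None,
    pseudocount: float = 0.5,
) -> Tables:
    """Train alphabets on ``chains`` and log-odds matrices on the trusted
    ``aligned_pairs`` (chain, chain, ground-truth column list)."""
    fp = feature_params or FeatureParams()
    feats = [extract_features(c, fp) for c in chains]
    alphabets = train_alphabets(feats, L=L, seed=seed)
    feat_by_id = {c.id: f for c, f in zip(chains, feats)}

    dfv_align = []
    for qa, ta, cols in aligned_pairs:
        fq = feat_by_id.get(qa.id) or extract_features(qa, fp)
        ft = feat_by_id.get(ta.id) or extract_features(ta, fp)
        dfv_align.append((discretize_chain(fq, alphabets),
                          discretize_chain(ft, alphabets), cols))

    matrices = {}
    sizes = dict(zip(FEATURE_NAMES, alphabets.sizes))
    for name in FEATURE_NAMES:
        counts = accumulate_counts(dfv_align, name, sizes[name],
                                   pseudocount=pseudocount)
        matrices[name] = train_logodds(counts)
    return Tables(
        alphabets=alphabets,
        matrices=ScoreMatrixSet(matrices=matrices),
        feature_params=fp,
        align_params=align_params or AlignParams(),
        quality_params=quality_params or QualityParams(),
    )


def make_profile(chain: ChainStructure, tables: Tables) -> ChainProfile:
    """Discretise a chain and compute its reversed-self score."""
    fp = tables.feature_params
    dfv = discretize_chain(extract_features(chain, fp), tables.alphabets)
    rev = reverse_chain(chain)
    dfv_rev = discretize_chain(extract_features(rev, fp), tables.alphabets)
    s_rev = smith_waterman(dfv, dfv_rev, tables.matrices,
                           tables.align_params).score
    return ChainProfile(chain=chain, dfv=dfv, s_rev=s_rev)


def prepare_profiles(db: list[ChainStructure],
                     tables: Tables) -> dict[str, ChainProfile]:
    return {c.id: make_profile(c, tables) for c in db}


@dataclass
class PairResult:
    """Full result of one pairwise comparison."""

    alignment: AlignmentResult
    delta_lddt: float
    s: float
    s_rev: float
    t: float
    aq: float
    evalue: float | None


def score_pair(
    qp: ChainProfile, tp: ChainProfile, tables: Tables,
    db_size: int | None = None,
) -> PairResult:
    """Align two profiled chains and compute AQ (and E if calibrated)."""
    aln = smith_waterman(qp.dfv, tp.dfv, tables.matrices, tables.align_params)
    d = lddt_mu(aln, qp.chain, tp.chain)
    qr = aq_statistic(d, aln.score, qp.s_rev, len(qp.chain), len(tp.chain),
                      tables.quality_params)
    ev = None
    if tables.calibration is not None and db_size is not None:
        ev = evalue_of(qr.aq, tables.calibration, db_size)
    return PairResult(alignment=aln, delta_lddt=d, s=aln.score,
                      s_rev=qp.s_rev, t=qr.t, aq=qr.aq, evalue=ev)


def calibrate(
    db: list[ChainStructure], tables: Tables,
    profiles: dict[str, ChainProfile] | None = None,
) -> EvalueCalibration:
    """Fit the E-value null from reversed-chain decoys of the database.

    Every query is aligned against the coordinate-reversed copy of every
    other database chain; those AQ values form the empirical null.  The
    calibration is stored on ``tables`` and returned.
    """
    profiles = profiles or prepare_profiles(db, tables)
    rev_profiles = {c.id: make_profile(reverse_chain(c), tables) for c in db}
    decoy_aqs: list[float] = []
    for q in db:
        qp = profiles[q.id]
        for t in db:
            if q.id == t.id:
                continue
            rp = rev_profiles[t.id]
            aln = smith_waterman(qp.dfv, rp.dfv, tables.matrices,
                                 tables.align_params)
            d = lddt_mu(aln, qp.chain, rp.chain)
            qr = aq_statistic(d, aln.score, qp.s_rev,
                              len(qp.chain), len(rp.chain),
                              tables.quality_params)
            decoy_aqs.append(qr.aq)
    cal = fit_evalue(decoy_aqs, n_decoy_comparisons=len(db) - 1)
    tables.calibration = cal
    return cal


def align_chains(
    q: ChainStructure, t: ChainStructure, tables: Tables,
    db_size: int = 1,
) -> PairResult:
    """Convenience: profile and score a single pair of chains."""
    return score_pair(make_profile(q, tables), make_profile(t, tables),
                      tables, db_size=db_size)
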