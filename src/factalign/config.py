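"""Run configuration: every tunable of the pipeline in one INI-style file.

CLI flags override config values; all randomness flows from the single
``seed`` field.  The file round-trips unchanged through load/save.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path

from .align import AlignParams
from .features import FeatureParams
from .quality import QualityParams


@dataclass
class RunConfig:
    seed: int = 0
    alphabet_size: int = 16
    noise_sigma: float = 1.0
    indel_rate: float = 0.05
    pseudocount: float = 0.5
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    align_params: AlignParams = field(default_factory=AlignParams)
    quality_params: QualityParams = field(default_factory=QualityParams)

    def save(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["run"] = {
            "seed": str(self.seed),
            "alphabet_size": str(self.alphabet_size),
            "noise_sigma": repr(self.noise_sigma),
            "indel_rate": repr(self.indel_rate),
            "pseudocount": repr(self.pseudocount),
        }
        fp = self.feature_params
        cp["features"] = {"kappa": str(fp.kappa),
                          "min_chain_sep": str(fp.min_chain_sep),
                          "offset_clip": str(fp.offset_clip)}
        ap = self.align_params
        cp["align"] = {"gap_open": repr(ap.gap_open),
                       "gap_extend": repr(ap.gap_extend)}
        qp = self.quality_params
        cp["quality"] = {k: repr(getattr(qp, k))
                         for k in ("alpha", "beta", "delta", "lam", "a", "b")}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(f"cannot read config file {path}")
        run = cp["run"]
        return cls(
            seed=run.getint("seed"),
            alphabet_size=run.getint("alphabet_size"),
            noise_sigma=run.getfloat("noise_sigma"),
            indel_rate=run.getfloat("indel_rate"),
            pseudocount=run.getfloat("pseudocount"),
            feature_params=FeatureParams(
                kappa=cp["features"].getint("kappa"),
                min_chain_sep=cp["features"].getint("min_chain_sep"),
                offset_clip=cp["features"].getint("offset_clip"),
            ),
            align_params=AlignParams(
                gap_open=cp["align"].getfloat("gap_open"),
                gap_extend=cp["align"].getfloat("gap_extend"),
            ),
            quality_params=QualityParams(
                **{k: cp["quality"].getfloat(k)
                   for k in ("alpha", "beta", "delta", "lam", "a", "b")},
            ),
        )
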