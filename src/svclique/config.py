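"""Run configuration: every tunable of the pipeline with its default.

Defaults follow the published operating point of the method where one is
stated (similarity threshold 0.8, non-overlap normalization 1000 bp, somatic
alpha 0.001, minimum SV size 50 bp); the remaining knobs are documented
choices (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass
class NroParams:
    """Parameters of the normalized reciprocal overlap (NRO) similarity."""

    nro_threshold: float = 0.8
    no_norm: float = 1000.0
    tra_halfwidth: int = 500
    #: "nro" (default) or "classical" (min-ratio reciprocal overlap); the
    #: classical criterion exists for comparative analyses.
    criterion: str = "nro"

    def __post_init__(self):
        if not 0 < self.nro_threshold <= 1:
            raise ValueError("nro_threshold must be in (0, 1]")
        if self.no_norm <= 0:
            raise ValueError("no_norm must be positive")
        if self.tra_halfwidth <= 0:
            raise ValueError("tra_halfwidth must be positive")
        if self.criterion not in ("nro", "classical"):
            raise ValueError("criterion must be 'nro' or 'classical'")


@dataclass
class GenotypeModel:
    """Three-state diploid binomial model over supporting/spanning reads."""

    epsilon: float = 0.1
    priors: tuple = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        total = sum(self.priors)
        if len(self.priors) != 3 or total <= 0:
            raise ValueError("priors must be three positive reals")
        self.priors = tuple(p / total for p in self.priors)


@dataclass
class RunConfig:
    """All pipeline tunables; serializable to/from a plain-text JSON file."""

    # similarity / clustering
    nro_threshold: float = 0.8
    no_norm: float = 1000.0
    tra_halfwidth: int = 500
    criterion: str = "nro"
    min_support: int = 2
    max_sd: float = float("inf")
    min_cohesion: float = 0.0
    # signature extraction
    min_sv_size: int = 50
    max_sv_size: int = 1_000_000
    merge_gap: int = 150
    min_mapq: int = 20
    ins_anchor_dist: int = 100
    # genotyping
    epsilon: float = 0.1
    priors: tuple = (1 / 3, 1 / 3, 1 / 3)
    # somatic
    alpha: float = 0.001
    control_nro_threshold: float = 0.8
    two_sided: bool = False
    bh_correction: bool = False
    # execution
    threads: int = 1
    seed: int = 0

    def nro_params(self) -> NroParams:
        return NroParams(
            nro_threshold=self.nro_threshold,
            no_norm=self.no_norm,
            tra_halfwidth=self.tra_halfwidth,
            criterion=self.criterion,
        )

    def control_nro_params(self) -> NroParams:
        return NroParams(
            nro_threshold=self.control_nro_threshold,
            no_norm=self.no_norm,
            tra_halfwidth=self.tra_halfwidth,
            criterion=self.criterion,
        )

    def genotype_model(self) -> GenotypeModel:
        return GenotypeModel(epsilon=self.epsilon, priors=tuple(self.priors))

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["priors"] = list(d["priors"])
        d["max_sd"] = "inf" if d["max_sd"] == float("inf") else d["max_sd"]
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if d.get("max_sd") == "inf":
            d["max_sd"] = float("inf")
        if "priors" in d:
            d["priors"] = tuple(d["priors"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
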