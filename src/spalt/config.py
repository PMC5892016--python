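"""Run configuration binding the scan and phylogeny parameters together.

A :class:`RunConfig` is fully serialisable (for manifests) and carries the
two parameter families the pipeline needs: the motif-grammar scan
parameters and the tree/orthology parameters, including the 0.95 clade
support threshold used for orthology decisions.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

from .scan import ScanParams


@dataclass(frozen=True)
class PhyloParams:
    score_table: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0
    distance_model: str = "poisson"   # p | poisson | gamma
    gamma_alpha: float = 1.0
    max_gap_fraction: float = 0.5     # alignment-trimming threshold
    n_replicates: int = 200
    support_threshold: float = 0.95
    seed: int = 0

    def validate(self) -> "PhyloParams":
        if self.distance_model not in ("p", "poisson", "gamma"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")
        if not (0 < self.support_threshold <= 1):
            raise ValueError("support_threshold must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 <= self.max_gap_fraction <= 1):
            raise ValueError("max_gap_fraction must be in [0, 1]")
        return self


@dataclass(frozen=True)
class RunConfig:
    scan: ScanParams = field(default_factory=ScanParams)
    phylo: PhyloParams = field(default_factory=PhyloParams)

    def to_dict(self) -> dict:
        return {"scan": asdict(self.scan), "phylo": asdict(self.phylo)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        scan = ScanParams(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in d.get("scan", {}).items()})
        phylo = PhyloParams(**d.get("phylo", {})).validate()
        return cls(scan=scan, phylo=phylo)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, phylo=replace(self.phylo, seed=seed))
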