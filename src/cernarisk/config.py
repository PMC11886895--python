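"""Analysis configuration: the thresholds the whole pipeline runs on.

Defaults mirror the study conditions: interactions kept at confidence
strictly above 0.3; a circRNA–gene pair is competitive when it shares at
least three miRNAs; GWAS variants map to the two closest features per side
plus everything within ±500 kb; differential expression at adjusted
p < 0.05 and linear |fold change| > 1.5; enrichment at FDR < 0.05; a gene
is a "common EC target" when it appears in at least six programs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class Config:
    min_confidence: float = 0.3
    min_shared_mirnas: int = 3
    window_bp: int = 500_000
    n_closest_per_side: int = 2
    de_alpha: float = 0.05
    de_fc_threshold: float = 1.5  # linear scale
    pseudocount: float = 1.0
    enrich_fdr: float = 0.05
    min_program_count: int = 6
    rng_seed: int = 0
    # 0 = exact Brandes betweenness; k>0 = seeded k-pivot approximation
    betweenness_pivots: int = 0

    def __post_init__(self) -> None:
        positive = (
            "min_confidence",
            "min_shared_mirnas",
            "window_bp",
            "n_closest_per_side",
            "de_alpha",
            "de_fc_threshold",
            "enrich_fdr",
            "min_program_count",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be strictly positive")
        if self.de_fc_threshold <= 1:
            raise ValueError("de_fc_threshold must exceed 1 (linear fold change)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
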