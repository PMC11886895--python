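"""Domain types shared by every pipeline stage.

The pipeline reasons about four molecular classes — circRNAs, miRNAs,
mRNAs/genes, and genetic variants — plus the derived objects that connect
them: scored RNA–RNA interactions, competitively regulated circRNA–gene
pairs with their shared-miRNA sets, differential-expression calls, and the
terminal variant → circRNA → miRNA → gene → program circuit chains.

Coordinates are 0-based half-open (BED convention) everywhere; readers that
accept 1-based dialects convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SOURCE_TYPES = {"circRNA", "miRNA"}
VALID_TARGET_TYPES = {"miRNA", "mRNA"}
VALID_TYPE_PAIRS = {("circRNA", "miRNA"), ("miRNA", "mRNA")}
VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """A file violated its declared format; the message names the line."""


@dataclass(frozen=True)
class Interaction:
    """One scored RNA–RNA interaction (circRNA→miRNA or miRNA→mRNA)."""

    source_id: str
    source_type: str
    target_id: str
    target_type: str
    confidence: float

    def __post_init__(self) -> None:
        if (self.source_type, self.target_type) not in VALID_TYPE_PAIRS:
            raise ValueError(
                f"invalid interaction type pair "
                f"({self.source_type} -> {self.target_type}) "
                f"for {self.source_id} -> {self.target_id}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence {self.confidence} outside [0, 1] "
                f"for {self.source_id} -> {self.target_id}"
            )


@dataclass(frozen=True)
class GenomicFeature:
    """A coordinate-bearing circRNA or gene (0-based, half-open)."""

    id: str
    feature_type: str  # "circRNA" | "gene"
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.id}: invalid interval "
                f"[{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"feature {self.id}: invalid strand {self.strand!r}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Variant:
    """A GWAS variant position (0-based)."""

    rsid: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"variant {self.rsid}: negative position {self.pos}")


@dataclass
class ExpressionMatrix:
    """A features × samples log2-scale expression matrix with group labels.

    ``values`` is a pandas DataFrame indexed by feature id with sample-id
    columns; ``labels`` maps every sample id to "case" or "control".
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = list(self.labels.index[self.labels.isna()])
            raise ValueError(f"samples missing from labels: {missing}")
        bad = set(self.labels.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"invalid group labels: {sorted(bad)}")
        counts = self.labels.value_counts()
        for group in ("case", "control"):
            if counts.get(group, 0) < 2:
                raise ValueError(f"fewer than 2 '{group}' samples")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group(self, label: str) -> np.ndarray:
        """Sub-matrix (features × samples) for one label, as a float array."""
        cols = self.labels.index[self.labels == label]
        return self.values[cols].to_numpy(dtype=float)


@dataclass
class DiseaseAnnotation:
    """Evidence flags attaching a feature to the disease.

    ``flags`` is a subset of {"gwas", "known", "de"}: proximity to a GWAS
    variant, curated database membership, or differential expression.
    """

    feature_id: str
    feature_class: str  # "circRNA" | "miRNA" | "gene"
    flags: frozenset[str]

    def __post_init__(self) -> None:
        self.flags = frozenset(self.flags)
        if not self.flags:
            raise ValueError(f"{self.feature_id}: empty evidence flags")
        bad = self.flags - {"gwas", "known", "de"}
        if bad:
            raise ValueError(f"{self.feature_id}: unknown flags {sorted(bad)}")


@dataclass(frozen=True)
class CeRNAPair:
    """A competitively regulated circRNA–gene pair and its shared miRNAs."""

    circ_id: str
    gene_id: str
    shared_mirnas: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared_mirnas)


@dataclass(frozen=True)
class Triplet:
    """One (circRNA, miRNA, gene) expansion of a CeRNAPair."""

    circ_id: str
    mirna_id: str
    gene_id: str


@dataclass(frozen=True)
class VariantAssignment:
    """A variant mapped to a nearby feature.

    ``relation`` is the strongest applicable label: "inside" (distance 0,
    position within the interval), "within_window" (gap ≤ window), or
    "closest_rank_k" (kept by the per-side nearest-k rule regardless of
    distance).
    """

    rsid: str
    feature_id: str
    feature_type: str
    relation: str
    distance_bp: int


@dataclass(frozen=True)
class DEResult:
    """Per-feature two-group differential-expression result."""

    feature_id: str
    log2fc: float
    t_stat: float
    p_value: float
    adj_p: float
    is_de: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided hypergeometric over-representation result for one term."""

    term: str
    overlap_k: int
    term_size_K: int
    query_size_n: int
    universe_N: int
    p_value: float
    fdr: float


@dataclass
class CircuitChain:
    """Terminal variant → circRNA → miRNA → gene → program linkage."""

    circ_id: str
    mirna_id: str
    gene_id: str
    programs: frozenset[str] = field(default_factory=frozenset)
    rsid: str | None = None
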