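"""Variant-to-feature proximity mapping.

Each GWAS variant is assigned the union of (a) every same-chromosome
feature within ±window_bp and (b) the k nearest features lying entirely to
its left and entirely to its right, regardless of distance — computed
separately for circRNAs and for genes. Distance is the gap to the nearest
interval boundary base (0 for containment); strand is ignored. Ties in the
nearest-k ranking break by (distance, start, id) for determinism.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .config import Config
from .models import GenomicFeature, Variant, VariantAssignment

_RELATION_RANK = {"inside": 0, "within_window": 1, "closest_rank_k": 2}


def feature_distance(variant: Variant, feature: GenomicFeature) -> int:
    """Gap in bp between a variant and a half-open interval; 0 if inside."""
    if variant.chrom != feature.chrom:
        raise ValueError(
            f"chromosome mismatch: {variant.rsid} on {variant.chrom}, "
            f"{feature.id} on {feature.chrom}"
        )
    if feature.contains(variant.pos):
        return 0
    if variant.pos < feature.start:
        return feature.start - variant.pos
    return variant.pos - (feature.end - 1)


def map_variant(
    variant: Variant,
    features: Sequence[GenomicFeature],
    window_bp: int = 500_000,
    n_closest_per_side: int = 2,
) -> list[VariantAssignment]:
    """Assign one variant to nearby features (window ∪ per-side nearest-k).

    A feature containing the variant is labeled "inside" and excluded from
    the left/right ranking; one assignment per feature, labeled with its
    strongest relation (inside > within_window > closest_rank_k).
    """
    out: list[VariantAssignment] = []
    by_type: dict[str, list[GenomicFeature]] = {}
    for f in features:
        if f.chrom == variant.chrom:
            by_type.setdefault(f.feature_type, []).append(f)

    for ftype, feats in by_type.items():
        dist = {f.id: feature_distance(variant, f) for f in feats}
        keep: dict[str, str] = {}  # feature id -> relation
        sort_key = lambda f: (dist[f.id], f.start, f.id)
        left = sorted((f for f in feats if f.end <= variant.pos), key=sort_key)
        right = sorted((f for f in feats if f.start > variant.pos), key=sort_key)
        for f in left[:n_closest_per_side] + right[:n_closest_per_side]:
            keep[f.id] = "closest_rank_k"
        for f in feats:
            if dist[f.id] <= window_bp:
                keep[f.id] = "within_window"
        for f in feats:
            if f.contains(variant.pos):
                keep[f.id] = "inside"
        for f in feats:
            if f.id in keep:
                out.append(
                    VariantAssignment(variant.rsid, f.id, ftype, keep[f.id], dist[f.id])
                )
    out.sort(key=lambda a: (a.feature_type, _RELATION_RANK[a.relation], a.distance_bp, a.feature_id))
    return out


def collect_gwas_features(
    variants: Iterable[Variant],
    features: Sequence[GenomicFeature],
    config: Config | None = None,
) -> tuple[set[str], set[str], list[VariantAssignment]]:
    """Union of per-variant assignments, split into circRNA and gene id sets."""
    cfg = config or Config()
    circ_ids: set[str] = set()
    gene_ids: set[str] = set()
    assignments: list[VariantAssignment] = []
    for v in variants:
        for a in map_variant(v, features, cfg.window_bp, cfg.n_closest_per_side):
            assignments.append(a)
            (circ_ids if a.feature_type == "circRNA" else gene_ids).add(a.feature_id)
    return circ_ids, gene_ids, assignments


def variants_on_circrnas(
    variants: Iterable[Variant], circ_features: Sequence[GenomicFeature]
) -> list[tuple[str, str]]:
    """(rsid, circRNA id) pairs where the variant lies inside the circRNA."""
    hits = []
    for v in variants:
        for f in circ_features:
            if f.chrom == v.chrom and f.contains(v.pos):
                hits.append((v.rsid, f.id))
    return sorted(hits)
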