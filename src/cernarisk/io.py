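"""Readers and writers for the plain-text formats the pipeline touches.

All files are UTF-8, tab-delimited, LF-terminated. Readers validate rather
than coerce: a malformed row raises :class:`~cernarisk.models.FormatError`
or ``ValueError`` naming the offending line. Round trips (write → read) are
identity for interactions, BED, and GMT.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import (
    CeRNAPair,
    CircuitChain,
    DEResult,
    EnrichmentResult,
    FormatError,
    GenomicFeature,
    Interaction,
    ExpressionMatrix,
    Triplet,
    Variant,
    VariantAssignment,
)

INTERACTION_COLUMNS = ["source_id", "source_type", "target_id", "target_type", "confidence"]


def _lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if line:
                yield lineno, line


# ---------------------------------------------------------------------------
# interactions


def read_interactions(path: str | Path, min_confidence: float = 0.3) -> list[Interaction]:
    """Load a scored interaction table, deduplicate, and confidence-filter.

    Keeps records with confidence strictly greater than ``min_confidence``.
    Duplicate (source, target) rows collapse to the maximum confidence
    before filtering.
    """
    rows = list(_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty interaction file")
    header = rows[0][1].split("\t")
    if header != INTERACTION_COLUMNS:
        raise FormatError(
            f"{path}:1: expected header {INTERACTION_COLUMNS}, got {header}"
        )
    best: dict[tuple[str, str], Interaction] = {}
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        if len(parts) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
        sid, stype, tid, ttype, conf_s = parts
        try:
            conf = float(conf_s)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric confidence {conf_s!r}") from None
        try:
            rec = Interaction(sid, stype, tid, ttype, conf)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        key = (sid, tid)
        prev = best.get(key)
        if prev is None or rec.confidence > prev.confidence:
            best[key] = rec
    return [r for r in best.values() if r.confidence > min_confidence]


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(INTERACTION_COLUMNS) + "\n")
        for r in interactions:
            fh.write(
                f"{r.source_id}\t{r.source_type}\t{r.target_id}\t{r.target_type}\t"
                f"{r.confidence:.6g}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path, feature_type: str = "gene") -> list[GenomicFeature]:
    """Parse BED3+ (chrom, start, end[, name, score, strand]); 0-based half-open."""
    features = []
    for lineno, line in _lines(path):
        if line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: BED needs ≥3 columns")
        chrom = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
        name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
        strand = parts[5] if len(parts) > 5 else "."
        try:
            features.append(GenomicFeature(name, feature_type, chrom, start, end, strand))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return features


def write_bed(features: Iterable[GenomicFeature], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t.\t{f.strand}\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse standard GMT (name, description, tab-separated members)."""
    sets: dict[str, set[str]] = {}
    for lineno, line in _lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, ≥1 member")
        name, members = parts[0], [m for m in parts[2:] if m]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = set(members)
    return sets


def write_gmt(collection: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            fh.write(name + "\tna\t" + "\t".join(sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(
    path: str | Path,
    labels_path: str | Path,
    already_log2: bool = True,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Load a features × samples matrix plus a two-column sample-label file.

    If ``already_log2`` is False the values are treated as linear and
    transformed with log2(x + pseudocount).
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None
    for col in values.columns:
        if not pd.api.types.is_numeric_dtype(values[col]):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            feature = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric value in sample {col!r}, feature {feature!r}"
            )
    if values.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")

    labels = {}
    for lineno, line in _lines(labels_path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{labels_path}:{lineno}: expected 'sample<TAB>group'")
        labels[parts[0]] = parts[1]
    missing = [s for s in values.columns if s not in labels]
    if missing:
        raise ValueError(f"{labels_path}: samples missing from labels: {missing}")

    if not already_log2:
        arr = values.to_numpy(dtype=float)
        if (arr + pseudocount <= 0).any():
            raise ValueError(f"{path}: value + pseudocount ≤ 0; cannot log2 transform")
        values = pd.DataFrame(
            np.log2(arr + pseudocount), index=values.index, columns=values.columns
        )
    return ExpressionMatrix(
        values=values.astype(float),
        labels=pd.Series({s: labels[s] for s in values.columns}),
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path, labels_path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
    with open(labels_path, "w", encoding="utf-8", newline="\n") as fh:
        for sample, group in matrix.labels.items():
            fh.write(f"{sample}\t{group}\n")


# ---------------------------------------------------------------------------
# variants and id lists


def read_variants(path: str | Path) -> list[Variant]:
    """TSV with header rsid, chrom, pos (extra columns ignored)."""
    rows = list(_lines(path))
    if not rows:
        raise FormatError(f"{path}: empty variant file")
    header = rows[0][1].split("\t")
    for col in ("rsid", "chrom", "pos"):
        if col not in header:
            raise FormatError(f"{path}:1: missing column {col!r}")
    idx = {c: header.index(c) for c in ("rsid", "chrom", "pos")}
    variants, seen = [], set()
    for lineno, line in rows[1:]:
        parts = line.split("\t")
        try:
            rsid, chrom, pos = parts[idx["rsid"]], parts[idx["chrom"]], int(parts[idx["pos"]])
        except (IndexError, ValueError):
            raise FormatError(f"{path}:{lineno}: malformed variant row") from None
        if rsid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate rsid {rsid!r}")
        seen.add(rsid)
        variants.append(Variant(rsid, chrom, pos))
    return variants


def write_variants(variants: Iterable[Variant], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rsid\tchrom\tpos\n")
        for v in variants:
            fh.write(f"{v.rsid}\t{v.chrom}\t{v.pos}\n")


def read_id_list(path: str | Path) -> set[str]:
    """Plain-text id list, one id per line; '#' comments allowed."""
    return {line for _, line in _lines(path) if not line.startswith("#")}


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in sorted(ids):
            fh.write(i + "\n")


# ---------------------------------------------------------------------------
# derived-object tables


def write_pairs(pairs: Sequence[CeRNAPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("circ_id\tgene_id\tn_shared\tshared_mirnas\n")
        for p in pairs:
            fh.write(
                f"{p.circ_id}\t{p.gene_id}\t{p.n_shared}\t"
                + ",".join(sorted(p.shared_mirnas))
                + "\n"
            )


def read_pairs(path: str | Path) -> list[CeRNAPair]:
    pairs = []
    for lineno, line in _lines(path):
        if lineno == 1:
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        pairs.append(CeRNAPair(parts[0], parts[1], frozenset(parts[3].split(","))))
    return pairs


def write_triplets(triplets: Sequence[Triplet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("circ_id\tmirna_id\tgene_id\n")
        for t in triplets:
            fh.write(f"{t.circ_id}\t{t.mirna_id}\t{t.gene_id}\n")


def write_assignments(assignments: Sequence[VariantAssignment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rsid\tfeature_id\tfeature_type\trelation\tdistance_bp\n")
        for a in assignments:
            fh.write(
                f"{a.rsid}\t{a.feature_id}\t{a.feature_type}\t{a.relation}\t{a.distance_bp}\n"
            )


def write_de_results(results: Sequence[DEResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("feature_id\tlog2fc\tt\tp\tadj_p\tis_de\n")
        for r in results:
            t = "inf" if math.isinf(r.t_stat) else f"{r.t_stat:.6g}"
            fh.write(
                f"{r.feature_id}\t{r.log2fc:.6g}\t{t}\t{r.p_value:.6g}\t"
                f"{r.adj_p:.6g}\t{int(r.is_de)}\n"
            )


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term\toverlap_k\tterm_size_K\tquery_size_n\tuniverse_N\tp_value\tfdr\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.overlap_k}\t{r.term_size_K}\t{r.query_size_n}\t"
                f"{r.universe_N}\t{r.p_value:.6g}\t{r.fdr:.6g}\n"
            )


def write_chains(chains: Sequence[CircuitChain], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rsid\tcirc_id\tmirna_id\tgene_id\tprograms\n")
        for c in chains:
            rsid = c.rsid if c.rsid is not None else "."
            fh.write(
                f"{rsid}\t{c.circ_id}\t{c.mirna_id}\t{c.gene_id}\t"
                + ";".join(sorted(c.programs))
                + "\n"
            )
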