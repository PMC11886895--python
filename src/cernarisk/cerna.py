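"""Enumeration of competitively regulated circRNA–gene pairs and triplets.

A circRNA and an mRNA that bind overlapping sets of miRNAs compete for the
same miRNA pool (the ceRNA hypothesis); a pair sharing at least
``min_shared`` miRNAs is called competitively regulated. Rather than
intersecting miRNA sets for every (circRNA, gene) combination — quadratic
in the network size — we count co-occurrences through the shared-miRNA
dimension with a sparse boolean product (equivalently, miRNA-indexed
inverted lists) and materialize the shared sets only for pairs passing the
threshold. Interaction direction is ignored: edges are binding relations.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

from .models import CeRNAPair, Interaction, Triplet


def build_bipartite(
    interactions: Iterable[Interaction],
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Split interactions into circRNA→miRNA-set and gene→miRNA-set maps."""
    circ_map: dict[str, set[str]] = {}
    gene_map: dict[str, set[str]] = {}
    for r in interactions:
        if r.source_type == "circRNA":
            circ_map.setdefault(r.source_id, set()).add(r.target_id)
        else:  # miRNA -> mRNA
            gene_map.setdefault(r.target_id, set()).add(r.source_id)
    return circ_map, gene_map


def _membership_matrix(
    feature_map: Mapping[str, set[str]], mirna_index: Mapping[str, int]
) -> tuple[list[str], sparse.csr_matrix]:
    ids = sorted(feature_map)
    rows, cols = [], []
    for i, fid in enumerate(ids):
        for m in feature_map[fid]:
            rows.append(i)
            cols.append(mirna_index[m])
    mat = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(ids), len(mirna_index)),
    )
    return ids, mat


def enumerate_cerna_pairs(
    circ_map: Mapping[str, set[str]],
    gene_map: Mapping[str, set[str]],
    min_shared: int = 3,
) -> list[CeRNAPair]:
    """All (circRNA, gene) pairs sharing at least ``min_shared`` miRNAs.

    Output is sorted by (circ_id, gene_id) and each pair carries its full
    shared-miRNA set.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be ≥ 1")
    if not circ_map or not gene_map:
        return []
    mirnas = sorted(set().union(*circ_map.values()) | set().union(*gene_map.values()))
    mirna_index = {m: j for j, m in enumerate(mirnas)}
    circ_ids, C = _membership_matrix(circ_map, mirna_index)
    gene_ids, G = _membership_matrix(gene_map, mirna_index)

    counts = (C @ G.T).tocoo()  # n_circ × n_gene shared-miRNA counts
    pairs: list[CeRNAPair] = []
    for ci, gi, n in zip(counts.row, counts.col, counts.data):
        if n >= min_shared:
            c, g = circ_ids[ci], gene_ids[gi]
            pairs.append(CeRNAPair(c, g, frozenset(circ_map[c] & gene_map[g])))
    pairs.sort(key=lambda p: (p.circ_id, p.gene_id))
    return pairs


def expand_triplets(pairs: Sequence[CeRNAPair]) -> list[Triplet]:
    """One (circ, miRNA, gene) triplet per shared miRNA of each pair."""
    return [
        Triplet(p.circ_id, m, p.gene_id)
        for p in pairs
        for m in sorted(p.shared_mirnas)
    ]


def network_summary(pairs: Sequence[CeRNAPair]) -> dict[str, int]:
    """Distinct-entity counts over a pair list and its shared-miRNA sets."""
    mirnas: set[str] = set()
    for p in pairs:
        mirnas |= p.shared_mirnas
    return {
        "n_pairs": len(pairs),
        "n_triplets": sum(p.n_shared for p in pairs),
        "n_circ": len({p.circ_id for p in pairs}),
        "n_mirna": len(mirnas),
        "n_gene": len({p.gene_id for p in pairs}),
    }
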