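"""Endothelial-cell-specific circuits: the pipeline's terminal product.

Genes recurring across many EC gene programs ("common target genes",
default ≥6 of 13) mark shared axes of endothelial dysfunction. A risk
triplet whose gene is common and whose miRNA is a known CAD miRNA becomes
a circuit chain; chains gain an rsid when a GWAS variant lies inside the
chain's circRNA, directly tying genetic risk to a sponge circuit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .models import CircuitChain, Triplet


@dataclass(frozen=True)
class ProgramMembership:
    gene_id: str
    program_names: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.program_names)


def program_frequency(programs: Mapping[str, set[str]]) -> list[ProgramMembership]:
    """One record per distinct gene appearing in ≥1 program, with its programs."""
    membership: dict[str, set[str]] = {}
    for name, members in programs.items():
        for g in members:
            membership.setdefault(g, set()).add(name)
    return [
        ProgramMembership(g, frozenset(ps)) for g, ps in sorted(membership.items())
    ]


def common_genes(programs: Mapping[str, set[str]], min_program_count: int = 6) -> set[str]:
    """Genes present in at least ``min_program_count`` programs."""
    if min_program_count < 1:
        raise ValueError("min_program_count must be ≥ 1")
    return {
        m.gene_id for m in program_frequency(programs) if m.count >= min_program_count
    }


def ec_subnetwork(
    triplets: Iterable[Triplet],
    common_gene_set: set[str],
    known_cad_mirnas: set[str],
    programs: Mapping[str, set[str]] | None = None,
) -> tuple[list[CircuitChain], dict[str, int]]:
    """Triplets with a common target gene AND a known CAD miRNA, as chains.

    Each chain is annotated with the programs containing its gene when a
    program collection is supplied.
    """
    gene_programs: dict[str, frozenset[str]] = {}
    if programs is not None:
        for m in program_frequency(programs):
            gene_programs[m.gene_id] = m.program_names
    chains = [
        CircuitChain(
            circ_id=t.circ_id,
            mirna_id=t.mirna_id,
            gene_id=t.gene_id,
            programs=gene_programs.get(t.gene_id, frozenset()),
        )
        for t in triplets
        if t.gene_id in common_gene_set and t.mirna_id in known_cad_mirnas
    ]
    summary = {
        "n_chains": len(chains),
        "n_circ": len({c.circ_id for c in chains}),
        "n_mirna": len({c.mirna_id for c in chains}),
        "n_gene": len({c.gene_id for c in chains}),
    }
    return chains, summary


def link_variants(
    chains: Sequence[CircuitChain],
    variant_circ_overlaps: Iterable[tuple[str, str]],
) -> list[CircuitChain]:
    """Attach rsids of variants lying inside each chain's circRNA.

    A circRNA hosting v variants yields v copies of each of its chains
    (one per rsid); circRNAs without overlaps pass through with rsid None.
    """
    by_circ: dict[str, list[str]] = {}
    for rsid, circ in variant_circ_overlaps:
        by_circ.setdefault(circ, []).append(rsid)
    out: list[CircuitChain] = []
    for c in chains:
        rsids = by_circ.get(c.circ_id)
        if not rsids:
            out.append(CircuitChain(c.circ_id, c.mirna_id, c.gene_id, c.programs, None))
        else:
            for rsid in sorted(rsids):
                out.append(
                    CircuitChain(c.circ_id, c.mirna_id, c.gene_id, c.programs, rsid)
                )
    return out


def circuit_report(chains: Sequence[CircuitChain]) -> list[dict]:
    """Per-circRNA aggregation ranked by number of distinct target genes."""
    agg: dict[str, dict] = {}
    for c in chains:
        rec = agg.setdefault(
            c.circ_id,
            {"circ_id": c.circ_id, "genes": set(), "mirnas": set(),
             "variants": set(), "programs": set()},
        )
        rec["genes"].add(c.gene_id)
        rec["mirnas"].add(c.mirna_id)
        rec["programs"] |= c.programs
        if c.rsid is not None:
            rec["variants"].add(c.rsid)
    rows = [
        {
            "circ_id": r["circ_id"],
            "n_genes": len(r["genes"]),
            "n_mirnas": len(r["mirnas"]),
            "variants": sorted(r["variants"]),
            "programs": sorted(r["programs"]),
        }
        for r in agg.values()
    ]
    rows.sort(key=lambda r: (-r["n_genes"], r["circ_id"]))
    return rows
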