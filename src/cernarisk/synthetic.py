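"""Synthetic input bundles with planted ground truth.

Every downstream stage is exercised against generated data whose true
structure is known by construction: ceRNA pairs wired through dedicated
shared miRNAs, variants placed inside or near features, two-group
expression with planted log2 effects, and gene programs with a controlled
set of genes recurring across many programs. The generator emits exactly
the text formats the readers consume, plus ``truth.json`` (the planted
truth) and ``manifest.json`` (seed and parameters), and is byte-identical
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io
from .models import ExpressionMatrix, GenomicFeature, Interaction, Variant


@dataclass
class PlantedTruth:
    """Ground truth planted into a synthetic bundle."""

    planted_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_pair_mirnas: dict[str, list[str]] = field(default_factory=dict)  # "circ|gene" -> miRNAs
    planted_de_features: dict[str, float] = field(default_factory=dict)  # id -> signed log2 effect
    planted_variant_hits: dict[str, str] = field(default_factory=dict)  # rsid -> feature inside
    within_window: dict[str, list[str]] = field(default_factory=dict)  # rsid -> features ≤ window
    planted_common_genes: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        data = {
            "planted_pairs": sorted([list(p) for p in self.planted_pairs]),
            "planted_pair_mirnas": {k: sorted(v) for k, v in sorted(self.planted_pair_mirnas.items())},
            "planted_de_features": {k: self.planted_de_features[k] for k in sorted(self.planted_de_features)},
            "planted_variant_hits": dict(sorted(self.planted_variant_hits.items())),
            "within_window": {k: sorted(v) for k, v in sorted(self.within_window.items())},
            "planted_common_genes": sorted(self.planted_common_genes),
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            planted_pairs={tuple(p) for p in d["planted_pairs"]},
            planted_pair_mirnas={k: list(v) for k, v in d["planted_pair_mirnas"].items()},
            planted_de_features=d["planted_de_features"],
            planted_variant_hits=d["planted_variant_hits"],
            within_window={k: list(v) for k, v in d["within_window"].items()},
            planted_common_genes=set(d["planted_common_genes"]),
        )


def _ids(prefix: str, n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"{prefix}_{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# interactome


def generate_interactome(
    n_circ: int,
    n_mirna: int,
    n_gene: int,
    background_edge_prob: float,
    n_planted_pairs: int,
    min_shared: int = 3,
    seed: int = 0,
) -> tuple[list[Interaction], PlantedTruth]:
    """Bipartite interactions with planted shared-miRNA ceRNA pairs.

    Each planted (circRNA, gene) pair is wired through exactly
    ``min_shared`` dedicated miRNAs that are never reused by another
    planted pair and carry no background edges, so zero-background
    recovery is exact. Background circ–miRNA and miRNA–gene edges are
    drawn independently with ``background_edge_prob`` on the remaining
    miRNAs. All confidences are uniform(0.31, 1.0), above the default
    retention threshold.
    """
    if n_planted_pairs > n_circ * n_gene:
        raise ValueError("n_planted_pairs exceeds the number of possible pairs")
    if n_planted_pairs * min_shared > n_mirna:
        raise ValueError("not enough miRNAs for dedicated planted wiring")
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ValueError("background_edge_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    circ_ids = _ids("circ", n_circ)
    mirna_ids = _ids("mir", n_mirna)
    gene_ids = _ids("gene", n_gene)

    pair_codes = rng.choice(n_circ * n_gene, size=n_planted_pairs, replace=False)
    dedicated_order = rng.permutation(n_mirna)
    truth = PlantedTruth()
    edges: dict[tuple[str, str, str, str], None] = {}
    confidences: list[float] = []

    def add_edge(sid: str, stype: str, tid: str, ttype: str) -> None:
        key = (sid, stype, tid, ttype)
        if key not in edges:
            edges[key] = None

    used = 0
    for code in pair_codes:
        c, g = circ_ids[int(code) // n_gene], gene_ids[int(code) % n_gene]
        dedicated = [mirna_ids[int(j)] for j in dedicated_order[used : used + min_shared]]
        used += min_shared
        truth.planted_pairs.add((c, g))
        truth.planted_pair_mirnas[f"{c}|{g}"] = dedicated
        for m in dedicated:
            add_edge(c, "circRNA", m, "miRNA")
            add_edge(m, "miRNA", g, "mRNA")

    background_mirnas = [mirna_ids[int(j)] for j in sorted(dedicated_order[used:])]
    if background_mirnas and background_edge_prob > 0:
        cm = rng.random((n_circ, len(background_mirnas))) < background_edge_prob
        mg = rng.random((len(background_mirnas), n_gene)) < background_edge_prob
        for ci, mi in zip(*np.nonzero(cm)):
            add_edge(circ_ids[int(ci)], "circRNA", background_mirnas[int(mi)], "miRNA")
        for mi, gi in zip(*np.nonzero(mg)):
            add_edge(background_mirnas[int(mi)], "miRNA", gene_ids[int(gi)], "mRNA")

    conf = rng.uniform(0.31, 1.0, size=len(edges))
    interactions = [
        Interaction(sid, stype, tid, ttype, round(float(c), 6))
        for (sid, stype, tid, ttype), c in zip(edges, conf)
    ]
    return interactions, truth


# ---------------------------------------------------------------------------
# genome + variants


def generate_genome_and_variants(
    circ_ids: Sequence[str],
    gene_ids: Sequence[str],
    n_variants: int,
    chrom_length: int = 250_000_000,
    window_bp: int = 500_000,
    n_inside_hits: int = 1,
    seed: int = 0,
    chrom: str = "chr1",
    circ_len_range: tuple[int, int] = (200, 2_000),
    gene_len_range: tuple[int, int] = (2_000, 10_000),
    inside_circ_ids: Sequence[str] | None = None,
) -> tuple[list[GenomicFeature], list[Variant], PlantedTruth]:
    """Place features without overlap on one chromosome and drop variants.

    Exactly ``n_inside_hits`` variants land strictly inside a circRNA
    (``inside_circ_ids`` selects which, else chosen at random); remaining
    variants are uniform over the chromosome, resampled if they would
    accidentally fall inside a circRNA. The truth records both the inside
    hits and, for every variant, the features within ``window_bp``.
    """
    rng = np.random.default_rng(seed)
    if n_inside_hits > min(n_variants, len(circ_ids)):
        raise ValueError("n_inside_hits exceeds n_variants or number of circRNAs")
    n_feat = len(circ_ids) + len(gene_ids)
    lengths = np.concatenate(
        [
            rng.integers(circ_len_range[0], circ_len_range[1] + 1, size=len(circ_ids)),
            rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=len(gene_ids)),
        ]
    )
    total = int(lengths.sum())
    if total > chrom_length:
        raise ValueError(
            f"chrom_length {chrom_length} too small for {n_feat} features "
            f"(need ≥ {total} bp)"
        )
    order = rng.permutation(n_feat)
    slack = chrom_length - total
    cuts = np.sort(rng.integers(0, slack + 1, size=n_feat))
    gaps = np.diff(np.concatenate([[0], cuts]))

    names = list(circ_ids) + list(gene_ids)
    types = ["circRNA"] * len(circ_ids) + ["gene"] * len(gene_ids)
    strands = rng.choice(["+", "-"], size=n_feat)
    features: list[GenomicFeature] = []
    pos = 0
    for slot, idx in enumerate(order):
        idx = int(idx)
        start = pos + int(gaps[slot])
        end = start + int(lengths[idx])
        features.append(
            GenomicFeature(names[idx], types[idx], chrom, start, end, str(strands[idx]))
        )
        pos = end
    by_id = {f.id: f for f in features}
    circ_feats = [f for f in features if f.feature_type == "circRNA"]

    truth = PlantedTruth()
    variants: list[Variant] = []
    if inside_circ_ids is not None:
        if len(inside_circ_ids) != n_inside_hits:
            raise ValueError("inside_circ_ids length must equal n_inside_hits")
        targets = [by_id[c] for c in inside_circ_ids]
    else:
        targets = [circ_feats[int(i)] for i in rng.choice(len(circ_feats), size=n_inside_hits, replace=False)]
    for i, f in enumerate(targets):
        rsid = f"rs{1_000_000 + i}"
        p = int(rng.integers(f.start, f.end))
        variants.append(Variant(rsid, chrom, p))
        truth.planted_variant_hits[rsid] = f.id

    starts = np.array([f.start for f in circ_feats])
    ends = np.array([f.end for f in circ_feats])
    n_bg = n_variants - n_inside_hits
    positions: list[int] = []
    while len(positions) < n_bg:
        cand = rng.integers(0, chrom_length, size=n_bg - len(positions))
        for p in cand:
            inside = bool(((starts <= p) & (p < ends)).any())
            if not inside:
                positions.append(int(p))
    for i, p in enumerate(positions):
        variants.append(Variant(f"rs{2_000_000 + i}", chrom, p))

    f_starts = np.array([f.start for f in features])
    f_ends = np.array([f.end for f in features])
    f_names = np.array([f.id for f in features])
    for v in variants:
        left = f_starts - v.pos  # >0 when feature right of pos
        right = v.pos - (f_ends - 1)  # >0 when feature left of pos
        gap = np.maximum(0, np.maximum(left, right))
        hits = f_names[gap <= window_bp]
        truth.within_window[v.rsid] = sorted(hits.tolist())
    return features, variants, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    feature_ids: Sequence[str],
    n_case: int,
    n_control: int,
    n_de: int,
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    de_feature_ids: Sequence[str] | None = None,
    sample_prefix: str = "s",
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Two-group log2-scale matrix with planted shifts on ``n_de`` features.

    Null features are Normal(mu_f, noise_sd) in both groups with mu_f ~
    Uniform(4, 10); planted features have the case mean shifted by
    ±effect_log2 with random sign.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("each group needs at least 2 samples")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_de > len(feature_ids):
        raise ValueError("n_de exceeds number of features")
    rng = np.random.default_rng(seed)
    n = len(feature_ids)
    mu = rng.uniform(4.0, 10.0, size=n)
    values = rng.normal(0.0, noise_sd, size=(n, n_case + n_control)) + mu[:, None]

    if de_feature_ids is not None:
        if len(de_feature_ids) != n_de:
            raise ValueError("de_feature_ids length must equal n_de")
        unknown = set(de_feature_ids) - set(feature_ids)
        if unknown:
            raise ValueError(f"unknown DE features: {sorted(unknown)[:5]}")
        de_idx = np.array([list(feature_ids).index(f) for f in de_feature_ids], dtype=int)
    else:
        de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=len(de_idx))
    truth = PlantedTruth()
    for i, s in zip(de_idx, signs):
        values[int(i), :n_case] += s * effect_log2
        truth.planted_de_features[feature_ids[int(i)]] = float(s * effect_log2)

    samples = [f"{sample_prefix}_case_{i:02d}" for i in range(1, n_case + 1)] + [
        f"{sample_prefix}_ctrl_{i:02d}" for i in range(1, n_control + 1)
    ]
    labels = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(np.round(values, 6), index=list(feature_ids), columns=samples),
        labels=labels,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# programs


def generate_programs(
    n_programs: int,
    genes_per_program: int,
    gene_pool: Sequence[str],
    n_common: int,
    min_program_count: int = 6,
    seed: int = 0,
    common_candidates: Sequence[str] | None = None,
) -> tuple[dict[str, set[str]], PlantedTruth]:
    """Overlapping gene programs with a designated set of recurrent genes.

    Exactly ``n_common`` genes are each placed in ≥ ``min_program_count``
    programs; every other member appears in at most ``min_program_count``
    − 1 programs, so the frequency filter recovers the designated set
    exactly. Every program has exactly ``genes_per_program`` members.
    """
    if min_program_count > n_programs:
        raise ValueError("min_program_count exceeds the number of programs")
    if n_common > genes_per_program:
        raise ValueError("n_common exceeds genes_per_program")
    pool = list(dict.fromkeys(gene_pool))
    if n_common > len(pool):
        raise ValueError("gene pool too small for n_common")
    rng = np.random.default_rng(seed)

    if common_candidates is not None:
        missing = set(common_candidates) - set(pool)
        if missing:
            raise ValueError(f"common candidates outside pool: {sorted(missing)[:5]}")
        common = list(common_candidates)[:n_common]
    else:
        common = []
    remaining = [g for g in pool if g not in set(common)]
    extra = n_common - len(common)
    if extra:
        common += [remaining[int(i)] for i in rng.choice(len(remaining), size=extra, replace=False)]
    common_set = set(common)

    programs: list[set[str]] = [set() for _ in range(n_programs)]
    for g in common:
        count = int(rng.integers(min_program_count, n_programs + 1))
        for j in rng.choice(n_programs, size=count, replace=False):
            programs[int(j)].add(g)
    if any(len(p) > genes_per_program for p in programs):
        raise ValueError("n_common too large: common genes overflow a program")

    non_common = sorted(set(pool) - common_set)
    cap = min_program_count - 1
    usage = {g: 0 for g in non_common}
    for j in range(n_programs):
        need = genes_per_program - len(programs[j])
        eligible = [g for g in non_common if usage[g] < cap and g not in programs[j]]
        if need > len(eligible):
            raise ValueError(
                f"gene pool too small to fill program {j + 1} "
                f"({need} slots, {len(eligible)} eligible genes)"
            )
        chosen = [eligible[int(i)] for i in rng.choice(len(eligible), size=need, replace=False)]
        for g in chosen:
            programs[j].add(g)
            usage[g] += 1

    collection = {f"EC_program_{j + 1:02d}": programs[j] for j in range(n_programs)}
    truth = PlantedTruth(planted_common_genes=common_set)
    return collection, truth


# ---------------------------------------------------------------------------
# full bundle


@dataclass
class BundleParams:
    """Shape and noise parameters of a complete synthetic input bundle."""

    n_circ: int = 500
    n_mirna: int = 300
    n_gene: int = 10_000
    background_edge_prob: float = 0.05
    n_planted_pairs: int = 20
    min_shared: int = 3
    chrom_length: int = 3_000_000_000
    n_variants: int = 307
    n_inside_hits: int = 2
    window_bp: int = 500_000
    n_case_circ: int = 24
    n_control_circ: int = 7
    n_case_gene: int = 6
    n_control_gene: int = 9
    n_de_circ: int = 25
    n_de_gene: int = 500
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    n_programs: int = 13
    genes_per_program: int = 300
    program_pool_size: int = 2_019
    n_common: int = 20
    min_program_count: int = 6
    n_known_circ: int = 29
    n_known_mirna: int = 179
    n_known_gene: int = 54

    @classmethod
    def paper_shaped(cls) -> "BundleParams":
        return cls()

    @classmethod
    def small(cls) -> "BundleParams":
        return cls(
            n_circ=30, n_mirna=60, n_gene=80,
            background_edge_prob=0.05, n_planted_pairs=5, min_shared=3,
            chrom_length=50_000_000, n_variants=20, n_inside_hits=2,
            window_bp=200_000,
            n_case_circ=10, n_control_circ=10, n_case_gene=10, n_control_gene=10,
            n_de_circ=5, n_de_gene=10,
            n_programs=13, genes_per_program=20, program_pool_size=60,
            n_common=8, min_program_count=6,
            n_known_circ=8, n_known_mirna=30, n_known_gene=10,
        )

    @classmethod
    def preset(cls, name: str) -> "BundleParams":
        if name == "small":
            return cls.small()
        if name == "paper-shaped":
            return cls.paper_shaped()
        raise ValueError(f"unknown preset {name!r}")


def generate_bundle(
    params: BundleParams, seed: int, out_dir: str | Path
) -> tuple[dict[str, Path], PlantedTruth]:
    """Generate and write a complete, internally consistent input bundle.

    The same circRNA/gene id universe threads through the interactome, the
    genome, the expression matrices, the curated disease lists and the
    program collection: planted circRNAs are on the known-circRNA list,
    their dedicated miRNAs on the known-miRNA list, planted pair genes are
    program-common genes and carry planted expression effects, and the
    planted inside-variants sit on planted circRNAs — so the full pipeline
    has a recoverable signal path from variant to circuit.
    """
    p = params
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=8)

    interactions, truth = generate_interactome(
        p.n_circ, p.n_mirna, p.n_gene, p.background_edge_prob,
        p.n_planted_pairs, p.min_shared, seed=int(subseeds[0]),
    )
    circ_ids = _ids("circ", p.n_circ)
    mirna_ids = _ids("mir", p.n_mirna)
    gene_ids = _ids("gene", p.n_gene)
    planted_circs = sorted({c for c, _ in truth.planted_pairs})
    planted_genes = sorted({g for _, g in truth.planted_pairs})
    dedicated_mirnas = sorted({m for ms in truth.planted_pair_mirnas.values() for m in ms})

    inside_circs = planted_circs[: p.n_inside_hits]
    if len(inside_circs) < p.n_inside_hits:
        raise ValueError("fewer planted circRNAs than requested inside hits")
    features, variants, truth_gv = generate_genome_and_variants(
        circ_ids, gene_ids, p.n_variants, p.chrom_length, p.window_bp,
        p.n_inside_hits, seed=int(subseeds[1]), inside_circ_ids=inside_circs,
    )
    truth.planted_variant_hits = truth_gv.planted_variant_hits
    truth.within_window = truth_gv.within_window

    de_circ_ids = [circ_ids[int(i)] for i in
                   np.random.default_rng(int(subseeds[2])).choice(p.n_circ, size=p.n_de_circ, replace=False)]
    expr_circ, truth_ec = generate_expression(
        circ_ids, p.n_case_circ, p.n_control_circ, p.n_de_circ,
        p.effect_log2, p.noise_sd, seed=int(subseeds[3]),
        de_feature_ids=de_circ_ids, sample_prefix="circ",
    )
    de_gene_ids = planted_genes[: p.n_de_gene]
    if len(de_gene_ids) < p.n_de_gene:
        others = [g for g in gene_ids if g not in set(de_gene_ids)]
        extra = np.random.default_rng(int(subseeds[4])).choice(
            len(others), size=p.n_de_gene - len(de_gene_ids), replace=False
        )
        de_gene_ids = de_gene_ids + [others[int(i)] for i in extra]
    expr_gene, truth_eg = generate_expression(
        gene_ids, p.n_case_gene, p.n_control_gene, p.n_de_gene,
        p.effect_log2, p.noise_sd, seed=int(subseeds[5]),
        de_feature_ids=de_gene_ids, sample_prefix="mrna",
    )
    truth.planted_de_features = {**truth_ec.planted_de_features, **truth_eg.planted_de_features}

    pool_rng = np.random.default_rng(int(subseeds[6]))
    pool_extra = [g for g in gene_ids if g not in set(planted_genes)]
    n_extra = min(p.program_pool_size - len(planted_genes), len(pool_extra))
    pool = planted_genes + [pool_extra[int(i)] for i in
                            pool_rng.choice(len(pool_extra), size=n_extra, replace=False)]
    programs, truth_pr = generate_programs(
        p.n_programs, p.genes_per_program, pool, p.n_common,
        p.min_program_count, seed=int(subseeds[7]),
        common_candidates=planted_genes[: p.n_common],
    )
    truth.planted_common_genes = truth_pr.planted_common_genes

    known_rng = np.random.default_rng(seed + 104729)
    def top_up(base: list[str], universe: list[str], n: int) -> list[str]:
        base = base[:n]
        others = [u for u in universe if u not in set(base)]
        need = n - len(base)
        if need > 0:
            base = base + [others[int(i)] for i in
                           known_rng.choice(len(others), size=need, replace=False)]
        return sorted(base)

    known_circ = top_up(planted_circs, circ_ids, p.n_known_circ)
    known_mirna = top_up(dedicated_mirnas, mirna_ids, p.n_known_mirna)
    known_gene = top_up([], gene_ids, p.n_known_gene)

    paths = {
        "interactions": out / "interactions.tsv",
        "circ_bed": out / "circrnas.bed",
        "gene_bed": out / "genes.bed",
        "variants": out / "variants.tsv",
        "expr_circ": out / "expr_circ.tsv",
        "expr_circ_labels": out / "expr_circ_labels.tsv",
        "expr_gene": out / "expr_gene.tsv",
        "expr_gene_labels": out / "expr_gene_labels.tsv",
        "known_circ": out / "known_circ.txt",
        "known_mirna": out / "known_mirna.txt",
        "known_gene": out / "known_gene.txt",
        "programs": out / "programs.gmt",
        "truth": out / "truth.json",
        "manifest": out / "manifest.json",
    }
    io.write_interactions(interactions, paths["interactions"])
    io.write_bed([f for f in features if f.feature_type == "circRNA"], paths["circ_bed"])
    io.write_bed([f for f in features if f.feature_type == "gene"], paths["gene_bed"])
    io.write_variants(variants, paths["variants"])
    io.write_expression(expr_circ, paths["expr_circ"], paths["expr_circ_labels"])
    io.write_expression(expr_gene, paths["expr_gene"], paths["expr_gene_labels"])
    io.write_id_list(known_circ, paths["known_circ"])
    io.write_id_list(known_mirna, paths["known_mirna"])
    io.write_id_list(known_gene, paths["known_gene"])
    io.write_gmt(programs, paths["programs"])
    truth.to_json(paths["truth"])
    manifest = {"seed": seed, "params": dataclasses.asdict(p)}
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return paths, truth
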