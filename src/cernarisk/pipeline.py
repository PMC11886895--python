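"""End-to-end orchestration: stages, manifest, and run report.

Stage order mirrors the analysis workflow: filter interactions → ceRNA
pairs/triplets → GWAS proximity mapping → differential expression (circRNA
and mRNA matrices) → disease-evidence assembly → risk subnetwork →
topology comparison + enrichment → EC circuits → report. Any stage error
aborts the run with the stage name. All outputs are deterministic text;
reruns with the same config, inputs and seed are byte-identical (the
manifest carries no timestamps — wall-clock goes to the stderr log).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import networkx as nx
import yaml

from . import cerna, circuits, io, proximity, risk, synthetic
from .config import Config

logger = logging.getLogger("cernarisk")

INPUT_KEYS = [
    "interactions", "circ_bed", "gene_bed", "variants",
    "expr_circ", "expr_circ_labels", "expr_gene", "expr_gene_labels",
    "known_circ", "known_mirna", "known_gene", "programs",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _relpath(path: Path, root: Path) -> str:
    """Paths inside the run directory are stored relative, for portability."""
    try:
        return str(Path(path).resolve().relative_to(root.resolve()))
    except ValueError:
        return str(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_config(path: str | Path) -> tuple[Config, dict[str, Path]]:
    """Read a YAML run config: threshold fields plus an ``inputs:`` mapping."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    inputs = {k: Path(v) for k, v in (raw.pop("inputs", {}) or {}).items()}
    import dataclasses

    known = {f.name for f in dataclasses.fields(Config)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return Config(**raw), inputs


def run_all(
    config: Config,
    inputs: dict[str, Path] | None,
    out_dir: str | Path,
    synthetic_preset: str | None = None,
    expr_already_log2: bool = True,
) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if synthetic_preset is not None:
        logger.info("[synth] generating '%s' bundle (seed=%d)", synthetic_preset, config.rng_seed)
        params = synthetic.BundleParams.preset(synthetic_preset)
        inputs, _ = synthetic.generate_bundle(params, config.rng_seed, out / "bundle")
    if inputs is None:
        raise ValueError("no inputs given and no synthetic preset requested")
    missing = [k for k in INPUT_KEYS if k not in inputs]
    if missing:
        raise ValueError(f"missing input files in config: {missing}")
    for k in INPUT_KEYS:
        if not Path(inputs[k]).exists():
            raise FileNotFoundError(f"input '{k}' not found: {inputs[k]}")

    manifest: dict = {
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "inputs": {k: {"path": _relpath(Path(inputs[k]), out), "sha256": _sha256(Path(inputs[k]))} for k in INPUT_KEYS},
        "stages": {},
    }
    summaries: dict = {}

    def stage(name):
        logger.info("[%s] running", name)

    def record(name: str, outputs: dict[str, Path], summary: dict) -> None:
        manifest["stages"][name] = {
            "outputs": {k: {"path": _relpath(v, out), "sha256": _sha256(v)} for k, v in outputs.items()},
            "summary": summary,
        }
        summaries[name] = summary

    # --- interactions -----------------------------------------------------
    try:
        stage("interactions")
        interactions = io.read_interactions(inputs["interactions"], config.min_confidence)
        record("interactions", {}, {"n_retained": len(interactions)})
    except Exception as exc:
        raise StageError("interactions", exc) from exc

    # --- ceRNA enumeration ------------------------------------------------
    try:
        stage("cerna")
        circ_map, gene_map = cerna.build_bipartite(interactions)
        pairs = cerna.enumerate_cerna_pairs(circ_map, gene_map, config.min_shared_mirnas)
        triplets = cerna.expand_triplets(pairs)
        pairs_path, trip_path = out / "cerna_pairs.tsv", out / "cerna_triplets.tsv"
        io.write_pairs(pairs, pairs_path)
        io.write_triplets(triplets, trip_path)
        record("cerna", {"pairs": pairs_path, "triplets": trip_path},
               cerna.network_summary(pairs))
    except Exception as exc:
        raise StageError("cerna", exc) from exc

    # --- GWAS proximity ---------------------------------------------------
    try:
        stage("gwas")
        circ_feats = io.read_bed(inputs["circ_bed"], feature_type="circRNA")
        gene_feats = io.read_bed(inputs["gene_bed"], feature_type="gene")
        variants = io.read_variants(inputs["variants"])
        gwas_circ, gwas_gene, assignments = proximity.collect_gwas_features(
            variants, circ_feats + gene_feats, config
        )
        overlaps = proximity.variants_on_circrnas(variants, circ_feats)
        assign_path = out / "variant_assignments.tsv"
        io.write_assignments(assignments, assign_path)
        record("gwas", {"assignments": assign_path},
               {"n_variants": len(variants), "n_nearby_circ": len(gwas_circ),
                "n_nearby_gene": len(gwas_gene), "n_inside_circ": len(overlaps)})
    except Exception as exc:
        raise StageError("gwas", exc) from exc

    # --- differential expression ------------------------------------------
    try:
        stage("de")
        from .diffexpr import call_de

        de_outputs, de_sets = {}, {}
        for tag, mat_key, lab_key in (("circ", "expr_circ", "expr_circ_labels"),
                                      ("gene", "expr_gene", "expr_gene_labels")):
            matrix = io.read_expression(inputs[mat_key], inputs[lab_key],
                                        already_log2=expr_already_log2,
                                        pseudocount=config.pseudocount)
            results = call_de(matrix, config)
            path = out / f"de_{tag}.tsv"
            io.write_de_results(results, path)
            de_outputs[f"de_{tag}"] = path
            de_sets[tag] = {r.feature_id for r in results if r.is_de}
        record("de", de_outputs,
               {"n_de_circ": len(de_sets["circ"]), "n_de_gene": len(de_sets["gene"])})
    except Exception as exc:
        raise StageError("de", exc) from exc

    # --- disease evidence -------------------------------------------------
    try:
        stage("disease_sets")
        known_circ = io.read_id_list(inputs["known_circ"])
        known_mirna = io.read_id_list(inputs["known_mirna"])
        known_gene = io.read_id_list(inputs["known_gene"])
        annotations = risk.assemble_disease_sets(
            gwas_circ=gwas_circ, gwas_gene=gwas_gene,
            known_circ=known_circ, known_mirna=known_mirna, known_gene=known_gene,
            de_circ=de_sets["circ"], de_gene=de_sets["gene"],
        )
        record("disease_sets", {}, risk.annotation_counts(annotations))
    except Exception as exc:
        raise StageError("disease_sets", exc) from exc

    # --- risk subnetwork --------------------------------------------------
    try:
        stage("risk_network")
        net = risk.extract_risk_network(pairs, annotations)
        edges_path = out / "risk_edges.tsv"
        io.write_pairs(net.edges, edges_path)
        graphml_path = out / "risk_network.graphml"
        nx.write_graphml(risk.to_graph(net.edges), graphml_path)
        record("risk_network", {"edges": edges_path, "graphml": graphml_path},
               net.summary())
    except Exception as exc:
        raise StageError("risk_network", exc) from exc

    # --- topology ---------------------------------------------------------
    try:
        stage("topology")
        background = risk.to_graph(pairs)
        disease_ids = {a.feature_id for a in annotations
                       if a.feature_class in ("circRNA", "gene")} & set(background.nodes)
        topo_summary = {}
        if disease_ids and len(disease_ids) < background.number_of_nodes():
            for metric in ("degree", "betweenness"):
                cmp = risk.compare_topology(
                    background, disease_ids, metric,
                    n_pivots=config.betweenness_pivots, seed=config.rng_seed,
                )
                topo_summary[f"{metric}_p"] = cmp.p_value
                topo_summary[f"{metric}_u"] = cmp.u_statistic
        else:
            topo_summary["note"] = "degenerate disease/background split; comparison skipped"
        record("topology", {}, topo_summary)
    except Exception as exc:
        raise StageError("topology", exc) from exc

    # --- enrichment -------------------------------------------------------
    try:
        stage("enrichment")
        programs = io.read_gmt(inputs["programs"])
        universe = {p.gene_id for p in pairs}
        query = {e.gene_id for e in net.edges}
        enr = risk.enrich(query, programs, universe) if universe else []
        enr_path = out / "enrichment.tsv"
        io.write_enrichment(enr, enr_path)
        n_sig = sum(1 for r in enr if r.fdr < config.enrich_fdr)
        record("enrichment", {"enrichment": enr_path},
               {"n_terms": len(enr), "n_significant": n_sig})
    except Exception as exc:
        raise StageError("enrichment", exc) from exc

    # --- EC circuits ------------------------------------------------------
    try:
        stage("ec_circuits")
        common = circuits.common_genes(programs, config.min_program_count)
        risk_triplets = cerna.expand_triplets(net.edges)
        chains, ec_summary = circuits.ec_subnetwork(
            risk_triplets, common, known_mirna, programs
        )
        chains = circuits.link_variants(chains, overlaps)
        chains_path = out / "circuit_chains.tsv"
        io.write_chains(chains, chains_path)
        report_rows = circuits.circuit_report(chains)
        report_path = out / "circuit_report.tsv"
        with open(report_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("circ_id\tn_genes\tn_mirnas\tvariants\tprograms\n")
            for r in report_rows:
                fh.write(f"{r['circ_id']}\t{r['n_genes']}\t{r['n_mirnas']}\t"
                         + ";".join(r["variants"]) + "\t" + ";".join(r["programs"]) + "\n")
        ec_graph = nx.Graph()
        for c in chains:
            ec_graph.add_edge(c.circ_id, c.mirna_id)
            ec_graph.add_edge(c.mirna_id, c.gene_id)
        ec_graphml = out / "ec_subnetwork.graphml"
        nx.write_graphml(ec_graph, ec_graphml)
        ec_summary["n_common_genes"] = len(common)
        ec_summary["n_variant_linked_chains"] = sum(1 for c in chains if c.rsid is not None)
        record("ec_circuits",
               {"chains": chains_path, "report": report_path, "graphml": ec_graphml},
               ec_summary)
    except Exception as exc:
        raise StageError("ec_circuits", exc) from exc

    report_md = report(manifest)
    (out / "report.md").write_text(report_md)
    manifest["report"] = {"path": "report.md",
                          "sha256": _sha256(out / "report.md")}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    logger.info("[done] manifest at %s", manifest_path)
    return manifest


def report(manifest: dict) -> str:
    """Human-readable markdown summary of a completed run."""
    s = manifest["stages"]
    lines = ["# ceRNA risk-network run report", ""]
    lines += [f"Seed: {manifest['seed']}", ""]

    def sec(title: str, rows: dict) -> None:
        lines.append(f"## {title}")
        lines.append("")
        if not rows:
            lines.append("(nothing to report)")
        for k, v in rows.items():
            if isinstance(v, float):
                v = f"{v:.4g}"
            lines.append(f"- {k}: {v}")
        lines.append("")

    sec("Interactions retained", s["interactions"]["summary"])
    sec("Global ceRNA network", s["cerna"]["summary"])
    sec("GWAS proximity", s["gwas"]["summary"])
    sec("Differential expression", s["de"]["summary"])
    sec("Disease-associated features", s["disease_sets"]["summary"])
    sec("Risk subnetwork", s["risk_network"]["summary"])
    sec("Topology (disease vs background)", s["topology"]["summary"])
    sec("Program enrichment", s["enrichment"]["summary"])
    sec("EC-specific circuits", s["ec_circuits"]["summary"])
    return "\n".join(lines)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
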