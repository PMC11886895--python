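"""CAD risk subnetwork extraction, topology comparison, and enrichment.

Disease evidence (GWAS proximity, curated databases, differential
expression) is unioned per feature; the risk subnetwork keeps exactly the
ceRNA edges with at least one annotated circRNA or gene endpoint. Its
nodes are compared to the full background network on degree and
betweenness (disease nodes are expected to be hubs/bottlenecks), and its
genes are tested for gene-set over-representation with a one-sided
hypergeometric test and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .diffexpr import bh_adjust
from .models import CeRNAPair, DiseaseAnnotation, EnrichmentResult


@dataclass
class RiskNetwork:
    """ceRNA edges retained by the disease filter, plus node metadata."""

    edges: list[CeRNAPair]
    nodes: dict[str, tuple[str, frozenset[str]]]  # id -> (class, flags)

    def summary(self) -> dict[str, int]:
        return {
            "n_edges": len(self.edges),
            "n_circ": len({e.circ_id for e in self.edges}),
            "n_gene": len({e.gene_id for e in self.edges}),
        }


@dataclass
class TopologyComparison:
    metric: str
    disease_values: np.ndarray
    background_values: np.ndarray
    u_statistic: float
    p_value: float


def assemble_disease_sets(
    gwas_circ: Iterable[str] = (),
    gwas_gene: Iterable[str] = (),
    known_circ: Iterable[str] = (),
    known_mirna: Iterable[str] = (),
    known_gene: Iterable[str] = (),
    de_circ: Iterable[str] = (),
    de_gene: Iterable[str] = (),
) -> list[DiseaseAnnotation]:
    """Union evidence flags per feature; one annotation per (class, id)."""
    flags: dict[tuple[str, str], set[str]] = {}

    def add(ids: Iterable[str], cls: str, flag: str) -> None:
        for i in ids:
            flags.setdefault((cls, i), set()).add(flag)

    add(gwas_circ, "circRNA", "gwas")
    add(gwas_gene, "gene", "gwas")
    add(known_circ, "circRNA", "known")
    add(known_mirna, "miRNA", "known")
    add(known_gene, "gene", "known")
    add(de_circ, "circRNA", "de")
    add(de_gene, "gene", "de")
    return [
        DiseaseAnnotation(fid, cls, frozenset(fl))
        for (cls, fid), fl in sorted(flags.items())
    ]


def annotation_counts(annotations: Sequence[DiseaseAnnotation]) -> dict[str, int]:
    out = {"circRNA": 0, "miRNA": 0, "gene": 0}
    for a in annotations:
        out[a.feature_class] += 1
    return out


def extract_risk_network(
    pairs: Sequence[CeRNAPair], annotations: Sequence[DiseaseAnnotation]
) -> RiskNetwork:
    """Keep the pairs with ≥1 disease-annotated circRNA or gene endpoint.

    miRNA-class annotations do not drive retention; they matter only for
    the downstream circuit filter.
    """
    circ_flags = {a.feature_id: a.flags for a in annotations if a.feature_class == "circRNA"}
    gene_flags = {a.feature_id: a.flags for a in annotations if a.feature_class == "gene"}
    edges = [
        p for p in pairs if p.circ_id in circ_flags or p.gene_id in gene_flags
    ]
    nodes: dict[str, tuple[str, frozenset[str]]] = {}
    for p in edges:
        nodes[p.circ_id] = ("circRNA", circ_flags.get(p.circ_id, frozenset()))
        nodes[p.gene_id] = ("gene", gene_flags.get(p.gene_id, frozenset()))
    return RiskNetwork(edges=edges, nodes=nodes)


def to_graph(pairs: Sequence[CeRNAPair]) -> nx.Graph:
    """Undirected simple graph over circRNA and gene nodes."""
    g = nx.Graph()
    for p in pairs:
        g.add_node(p.circ_id, node_class="circRNA")
        g.add_node(p.gene_id, node_class="gene")
        g.add_edge(p.circ_id, p.gene_id, n_shared=p.n_shared)
    return g


def node_degree(network: nx.Graph | Sequence[CeRNAPair]) -> dict[str, int]:
    g = network if isinstance(network, nx.Graph) else to_graph(network)
    return dict(g.degree())


def node_betweenness(
    network: nx.Graph | Sequence[CeRNAPair],
    n_pivots: int = 0,
    seed: int = 0,
) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (halved for undirected graphs).

    ``n_pivots > 0`` switches to the seeded pivot-sampling approximation
    for large networks; 0 runs exact Brandes.
    """
    g = network if isinstance(network, nx.Graph) else to_graph(network)
    k = None if n_pivots <= 0 or n_pivots >= g.number_of_nodes() else n_pivots
    return nx.betweenness_centrality(g, k=k, normalized=False, seed=seed if k else None)


def compare_topology(
    network: nx.Graph | Sequence[CeRNAPair],
    disease_node_ids: Iterable[str],
    metric: str = "degree",
    n_pivots: int = 0,
    seed: int = 0,
) -> TopologyComparison:
    """One-sided Mann–Whitney U: disease-node metric > background-node metric.

    Uses the exact U null when both groups have ≤8 values and no ties,
    the tie-corrected normal approximation otherwise.
    """
    if metric == "degree":
        values: Mapping[str, float] = node_degree(network)
    elif metric == "betweenness":
        values = node_betweenness(network, n_pivots=n_pivots, seed=seed)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    disease = set(disease_node_ids)
    unknown = disease - values.keys()
    if unknown:
        raise ValueError(f"disease nodes absent from network: {sorted(unknown)[:5]}")
    d = np.array([v for n, v in values.items() if n in disease], dtype=float)
    b = np.array([v for n, v in values.items() if n not in disease], dtype=float)
    if d.size == 0 or b.size == 0:
        raise ValueError("both disease and background groups must be non-empty")
    u, p = stats.mannwhitneyu(d, b, alternative="greater", method="auto")
    return TopologyComparison(metric, d, b, float(u), float(p))


def enrich(
    query_genes: Iterable[str],
    term_sets: Mapping[str, set[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation per term, BH across terms.

    p = P[X ≥ k], X ~ Hypergeom(N, K, n) with N the universe size, K the
    term size within the universe, n the query size, k the overlap.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    extra = set(query_genes) - universe
    if extra:
        raise ValueError(f"query genes outside universe: {sorted(extra)[:5]}")
    N, n = len(universe), len(query)
    results = []
    for term in sorted(term_sets):
        members = term_sets[term] & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(EnrichmentResult(term, k, K, n, N, min(p, 1.0), fdr=np.nan))
    fdr = bh_adjust([r.p_value for r in results]) if results else []
    results = [
        EnrichmentResult(r.term, r.overlap_k, r.term_size_K, r.query_size_n,
                         r.universe_N, r.p_value, float(f))
        for r, f in zip(results, fdr)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
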