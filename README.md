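# cernarisk

Variant-to-circuit analysis of circRNA-mediated competing-endogenous-RNA
(ceRNA) networks in coronary artery disease (CAD) risk.

## The problem

Most CAD GWAS variants fall in non-coding sequence, and many of the genes
they influence are regulated post-transcriptionally by microRNAs. Circular
RNAs (circRNAs) can sequester ("sponge") miRNAs: a circRNA and an mRNA
that bind overlapping miRNA sets compete for the same miRNA pool, so a
variant that disrupts a circRNA can ripple through every gene downstream
of its sponged miRNAs. `cernarisk` turns that idea into a reproducible
pipeline for researchers studying non-coding regulation in cardiovascular
genetics:

1. **ceRNA network** — from scored circRNA–miRNA and miRNA–mRNA
   interaction tables (confidence > 0.3), enumerate every circRNA–mRNA
   pair sharing ≥ 3 miRNAs and expand each pair into its
   (circRNA, miRNA, mRNA) triplets.
2. **GWAS proximity** — map each CAD variant to the two closest circRNAs
   and genes on either side plus everything within ±500 kb, and flag
   variants lying *inside* a circRNA.
3. **Differential expression** — Welch *t* per feature on log2 case/control
   matrices, Benjamini–Hochberg adjustment, calls at adj. *p* < 0.05 and
   linear |fold change| > 1.5.
4. **Risk subnetwork** — keep ceRNA edges with ≥ 1 endpoint that is
   GWAS-nearby, database-curated, or differentially expressed; compare
   degree and betweenness of disease nodes against the background network
   (one-sided Mann–Whitney U) and run hypergeometric gene-set enrichment
   (BH FDR < 0.05) on the subnetwork's genes.
5. **EC circuits** — intersect risk triplets with genes recurring in ≥ 6
   of 13 endothelial-cell (EC) gene programs and with known CAD miRNAs,
   then attach GWAS variants that sit inside the chain's circRNA. The
   terminal product is the circuit chain
   variant → circRNA → miRNA → gene → program.

A synthetic-data module generates complete input bundles with planted
ground truth (planted ceRNA pairs, inside-variants, expression effects,
program-common genes), so every stage is testable end to end without any
database download.

## Core quantities

For a circRNA *c* with miRNA set *M(c)* and gene *g* with miRNA set
*M(g)*, the pair (*c*, *g*) is competitively regulated when
|*M(c)* ∩ *M(g)*| ≥ *k* (default *k* = 3); enumeration runs through a
sparse miRNA-indexed co-occurrence product rather than all-pairs
intersection, so paper-scale inputs (500 × 300 × 10,000) finish in
seconds. Enrichment uses the hypergeometric tail
P[X ≥ k], X ~ Hypergeom(N, K, n); topology comparison uses the exact
Mann–Whitney null for small groups and the tie-corrected normal
approximation otherwise.

## Worked example

```bash
cernarisk run --synthetic small --seed 7 --out runs/demo
```

generates a small synthetic bundle (30 circRNAs, 60 miRNAs, 80 genes,
5 planted ceRNA pairs, 2 variants planted inside circRNAs) and runs all
stages. The run report (`runs/demo/report.md`) prints:

```
## Global ceRNA network
- n_pairs: 5
- n_triplets: 15
...
## GWAS proximity
- n_variants: 20
- n_nearby_circ: 28
- n_nearby_gene: 51
- n_inside_circ: 2
...
## EC-specific circuits
- n_chains: 15
- n_circ: 5
- n_mirna: 15
- n_gene: 5
- n_common_genes: 8
- n_variant_linked_chains: 6
```

Reading this: the 5 recovered ceRNA pairs are exactly the 5 planted ones
(each wired through 3 dedicated miRNAs, hence 15 triplets); both planted
inside-variants are found; the 8 program-common genes are recovered; and
the 6 variant-linked chains are the circuits whose circRNA hosts a planted
variant. `runs/demo/manifest.json` records config, input hashes and
per-stage output hashes; rerunning with the same seed reproduces it
byte-for-byte.

Each stage is also exposed as a library function
(`cernarisk.cerna.enumerate_cerna_pairs`, `cernarisk.proximity.map_variant`,
`cernarisk.diffexpr.call_de`, `cernarisk.risk.enrich`, ...) and as a CLI
subcommand (`synth`, `cerna`, `gwasmap`, `de`).

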