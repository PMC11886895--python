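# Methods

## ceRNA pair and triplet enumeration

The competing-endogenous-RNA model treats circRNA–miRNA and miRNA–mRNA
interactions as binding relations (direction is ignored). After retaining
interactions with confidence strictly greater than `min_confidence`
(default 0.3; duplicates collapse to the maximum confidence before
filtering), a circRNA *c* and gene *g* form a competitive pair when they
share at least `min_shared_mirnas` miRNAs (default 3). Enumeration builds
sparse boolean membership matrices over the miRNA dimension and takes
their product — equivalent to miRNA-indexed inverted lists — materializing
shared-miRNA sets only for pairs that pass the threshold. A naive
all-pairs intersection is kept in the test suite as the oracle; the two
agree exactly on hundreds of random instances. Each pair expands into one
triplet per shared miRNA, so the triplet count is the sum of shared-set
sizes.

circRNA and gene identifiers live in separate namespaces (distinct id
prefixes in the generator), so a circRNA named after its host gene can
never alias it.

## Variant proximity mapping

A variant maps to the union of (a) every same-chromosome feature whose
interval gap is ≤ `window_bp` (default ±500 kb, boundary inclusive) and
(b) the `n_closest_per_side` (default 2) nearest features lying entirely
left and entirely right of the position, regardless of distance — so gene
deserts still yield candidates. The two rules are computed separately for
circRNAs and genes. Distance is the gap to the nearest interval boundary
base on 0-based half-open coordinates (0 when the position is inside);
strand and transcription start sites are ignored, matching the common
interval-arithmetic convention. A containing feature is labeled `inside`,
is excluded from the left/right ranking, and dominates the other
relations; ranking ties break by (distance, start, id). Union semantics
(window ∪ per-side nearest-k) are the superset-safe reading of combining
a fixed window with a nearest-neighbour guarantee; the per-side count and
window are both configurable.

## Differential expression

Expression matrices are analyzed on the log2 scale; declared-linear input
is transformed as log2(x + pseudocount) with pseudocount 1. Each feature
gets a Welch unequal-variance *t* (two-sided, Welch–Satterthwaite df) —
assumption-light for small two-group designs and free of any fitted
mean–variance trend; a moderated-*t* empirical-Bayes variant is out of
scope. If both groups are constant the statistic degenerates to
(t = 0, p = 1) for equal means and (±∞, 0) otherwise. Adjustment is
Benjamini–Hochberg step-up (the field default behind "adjusted p" with
FDR-style cutoffs), cross-checked in tests against an independent loop
implementation and statsmodels. The DE call is conjunctive and strict:
adj. p < `de_alpha` (0.05) AND |log2FC| > log2(`de_fc_threshold`)
(1.5 on the linear scale, ≈ 0.585 in log2). Both thresholds are
anti-monotone by construction: tightening either never adds a call.

## Risk subnetwork, topology, enrichment

Disease evidence is a per-feature union of three flags: `gwas`
(proximity-mapped), `known` (curated lists), `de` (differential
expression). The risk subnetwork keeps exactly the ceRNA edges with at
least one annotated circRNA or gene endpoint; miRNA annotations do not
drive edge retention (they gate the circuit stage instead). The
background for topology comparison is the full pre-filter ceRNA network,
with disease nodes taken as the annotated nodes inside it. Degree is
incident-edge count; betweenness is unnormalized shortest-path
betweenness (halved for undirected graphs). Because degree distributions
are heavy-tailed, location shift is tested with a one-sided Mann–Whitney
U (disease > background): exact null when both groups have ≤ 8 untied
values, tie-corrected normal approximation with continuity correction
otherwise. On networks above a few thousand nodes, exact betweenness is
replaced by the seeded pivot-sampling estimator (64 pivots in the
full-scale preset), which is deterministic under a fixed seed; exact
Brandes remains the default.

Enrichment is flat over-representation against any user-supplied GMT
collection: p = P[X ≥ k] with X ~ Hypergeom(N, K, n), K counted inside
the universe, BH across terms, significance at FDR < `enrich_fdr`
(0.05). The universe defaults to all genes of the background ceRNA
network. No GO-DAG traversal or term ancestry is performed.

## EC circuits

Gene programs are consumed as a GMT collection (13 endothelial-cell
programs of 300 genes each in the full-scale preset). "Common target
genes" are those present in ≥ `min_program_count` programs (default 6) —
a configurable threshold, not a constant. A risk-network triplet becomes
a circuit chain when its gene is common AND its miRNA is on the known
CAD-miRNA list; chains inherit the program sets of their gene. Variant
attachment uses strict containment (variant position inside the circRNA
interval, half-open); a circRNA hosting *v* variants duplicates each of
its chains once per rsid. The per-circRNA report ranks by number of
distinct target genes (ties by id). The circuits are drawn from the risk
network rather than the global network — the conservative choice, and
configurable by passing any triplet list.

## Synthetic data: what it emulates, and what it does not

The generator emits the exact formats the readers consume plus
`truth.json`, and is byte-identical under a fixed seed.

- **Interactome** — planted ceRNA pairs are wired through dedicated
  shared miRNAs (never reused across planted pairs, never carrying
  background edges), so zero-background recovery is exact and noisy
  recovery is a superset. Background edges are independent Bernoulli
  (default probability 0.05); confidences are uniform(0.31, 1) so none
  are lost to the retention filter.
- **Genome** — features are placed without overlap on a single 3-Gb
  chromosome (human-genome order of magnitude, so ±500 kb windows cover
  a realistic minority of features); circRNA lengths 200–2,000 bp, gene
  lengths 2–10 kb. Exactly `n_inside_hits` variants are planted strictly
  inside circRNAs; the rest are uniform, resampled out of circRNAs.
- **Expression** — Gaussian noise on the log2 scale (sd 0.5) around
  per-feature baselines uniform in [4, 10]; planted features shift the
  case mean by ±2 log2 units (sign random, exercising both fold-change
  tails). Group sizes follow the study design the pipeline targets:
  24 vs 7 for the circRNA matrix, 6 vs 9 for the mRNA matrix.
- **Programs** — 13 sets of 300 genes drawn from a ~2,000-gene pool;
  exactly `n_common` = 20 designated genes appear in ≥ 6 programs and
  every other member in ≤ 5, so the frequency filter recovers the
  designated set exactly.
- **Curated lists** — sized like their real counterparts (29 circRNAs,
  179 miRNAs, 54 genes) and seeded with the planted circRNAs and
  dedicated miRNAs so a complete variant → circuit signal path exists.

Not emulated: real interaction-database degree distributions, microarray
platform artifacts or probe mapping, negative-binomial count noise, LD
structure among variants, and GO term content. Passing tests therefore
demonstrate algorithmic correctness and statistical calibration under a
clean generative model — not robustness to those real-data complications.

## Numerical and reproducibility choices

All coordinates are 0-based half-open; 1-based dialects convert at the
reader boundary. Readers reject malformed rows with the offending line
named rather than coercing. Every stochastic component draws from a
`numpy` Generator seeded from one configured seed; the pipeline manifest
records config, input hashes and output hashes, and contains no
timestamps (wall-clock goes to the stderr log), so identical runs are
byte-identical. Degenerate inputs have defined behavior: empty
interaction tables produce empty networks; a fully tied topology metric
yields p = 1; enrichment with an empty universe is an error.

Problem sizes: the default test and acceptance runs use a small preset
(30 × 60 × 80) for breadth and the full-scale preset
(500 × 300 × 10,000, 307 variants, 13 × 300 programs) for the end-to-end
determinism and calibration checks; the calibration simulations use 200
null replicates of 1,000 features and 50 powered replicates of 200
features at 10 vs 10 samples.

## Known limitations

- The Welch *t* on 6 vs 9 or 24 vs 7 arrays is less powerful than a
  moderated-variance model; calls on very small groups are conservative.
- Pivot-sampled betweenness is an estimator; its Mann–Whitney p-value at
  full scale is approximate (exact mode is available at any size).
- Proximity mapping knows nothing about LD: a variant's candidate set is
  purely positional.
- Enrichment treats gene sets as flat and independent; overlapping
  programs are tested separately without decorrelation.
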