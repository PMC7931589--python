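# Methods

This note documents the models, rules and numerical choices behind
`mirgrn`, and what the synthetic validation does and does not demonstrate.

## The comparative model

The unit of analysis is the miRNA *family*: loci sharing an identical seed
(mature positions 2–8, 1-based from the 5' end) and a common ancestral
precursor. Conservation is an **expression** concept here: a family is
conserved when at least one member is detected in every vertebrate group
analyzed, and group-specific when detected exclusively in one group —
regardless of whether the family exists in other genomes. Families never
detected anywhere are excluded before labeling; everything else that is
neither conserved nor exclusive is a shared subset.

## Family assignment

Similarity search is Smith–Waterman local alignment (match +2, mismatch −3,
gap open −5 charged on the first gapped position, extension −2), executed
with Biopython's `PairwiseAligner`. A hit is accepted when aligned query
coverage ≥ 0.80 and aligned identity ≥ 0.70; coverage is defined on the
query (the expressed precursor), the conservative reading. The primary
reference tier is searched first; a secondary tier is consulted only when
the primary yields nothing, and its hits carry a needs-review flag, mirroring
manual curation of second-pass database hits. Ties break by score, then
identity, then lexicographic family name, making assignment independent of
reference order. The test suite checks alignment scores against a
hand-written quadratic Gotoh oracle.

## TMM normalization

Implemented at formula level: the reference sample is the one whose
75th-percentile count fraction is closest to the cross-sample mean. For each
sample against the reference, M and A values are computed over features
nonzero in both libraries; the top/bottom 30 % of M and 5 % of A (two-sided
rank trims) are discarded; the factor is the antilog of the
inverse-variance-weighted mean of the remaining M values, with weights
`1/((N_j−x)/(N_j x) + (N_r−x_r)/(N_r x_r))`; factors are rescaled to
geometric mean 1. Identical or purely depth-scaled libraries give factors of
exactly 1 (all M = 0). One caveat: scaling a single column leaves M, A and
the trimming set unchanged but perturbs the precision weights, so factors
are only *approximately* invariant to per-column scaling (the same holds for
any precision-weighted TMM); the property test bounds the drift at 0.02 in
log space.

Because each species contributes its own loci, the locus × species count
matrix has species-disjoint row support and no locus is nonzero in two
samples. The pipeline therefore computes TMM factors on the family-aggregated
(family × species) matrix — families are shared across species — and applies
the per-sample factors to locus-level CPM. Detection uses a configurable
count threshold (default ≥ 5 reads), a proxy for the upstream discovery
pipeline that is out of scope here.

## Exact intersection test

For k sets of sizes `n_1..n_k` drawn uniformly at random from a universe of
`n`, the intersection size X follows an iterated hypergeometric mixture:
`X_2 ~ HG(n, n_1, n_2)` and, given `X_j = m`, `X_{j+1} ~ HG(n, m, n_{j+1})`.
The reported p-value is the exact upper tail `P(X ≥ x)`; k = 2 reduces to
Fisher's one-sided exact test. The universe defaults to the number of
distinct families detected in at least one group (configurable) — the
background size is otherwise unknowable from expression data alone.
Significance is declared at α = 0.005. Tests verify the tail against
brute-force enumeration of all subset configurations for n ≤ 12, k ≤ 3.

## Rank-sum test

U counts favorable pairs (`x_i > y_j`, ties ½). With `n_1+n_2 ≤ 20` and no
ties the p-value is exact, from the permutation distribution of U computed
by the standard counting recurrence; otherwise a normal approximation with
tie correction and a 0.5 continuity correction is used (it agrees with
`scipy.stats.mannwhitneyu` to nine digits in tests, but scipy is only an
oracle, not the implementation). The conserved-vs-specific comparisons are
one-sided ("conserved greater"), matching the expected direction for both
expression level and target count. The per-family expression summary is the
median TMM-CPM over detected member loci — a robust choice where the
summary statistic is otherwise unspecified.

## Target prediction

*3'UTR inference.* The UTR runs from the first base after the stop codon to
the last base of the closest AAUAAA hexamer. If that UTR would exceed
2,500 nt, the closest AUUAAA is used instead; if both exceed the cap the
shorter record is kept with a `long` flag rather than discarded (preserves
the gene while marking uncertainty). No signal within the 10,000-nt scan
window excludes the gene. Coordinates are 0-based half-open throughout, on
the sense strand only.

*Seed predictor.* Exact reverse-complement scan of the 6mer core (positions
2–7), extended by the position-8 match (one base 5' of the core) and the A
opposite position 1 (one base 3'); the longest applicable type among
8mer / 7mer-m8 / 7mer-A1 / 6mer is assigned per occurrence.

*Hybridization predictor.* Gotoh local alignment of the mature (3'→5')
against the UTR (5'→3'): Watson–Crick pair +5, G:U wobble +1 outside the
seed (scored as mismatch inside it), mismatch −3, gap open −8, extension −2.
The energy proxy sums dinucleotide stack terms over maximal gap-free WC runs
(G:C/G:C −3.3, A:U/A:U −0.9, mixed −2.1 kcal/mol). Strict retention requires
score ≥ 80, energy ≤ −7 kcal/mol, and positions 2–8 fully WC-paired without
gaps. These are declared, oracle-testable stand-ins for a thermodynamic
duplex model; the algorithm's shape (local duplex alignment + strict seed)
is what matters for the contract. In the pipeline the duplex scan is
anchored at 6mer-core matches: any alignment passing the strict seed rule
necessarily contains an exact core match, so anchoring loses nothing and
keeps the stage near-linear.

*Consensus.* A (miRNA, gene) pair is kept when a seed site and a passing
duplex have seed-match coordinates within 10 nt (positional mode, default;
a gene-level mode is available). Consensus is a subset of both predictors
by construction. The expression filter then keeps targets with TPM ≥ 1
(boundary inclusive) in that species' heart; genes absent from the TPM
table are dropped and logged.

## Network assembly and analysis

Assembly applies, in order: ortholog mapping to the reference namespace
(many-to-one collisions resolved by confidence then lexicographic order),
the interaction score rule (`experimental > 0` and `combined >
experimental`, both strict), kernel adjacency (kernel genes are always
retained, even isolated — they anchor the network), a conserved-expression
rule for genes (TPM ≥ 1 in ≥ ⌈n/2⌉ of the group's species; the qualitative
requirement is not quantified upstream, so this reuses the interaction
threshold), and the per-group interaction support threshold ⌈n/2⌉ — a single
rule reproducing both stated instances (2 of 3 fish species, 4 of 8
mammals). miRNA families with no surviving target are excluded from the
graph. Validated interactions supplied by the user annotate matching edges.

Graphs are undirected and unweighted for analysis. Closeness is the
within-component normalization `(r−1)/Σd` (0 for isolates). Walktrap is
implemented from its definition: transition matrix `P = D⁻¹A`, node distance
`r_ij² = Σ_k (P^t_ik − P^t_jk)²/d(k)` with t = 4, greedy merging of the
*adjacent* community pair minimizing the Ward-style
`Δσ = (1/n)·|C1||C2|/(|C1|+|C2|)·r²` (community profiles are size-weighted
means), and the reported cut maximizes Newman modularity along the merge
sequence. Adjacency-restricted merging means components are never merged
across. python-igraph's Walktrap serves as an independent cross-check in
tests only. Network comparison is exact edge-set intersection in the shared
(family, reference gene) namespace — Jaccard similarity plus the conserved
interaction list; with integer conserved-interaction counts this is the only
well-defined reading of pairwise network alignment.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the emulated study conditions: 20 species in
five groups (6 fishes, 2 amphibians, 1 reptile, 2 birds, 9 mammals),
54 conserved families, 10 group-specific families per group (a round figure
in the range observed for non-mammal groups; mammal-scale specific counts
would add nothing structurally), 2 loci per family, substitution rate 0.02
per non-seed site, log2-normal counts with means 9 (conserved) vs 7
(specific) and SD 1 — a two-log2-unit planted effect in the direction of
the reported comparisons — dropout probability 0.05, 500 genes with 3 sites
per miRNA, signal offsets of 150–400 nt, and a 600-edge interaction table
around an 8-gene heart kernel. Counts are rounded log-normal draws floored
at 1, with zero-inflation only through dropout — the simplest model
reproducing the expression ordering; the true count distribution of small-RNA
libraries is not modeled. Randomness derives from a single root seed through
per-stage `SeedSequence` spawn keys (catalog 0, counts 1, genes 2, ppi 3),
so outputs are byte-identical per seed regardless of stage subsets.

Planted target sites are full-length Watson–Crick complements of the mature
(reverse complement of positions 2..L plus an A opposite position 1), which
contain a perfect 8mer and pass both predictors — sites complementary only
in the seed would, by design of the strict duplex thresholds, never reach
consensus. Decoy classes each violate exactly one downstream rule: genes
with TPM < 1 (expression filter), sites planted in a single species of a
≥3-species group (support threshold), sites on genes disconnected from the
kernel (kernel filter), and interaction-table strata failing the score rule.
Backgrounds are scrubbed of spurious polyadenylation hexamers and of seed
cores of catalog miRNAs, and ancestral matures are rejection-sampled so no
planted site contains a signal hexamer.

What passing on this data shows: every filter implements its stated rule
exactly, the statistics match independent oracles, and the planted structure
is recovered end to end. What it does not show: robustness to real-data
phenomena the generator omits — sequencing noise and multi-mapping, isomiR
heterogeneity, hairpin structure, annotation errors in reference catalogs
and ortholog maps, UTRs without canonical polyA signals, and biased or
incomplete interaction databases.

## Problem sizes and determinism

Tests run planted-label recovery at 5 groups × 4 species with 65 families;
target recovery at 500 genes × 50 miRNAs; network exactness at 3 fish + 8
mammal species (exercising both stated thresholds); rank-test power at 30
families per arm over 100 seeds and calibration over 500 seeds; and
determinism as two full runs compared byte-for-byte. `scripts/acceptance.py`
runs the full default 20-species configuration. With the default 5 % dropout
a single-species group occasionally loses a planted family (the reptile
group has no redundancy), so label recovery and network agreement are
reported as measured rather than forced to 100 %.

## Known limitations

Novel-miRNA discovery, read processing and mapping are out of scope (inputs
begin at per-species catalogs and count matrices). TargetScan-style context
scores are not computed — site detection only. Only a single reference
(human-like) interaction table is used, mirroring the corresponding upstream
limitation. The Walktrap implementation is dense-matrix (`P^t` via repeated
multiplication) and intended for networks of up to a few thousand nodes.
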