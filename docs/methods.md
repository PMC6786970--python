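# Methods

This note documents the models and procedures implemented in `soilvirome`,
the parameter defaults and why they were chosen, the numerical choices made
where the procedure descriptions were open, and what the synthetic-data tests
do and do not establish.

## Viral populations and host dereplication

Viral contigs are clustered into species-level populations at ≥95% nucleotide
identity.  Identity between two contigs is estimated by k-mer–anchored,
gap-free diagonal comparison: shared 16-mers vote for a diagonal offset, the
dominant diagonal's overlap is scored base-by-base, and the aligned fraction
is the overlap over the shorter sequence.  This estimator is exact for the
substitution-dominated divergence that separates population members; an exact
dynamic-programming aligner (Biopython `PairwiseAligner`) is the test oracle,
with agreement required within ±0.01 on sequences ≤5 kb.  Clustering is
greedy longest-first (ties by id), matching the behaviour of word-based
clustering tools while being fully deterministic.  Membership requires ≥95%
identity over ≥85% of the shorter sequence; the 85% aligned-fraction cutoff
is the community (MIUViG-style) convention and is configurable.  A population
is retained iff its representative is ≥10,000 bp (inclusive) or circular,
where circularity means an exact terminal direct repeat of ≥20 bp.

Host genome bins are dereplicated by single-linkage grouping of pairs with
>95% average amino acid identity, consumed as a precomputed table (protein-
level AAI computation is out of scope).  Each group's representative is its
highest-quality bin, quality = completeness − 4 × contamination, ties broken
by id.

## Abundance profiles

Read alignments are consumed as tabular records (no read sequences); the
viral filter keeps records at ≥95% identity covering ≥90% of the read, the
host filter relaxes the read fraction to 75%.  Coverage per contig is the
truncated mean depth: positions sorted by depth, the lowest and highest
⌊0.1·L⌋ positions dropped, the rest averaged.  The floor convention means
vectors shorter than 10 positions are not trimmed; the rounding is not
specified by the coverage tools this mirrors, so it is documented here and
configurable.  Viral detection requires ≥70% breadth (fraction of positions
with depth ≥1), otherwise the coverage is zeroed — this guards against reads
piling on a short shared element faking a detection.  Host bins combine
per-contig truncated means weighted by contig length, with coverages <0.25×
zeroed.  Sample normalization multiplies each sample by
mean(read totals)/own total; square-root transformation is applied once
before dissimilarity-based statistics.  Both transforms are flagged on the
matrix object and refuse double application.

## Activity detection

Gene-level transcript coverage is the arithmetic mean depth over the gene
interval.  A population is detected in a metatranscriptome iff reads map to
at least one gene per 10 kb of genome; this is implemented as
⌈L/10,000⌉ with a minimum of one.  The worked rule (20 kb → 2 genes) is
consistent with both ceiling and floor; ceiling is the stricter reading and
is the documented, configurable choice (15 kb → 2 genes here).  Coverages of
undetected populations are zeroed, never increased.

## AMG genomic-context screen

Glycoside hydrolases on viral contigs are screened by context:
**excluded** if the contig is proviral or carries any other microbial
metabolic gene (possible host contamination); **high** confidence if at
least one viral hallmark gene (structural/terminase/integrase) lies strictly
upstream *and* one strictly downstream in contig coordinates; **medium**
otherwise.  Upstream/downstream is strand-agnostic because the contig has no
defined orientation.  Verdicts depend only on gene positions, not input
order.

## Virus–host linkage

Five evidence tiers, most to least confident:

1. CRISPR protospacer with PAM.  Spacers (≥20 bp) are scanned against both
   strands of each viral contig at every offset by Hamming distance;
   matches with ≤1 mismatch are kept.  E-values are not computed — for
   20–40 bp words they are aligner-dialect-specific, and the mismatch cap
   plus the length floor bound the false-positive rate.  The PAM (default
   `GG`, configurable; the motif is a required input since no standard
   motif exists across CRISPR systems) must sit immediately 3′ of the
   protospacer **on the match strand**: for minus-strand matches that is the
   reverse complement of the bases immediately preceding the match in
   forward coordinates.
2. CRISPR protospacer without PAM.  Either way, the array's repeat sequence
   must match a host genome exactly (100% identity, full length, either
   strand) to tie the array to a host bin.
3. Shared genomic region covering ≤90% of a host contig (putative
   provirus).  Hits require ≥2,500 bp, ≥70% identity, bit score ≥50 and
   E ≤ 10⁻³ when supplied as external alignment tables; internally
   discovered hits (exact 64-mer seeds, gap-free extension tolerating
   mismatch runs ≤10) satisfy the bit/E thresholds by construction.
4. Shared region covering ≥90% of a host contig (co-binned virus).
5. Nearest tetranucleotide frequency (TNF) signature.  TNF vectors are
   forward-strand 4-mer frequencies in fixed lexicographic order,
   L1-normalized, windows containing N skipped.  The distance is the mean
   absolute component difference with acceptance threshold 10⁻³.  The
   metric and strand convention are choices (the threshold's source does
   not specify them); both are configurable.  Under the mean-absolute
   metric the threshold separates cleanly: two halves of one genome sit at
   ~5×10⁻⁴, genomes from different composition models at ≥3×10⁻³.

All evidence is retained and reported (broad host ranges are real); a single
assignment per virus is then resolved by taking the lowest-numbered tier
present and, when several hosts tie there, the last common ancestor — the
longest common semicolon-delimited rank prefix — of their lineages.
Resolution is invariant to evidence order.

## Gene-sharing network and taxonomy

For two genomes with a and b protein clusters (PCs) sharing c in a universe
of n, the edge weight is −log₁₀[P(X ≥ c) · C], X ~ Hypergeometric(n, a, b),
C = G(G−1)/2 pairwise comparisons among the G genomes analysed (the "total
comparisons" multiplier is not given a formula by its source; pairs-possible
is the defensible reading).  The upper tail is inclusive (P(X ≥ c)); scores
≤0 are floored at 0 and only scores >1 become edges.  A randomization
control permutes PCs within the combined pool of every pair scoring ≤1
(1,000 rounds by default) and reports the maximum score observed; on the
synthetic communities it stays ≤1.

Markov clustering is implemented from scratch: self-loops at each node's
maximum incident weight, column-stochastic normalization, then alternating
expansion (matrix squaring) and inflation (elementwise power 2,
renormalize), pruning entries <10⁻¹², until the matrix changes by <10⁻⁶ or
100 iterations; clusters are connected components of the converged support.
Taxonomy per cluster counts only reference members with near-complete
lineages (≥5 of 7 ranks filled — "near-complete" is not quantified by its
source, so this is the documented choice): at each rank the modal value's
support (fraction of counted references) maps to high/medium/low confidence
at ≥50/30/10%; when references disagree at a rank, deeper ranks are not
called (the call stops at the majority's common ancestor).  Novelty per
population: `taxonomy_assigned` if its cluster has any call,
`shared_with_public` if clustered with reference/public genomes,
`exclusive` otherwise (singletons included).

## Statistics

Bray–Curtis dissimilarities are computed on the square-root–transformed OTU
table; PCoA is Gower double-centering with eigendecomposition, negative
eigenvalues reported, not corrected.  PERMANOVA partitions squared
distances into among/within-group components (pseudo-F); ANOSIM uses rank
dissimilarities; PERMDISP runs a one-way ANOVA on distances to group
centroids computed in PCoA space with the negative-axis correction
(imaginary components subtract), permuting those distances' group labels.
The Mantel test correlates off-diagonal entries by Spearman rank, permuting
rows and columns of one matrix jointly.  The permutation interaction test
for habitat-specific regressions compares a pooled single-line model with a
full per-group slope+intercept model by F ratio, permuting group labels;
groups with fewer than 3 points are excluded from fitting.  Every
permutation p-value is (count of permuted statistics ≥ observed + 1) /
(permutations + 1) with a recorded seed; defaults are 999 permutations
(desk scale — larger counts are a parameter away).  These implementations
are cross-checked in tests against scikit-bio's PERMANOVA/ANOSIM/Mantel
statistics; they are in-package because the tests need explicit seeds, the
+1 convention, and speed (the calibration suite runs 1,500 permutation
tests).

The binomial pervasiveness test is the exact upper tail
P(X ≥ k | n, α) for k of n correlations significant at α; Bonferroni
thresholds are α/n.  PLS regression wraps scikit-learn's NIPALS
implementation (predictors centered and unit-scaled, constant columns
dropped, rows with missing response removed, components capped by the
predictor rank); the reported r is the in-sample Pearson correlation of
fitted vs observed responses, matching how such regressions are usually
summarized; the default component count is min(2, rank) — a flagged choice,
since no component count is prescribed by the analyses this mirrors.

## The synthetic world

The generator's defaults are the stated world the recovery tests measure
against: 20 hosts, 50 viruses, 3 habitats × 10 samples, host genomes of
20 kb (+3 kb satellite contig), viral contigs 10–15 kb, spacers of 32 bp in
6-spacer arrays, link fractions 30% CRISPR (a quarter of those without
PAM) / 30% TNF / 10% provirus / 10% co-binned / 20% unlinked, lognormal(0,1)
baseline abundances with a ×4 preferred-habitat effect, 20–30k reads of
150 bp per sample, 10% of records failing the identity filter and 5% the
aligned-fraction filter, 2 metatranscriptomes per habitat with half the
viruses active, 10-cluster planted PC structure with 10 reference and 5
public genomes, and geochemical responses linear in standardized
virus/host group abundance sums with Gaussian noise (σ = 0.1).  Host
composition models are order-3 Markov chains with independent Dirichlet(1)
transition rows — enough separation that TNF assignment is unambiguous
without real genomes.  Responses use *standardized* predictors so the
coefficient vector and the noise standard deviation live on the same scale;
with raw relative-abundance sums the default coefficients would be
dominated by any O(0.1) noise for accidental unit reasons.

What the synthetic world does **not** emulate: read-level sequence error,
assembly artefacts, chimeras, uneven genome completeness, strain-level
microdiversity within populations, compositional correlations among taxa,
or the field data's ~200-sample depth/time structure.  A green recovery
test therefore establishes that the pipeline's logic is correct on data
satisfying its assumptions — not that the field-scale numbers of any
particular survey are reproduced.  Abundance distribution (lognormal) is a
modelling choice; no distribution is prescribed by the study designs this
emulates.

## Determinism

One global seed fans out to each generator stage via explicit
`SeedSequence(seed, spawn_key=(stage,))` streams, and to the statistics
stage via a SHA-256 stage-name hash reduced below 2³¹.  Identical
configuration and seed reproduce byte-identical output files; the pipeline
manifest records per-file SHA-256 checksums so reruns are verifiable.

## Known limitations

* The identity estimator is gap-free; indel-rich divergence would be
  underestimated (the DP oracle in the tests bounds the error for the
  regimes exercised).
* Internal shared-region discovery requires an exact 64-bp seed; diverged
  proviral remnants below that exactness are only found via external
  alignment tables.
* PERMDISP permutes distances-to-centroid rather than recomputing
  centroids per permutation (the common software default; slightly
  conservative).
* Protein-cluster construction from protein alignments is out of scope;
  memberships are inputs.
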