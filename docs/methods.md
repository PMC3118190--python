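# Methods

This note documents the models, parameter choices and numerical behaviour
of `embryotx`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinates and annotation

All intervals are 0-based half-open internally. BED12 input/output is
native; GTF (1-based inclusive) is converted at the file boundary only, and
both directions of the conversion are tested. A gene model is a set of
sorted, disjoint exons on one strand of one chromosome; the "exon model" is
their union, whose total length is the *L* of RPKM. Distance from an
interval to the annotation is measured to gene *spans* (first-exon start to
last-exon end), strand-agnostically — the proximity filter for novel-region
calling does not care which strand a known gene is on, and using spans
rather than exons is the conservative reading ("near a known gene"
includes its introns). Abutting intervals have distance 0; a chromosome
without genes yields an infinite distance, so candidates there pass any
distance filter.

## Quantification

Read filtering keeps uniquely placed reads (`n_hits == 1`) with alignment
score ≥ 24; the boundary is inclusive. Counting is strand-matched by
default (the library protocol emulated is stranded); an `stranded=False`
flag collapses strands. A read overlapping exons of more than one gene is
assigned to none and tallied as ambiguous — conservative, and the tally
preserves the conservation identity

    assigned + ambiguous + unassigned = reads entering counting,

asserted on every run. The RPKM denominator *N* defaults to the number of
reads that survived filtering (the reads actually counted); an explicit
`library_sizes` argument substitutes externally known totals (e.g. all
mapped reads) when preferred. Detection is C ≥ 2 with the cutoff
configurable. Mapping summaries round percentages to whole percent
(half-up), matching how such tables are conventionally reported.

## Stage sharing

The Venn partition assigns every entity to one of the 2⁴ presence patterns;
the sum over patterns always equals the universe size (asserted). The same
machinery serves gene detection flags and novel-region presence matrices.
Ranking ties are broken by gene_id lexicographic order — arbitrary, but
deterministic and therefore testable; `rank_top(n)` is a prefix of
`rank_top(n+1)`. Replicate agreement is the squared Pearson correlation,
by default on log2(RPKM+1) over genes detected in either replicate; both
the transform and the inclusion rule are arguments and are echoed in the
result object, since neither choice is canonical.

## Profile clustering and trend labels

K-means is a plain Lloyd iteration: Euclidean distance, K = 20, at most 50
iterations, initial centroids drawn as k distinct profiles under the seed,
and an empty cluster reseeded with the point currently farthest from its
centroid. The within-cluster sum of squares is non-increasing across
iterations (tested), and on well-separated data the converged partition
matches scikit-learn's K-means (cross-checked in the test suite;
scikit-learn is deliberately not the implementation because the
initialization and empty-cluster rules here are part of the contract).
`n_init` defaults to 1, mirroring a single clustering run of the original
analysis; raise it for stability studies.

Trend labelling replaces the original visual scoring of cluster shapes
with a reproducible rule: a centroid is *increasing* iff it is
non-decreasing stage-to-stage and (last+ε)/(first+ε) ≥ f, *decreasing*
symmetrically, else *steady*; defaults f = 2, ε = 1, no tolerated
monotonicity violations. The rule is always applied to centroids on the
RPKM scale. Clustering itself defaults to raw RPKM (as in the original
analysis) with a `log_transform` flag for log2(RPKM+1); when the flag is
used, centroids are back-transformed (2^c − 1) before trend classification
— applying a fold rule to log-space values would be a unit error.
Raw-scale Euclidean K-means is dominated by high-RPKM genes and mixes
low-abundance profiles of different shapes into shared clusters; the
parameter-recovery analysis therefore runs with the log flag, and this is
the recommended setting when trend composition is the question.

## Novel transcribed regions

Seqfrags are connected components of the strict-overlap graph of
same-strand reads (abutting half-open intervals do not overlap; ≥ 2 reads
required; singletons discarded). Candidates are seqfrags with read count
strictly greater than 5 lying at least 20 kb from every gene across all
supplied annotation sets. The intronic/intergenic gap rule uses the
boundary x\* where the two assumed normal length densities are equal:
equating log-densities gives a quadratic whose root between the two means
is x\*; the solver verifies the density-equality residual to < 1e−9, and
the equal-variance degenerate case reduces to the midpoint of the means.
With the genome-wide estimates (intron 2.8/5.6 kb, intergenic 97/164 kb)
x\* = 17.604 kb. Gaps strictly below x\* merge consecutive candidates
(transitively) into one transcribed region; a gap at or above the boundary
— including exactly at it — splits. The order of operations is fixed as
seqfrags → support+distance filter → grouping. x\* is recomputed from the
model by default; `boundary_kb` overrides it. Across stages, regions
overlapping ≥ 1 bp on the same strand are identified as one entity
(transitive closure), and the entity × stage presence matrix feeds the same
Venn partition used for genes.

## GO enrichment

Direct annotations are propagated to all is_a ancestors (memoized closure;
propagation is idempotent and matched against breadth-first enumeration in
tests). Over-representation of a term annotating K of N population genes
and k of n study genes is the exact hypergeometric tail P(X ≥ k)
(scipy's survival function; validated against direct combinatorial
enumeration for N ≤ 30). Terms with K ≥ 1 are tested; correction is
Bonferroni by default — the behaviour of the classic term-finder tools —
with Benjamini-Hochberg available; significance is adjusted p < 0.01. The
population defaults to the full gene-model universe. The heatmap matrix
carries −log₁₀ adjusted p for terms significant somewhere and NaN where a
term is not significant in a stage (the "absent category" sentinel).

## ddCt relative quantification

dCt is target Ct minus the mean Ct of the control assays within the same
stage and replicate. The protocol description this reimplements states the
subtraction in the opposite direction, which is inconsistent with
RQ = 2^(−ddCt) producing fold change > 1 for up-regulation; the
conventional orientation is the default and the literal one is available
via `orientation="control_minus_target"` rather than being silently
corrected. ddCt subtracts the same replicate's reference-stage dCt
(pairing within replicate), RQ = 2^(−ddCt) is computed per replicate and
aggregated as mean ± SE, and fold change is anchored to exactly 1 at the
reference stage. A global plate shift leaves all RQ unchanged, and
noiseless RQ is multiplicative across reference choices (both tested).

## Synthetic data: what it emulates, and what it does not

The generator lays genes left-to-right per chromosome. Gaps between
successive genes are drawn from a normal with mean 97 kb, sd 164 kb
truncated below at 1 kb; intron lengths from a normal with mean 2.8 kb,
sd 5.6 kb truncated below at 50 bp — the same densities the decision rule
assumes, truncated because a normal with these parameters has substantial
negative mass. Truncation shifts the moments (the truncated intron mean is
≈ 5.7 kb rather than 2.8 kb); sampled lengths are tested against the
closed-form truncated-normal moments, not the untruncated ones. Defaults:
8 chromosomes × 24 Mb, 600 genes, 4–8 exons of 100–300 bp. The chromosome
length leaves several standard deviations of headroom above the expected
layout length, so generation does not overflow for any seed; a genuinely
too-small chromosome fails with an error naming it.

Per gene and stage, read counts are negative binomial (dispersion 10 by
default; `dispersion=None` is the Poisson limit used in distribution
tests) around truth means shaped by trend: increasing genes follow
base × (1, 3, 9, 27) across the four stages, decreasing genes the reverse,
steady genes a constant. Regulated genes (15% increasing, 15% decreasing)
draw their base from lognormal(median 50, σ = 0.6) and steady genes from
lognormal(median 50, σ = 1.2) — regulated profiles spanning roughly 1.5
orders of magnitude, emulating the archetypal cluster shapes of the
original analysis where regulated clusters rise or fall between modest and
>1000 RPKM levels. These effect sizes were calibrated once, via a
surrogate simulation across 40 seeds, so that ≥ 90% of regulated genes land
in a matching-trend cluster under the default clustering configuration
(with the log transform); at this scale the observed recovery is 96–100%.
Reads are 50 bp (matching the emulated chemistry), placed uniformly over
the exon model on the gene strand; configurable fractions are emitted
multi-hit (10%) or with score < 24 (5%) to exercise filtering, thinning
observed counts uniformly without biasing trends.

Planted intergenic transcription: 8 regions of 1 kb centred in intergenic
gaps wide enough to guarantee > 20 kb clearance from every gene span
(asserted at build time). Their reads are clean (unique, score ≥ 24) and
tiled at 25 bp steps so they always chain into a single seqfrag with
exactly the stated count. The default set covers the interesting
boundaries: counts 8/12/20/25 in all stages, one region with exactly 6
reads (the support filter is strict, "more than 5"), one with 3 (must
never be called), and two stage-exclusive regions to exercise the
cross-stage Venn. Background reads (500 per stage) land uniformly on the
genome; at this density they essentially never form a ≥ 2-read seqfrag, so
they exercise singleton discarding and stray exon overlap without
perturbing calls.

Ct tables are constructed by inverting the ddCt math: controls sit at fixed
base Cts (16 and 18), targets at base − log2(RQ) with RQ normalized to the
reference stage, plus optional Gaussian noise. At noise 0 the analysis
recovers the planted fold changes exactly (to floating-point round-trip of
log2/2^x, i.e. bit-exact for dyadic truths).

What passing these tests does **not** show about real data: the generator
has no sequence content, no mapping errors correlated with genomic
features, no isoforms or overlapping genes, no junction-spanning reads, no
rRNA contamination structure, and NB dispersion is global rather than
mean-dependent. Recovery results quantify the pipeline's correctness under
its own model assumptions, not RNA-seq accuracy in general.

## Problem sizes and numerical choices

The default synthetic run (600 genes, ~0.5–0.7 M reads over four stages)
executes the full pipeline in ~10 s; oracle-equivalence suites use 100
randomized instances of ≤ 1000 reads × ≤ 50 genes per operation. Ranking
tie-break is lexicographic; the Venn pattern order follows the stage order
given; percentages round half-up; the boundary solver rejects models
without a root between the means (impossible for valid mu_intron <
mu_intergenic, asserted). Degenerate inputs fail loudly with located
errors (malformed annotation lines report line numbers, missing controls
report stage and replicate, chromosome overflow names the chromosome).
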