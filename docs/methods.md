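# Methods

`kaikobuild` reconstructs, at desk scale, the analysis chain used to build a
gene catalogue for a lepidopteran genome from full-length cDNA (FL-cDNA)
evidence: 5′-EST clustering, splice-aware transcript-to-genome mapping,
evidence-class gene sets, EST-count expression profiling, and chromosomal
cluster statistics. Because the original raw libraries are not reproducible
at this scale, every analysis is exercised against a synthetic genome whose
generator is itself a first-class, tested component with a ground-truth
table.

## Synthetic data model

`simulate_genome` places `n_genes` multi-exon genes on `n_chromosomes`
equal-length chromosomes (the first, `chrZ`, is the Z-like sex chromosome).
Structural parameters follow the statistics typical of a
transposon-inflated lepidopteran genome:

| parameter | default | meaning |
|---|---|---|
| exon count | 1 + Poisson(3.8) | mean ≈ 4.8 exons per transcript |
| exon length | lognormal, median 179 bp / mean 353 bp, clip [27, 8000] | |
| intron length | lognormal, median 730 bp / mean 1904 bp, clip [34, 20000] | |
| GC content | 0.38 | genome background |
| te_fraction | 0.35 | share of intronic+intergenic space overwritten by repeats |
| tissue_specific_fraction | 0.35 | genes planted with a single-tissue label |
| testis_z_enrichment | 1.6 | target testis-gene density ratio on chrZ |
| est_error_rate | 0.01 | per-base substitution rate in ESTs |
| chimera_rate | 0.02 | FL-cDNA clones built as two-gene fusions |
| polya tail | uniform 10–30 nt | appended to clones |

Clipping a lognormal to finite bounds biases its realized mean low, so the
log-scale is shifted (bisection on the closed-form clipped mean) until the
*clipped* expectation equals the configured mean; with the 20-kb intron cap
this keeps the realized intron mean within sampling error of 1904 bp while
bounding gene spans so miniature chromosomes remain placeable. Every intron
is written with canonical GT..AG (strand-aware) dinucleotides.
Transposon-like repeats are a library of four 250–450 bp motifs inserted as
2%-mutated copies only into non-exonic space. Planted tissue-specific
clusters (`cluster_plant_spec`) use compact gene structures (introns ≤ 2 kb)
so that, e.g., 12 ovary-specific genes fit in 100 kb, mirroring
chorion-like loci; a configurable prefix of each cluster forms a
duplication family whose exons are ~3% diverged copies of a founder.
Placement order is shuffled so that sequential space-filling cannot
correlate with tissue labels — without this, null simulations of the
adjacency test show badly inflated type-I error. The `testis_z_enrichment`
knob is defined directly as the measured statistic (density on Z over
genome-average density); the chromosome-sampling weight is derived from it.

Libraries: each gene draws a Poisson number of 5′ ESTs (mean 12 if
tissue-specific, 6 if broad); ESTs are truncated at the 5′ end
(exponential, scale 20 bp), read to ~N(500, 60) bp, and error-mutated.
A tissue-specific gene's ESTs come from its own tissue's libraries except
for a 0.2% leakage; `library → (tissue, n_ests)` manifest entries act as
within-tissue sampling weights and the realized counts are what the
manifest TSV reports. 90% of genes get one full-length clone (error rate
5e-4, poly-A tail); `chimera_rate` of clones are replaced by 5′+3′ fusions
of two genes on different chromosomes, with both contributions forced to be
≥30% of the fused clone so that chimerism is detectable by construction.
A few genes are simulated off-assembly (W-chromosome-like): their
transcripts exist but have no genomic home, populating gene set C.

What the generator does **not** emulate: sequencing-quality trajectories
(QV trimming is upstream of this pipeline), alternative splicing isoforms,
overlapping or nested genes, paralog families outside planted clusters,
assembly gaps, and genome-wide repeat families shared between exons.
Passing recovery tests therefore demonstrates algorithmic correctness under
these idealized conditions, not performance on real trace data.

## EST clustering

Two 5′ ESTs are "identical clones" when some gapped local alignment
(Smith–Waterman, +1/−1/−2) contains a window of ≥100 aligned columns with
>95% matches; `N` matches nothing. Contigs are single-linkage closures of
this relation — assembly semantics, not centroid clustering. Candidate
pairs are prescreened by shared exact 16-mers (sampled densely; a strided
sample would miss pairs whose relative offset is not a multiple of the
stride). Relative 5′ offsets propagate through the linkage graph by BFS;
the representative (full-length candidate) is the member with the most
upstream 5′ end, ties broken by smallest clone id.

## Spliced alignment

Mapping is two-stage. A sorted-array exact k-mer index (k = 14) yields
per-chromosome, per-strand seed chains (split at gaps > `max_intron`
= 120 kb); each chain becomes a window. Padding is adaptive: a flank is
extended by `max_intron` only when the unseeded transcript end — after
discounting terminal homopolymer runs such as poly-A tails — is ≥30 bp and
could hold a missed exon; otherwise a 60-bp margin suffices. Windows whose
seed count is far below the best chain (<5%, or <3 seeds when the best has
≥12) are discarded as chance k-mer scatter. A per-window cell budget
(2.5×10⁸) bounds memory/time; oversized windows are clamped to the densest
seed core.

The aligner is a four-state local DP (match/mismatch, genome gap, query
gap, intron) in the est2genome tradition, jitted with numba. Scores:
match +2, mismatch −3, gap open −6, extend −2, intron −40 with a +20
GT..AG bonus split between donor and acceptor (non-canonical introns are
allowed, just cheaper not to use). The intron penalty must be high enough
that chaining chance ~75%-identity patches across a 100-kb window never
pays — with a net cost of ~5 such "spaghetti" paths let unrelated sequence
reach high coverage, masking chimeras. Intron entry jumps `min_intron`
(30) columns at once, so the minimum intron length is enforced exactly in
the recurrence. Minus-strand placements align the transcript against the
reverse-complemented window so splice motifs read GT..AG; emitted blocks
are always forward-genome, 0-based half-open (GFF3 output converts to
1-based inclusive).

A transcript maps when its best placement reaches 95% identity over aligned
columns and 50% coverage (aligned transcript length over total length);
otherwise it is `unmapped_low_homology` / `unmapped_low_coverage`.
Chimerism: a clone is clean when one placement (single chromosome, strand,
and ≤100-kb span) covers ≥90% of it — the near-complete-placement reading
of "perfect alignment within 100 kb". It is chimeric when no such placement
exists but a second, incompatible high-identity segment covers ≥20% of the
read with <20% transcript-interval overlap against the best placement.
The literal rule "placeable iff jointly covering ≥ min_coverage = 0.5"
cannot recall balanced fusions, since either half alone can exceed 0.5.

## Gene sets

Mapped full-length clones, mRNAs and predicted models merge into set-A loci
by transitive ≥1-bp exon overlap on the same strand (exon, not span,
overlap — nested genes stay separate). Mapped ESTs attach to an overlapping
A locus, or group among themselves into set B (`e`-prefixed ids). Unmapped
transcripts cluster by the EST identity rule into coordinate-free set C.
Chimeric clones are excluded from locus building but retained in the
accounting, so every transcript lands in exactly one of {A, B, C,
chimeric}. Isoform counts are distinct exon-chain signatures (the ordered
intron-junction list) among a locus's full-length members.

ORFs are the longest forward-strand ATG-to-stop frame with more than 30
codons (≥31 aa excluding the stop; clones are oriented, so reverse frames
are not searched). Poly-A: the final 15 nt must contain a ≥10-A run with at
most one non-A interruption.

## Expression and clusters

Per-locus profiles count assigned ESTs pooled by tissue via the library
manifest. A locus is tissue-specific when its total exceeds 3 copies
(i.e. ≥4) and the argmax tissue holds strictly more than 90% — both
inequalities strict, which reconciles "more than 90%" with "fewer than 10%
from other tissues". Calls are deliberately not scale-invariant below the
copy floor.

Clusters chain same-tissue specific loci whose interval gap (end to next
start) is ≤100 kb on one chromosome; chains of ≥2 are clusters. The
adjacency independence test builds a 2×2 table over genome-ordered
neighbouring locus pairs — by default rows and columns both ask
"tissue-specific at all?", a symmetric construction whose two rows are
directly comparable; the stricter same-tissue column variant is available
but mixes incommensurable baselines and so has little power. The Fisher
exact two-sided p sums hypergeometric mass of tables no more probable than
the observed one, computed in exact integer/rational arithmetic (ties are
exact; no reporting floor such as 2.2e-16 is imposed). Duplication within a
cluster is pairwise sequence linkage (local alignment identity ≥0.7 over
≥50% of the shorter sequence, on ORFs when available). Density enrichment
is per-bp density on the focal chromosome over the genome-wide per-bp
density.

## Comparative summaries

Ortholog-group tables are categorized from their species sets
(species-specific / lineage-specific / universal 1:1 / universal N:N /
other) with the insect and lepidopteran sets supplied by configuration, so
synthetic three-species tables work unchanged. Paralog expansion is
genes-per-group; Pearson correlations use the t-distributed two-sided p
with n−2 df.

## Problem sizes and numerical choices

Default study conditions: 4 × 1 Mb chromosomes, 200 genes, ~1700 ESTs,
~190 full-length clones; recovery-at-scale checks use annotation-only
simulations (500–600 genes on 6 × 2.2 Mb) where sequence synthesis is not
needed; the adjacency null suite runs 200 annotation replicates at 120
genes. Structure recovery counts a mapped clone as exact when every
internal splice junction matches the planted annotation and the outer ends
overlap their terminal exons (local alignment may soft-clip a truncated 5′
end or absorb poly-A into the 3′ exon). Ties between equally-scoring loci
resolve toward the forward strand and lexicographically first position;
equal EST anchor offsets resolve to the smallest clone id.

## Known limitations

The DP is exact only within seeded windows: a transcript whose locus
yields no seed chain (e.g. >7% divergence spread uniformly) is unmapped
rather than rescued by exhaustive search. The splice model scores
introns independently of length apart from the entry cost, so extreme
introns (>120 kb) are invisible by construction. Chimera screening
assumes fusion partners are distant (>100 kb or different chromosomes);
tandem local fusions are indistinguishable from long loci. The expression
model has no library-depth normalization — by design, since raw identical-
EST counts are the object of study.
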