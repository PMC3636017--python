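# Methods

`interphyte` reconstructs, at desk scale, the computational workflow used to
deconvolute a mixed-species RNA-seq library sampled where a parasitic plant
feeds on its host: the transcript population of the haustorial interface
contains both parasite and host mRNA, and every downstream comparison
depends on separating them informatically. The package implements the full
chain — read QC, identity-threshold calibration, host screening, staged
unigene classification, orthogroup-level comparison, RPKM expression, and
qPCR verification — against synthetic data with complete ground truth.

## The similarity engine

All screening decisions reduce to nucleotide alignments, produced by a
self-contained k-mer-seeded banded dynamic-programming aligner
(`similarity`). Scoring is match +1, mismatch −2, insertion −3, deletion
−3; percent identity is matches over alignment columns (gaps included),
the same convention the 95 % screening thresholds assume. Three modes are
supported: global (pairwise identity), glocal (query end-to-end, free
subject end gaps; used for best-hit database searches), and local
(Smith–Waterman; used for read mapping).

The DP optimises the triple (score, matches, −columns) lexicographically by
packing it into one 64-bit integer per cell. This removes tie ambiguity:
repeated runs are bit-identical, and global-mode identity is symmetric in
its arguments because insertion and deletion costs are equal. Seeding uses
exact k-mers (default k = 11) bucketed by diagonal; the top candidate
subjects (default 8) are aligned in a band of half-width 32 around the
seeded diagonal. When no seed diagonal is known the full matrix is used, so
pairwise calls are exact. Defaults suit screening at ≤ 20 % divergence;
at higher divergence seeds become sparse and hits legitimately disappear,
which is the behaviour the no-hit category relies on. Significance is a raw
score threshold (default 25, roughly a 25 bp exact match) standing in for
an e-value cutoff; exact Karlin–Altschul statistics are out of scope.

Read mapping accepts a read only if at least a fraction 0.5 of it aligns
and identity on the aligned part is at least 0.8 (both configurable);
ambiguous reads go to their single best hit — ties break by score, then
identity, then alignment length, then lexicographically smallest subject
id — and are never fractionally split.

## Read QC and host screening

Trimming strips the maximal prefix and suffix of bases below Q20 and keeps
a read only if at least half its original length survives; interior
low-quality bases are untouched. Pairs are rebuilt after trimming; single
survivors become orphans, and the accounting identity
`2·pairs + orphans = survivors` is asserted throughout. Host screening maps
surviving reads against the host reference with the calibrated identity
threshold as the mapping similarity; a pair with exactly one host-assigned
mate is discarded whole (conservative against chimeric carry-through) and
counted separately.

## Threshold calibration

The host-exclusion threshold τ is the 1-point bin boundary minimising
(host-distribution mass below τ) + (control-distribution mass at/above τ),
i.e. the valley between the genuine-host high-identity mode and the
incidental cross-species mode. The host mode is anchored by querying the
host reference against itself (genuine contaminants are near-identical to
the host reference); the incidental mode comes from the assembly queried
against a non-parasitic control relative. Ties on the valley floor resolve
to the plateau midpoint, centring τ between the modes; the result is
invariant to uniform scaling of either histogram. If the minimised combined
error exceeds an overlap ceiling (default 0.10) the distributions are
declared non-separable and τ is reported with a warning flag. The
conventional fixed value 95 remains available as a config override.
Queries with no hit contribute to neither error mass.

## Classification cascade

Stages run host screen → parasite screen → labelled-annotation screen →
no-hit, in that order, so a unigene above both identity thresholds is
called host — conservative against contamination. The annotation screen
assigns `other_plant` or `non_plant` from the taxon label of the best
significant hit; plant-labelled and no-hit unigenes are pooled with
parasite-screen survivors as the putative parasite set used downstream.
An `ambiguous_band` report lists the dual-threshold unigenes whose category
would flip if the first two stages swapped. Assembly post-processing
removes exact duplicates and contained substrings on either strand
(longest representative kept) and drops sequences whose longest stop-free
stretch across six frames is under 0.3 of their length — a permissive
ORF-fraction heuristic standing in for a frame-shift-aware coding filter.
Both screens additionally require the best hit to cover at least
`min_alignment_fraction` (default 0.5) of the unigene. N50 is the shortest
length in the smallest descending-length prefix reaching half the total.

## Comparative layer

Unigenes inherit the orthogroup of their best significant hit against an
orthogroup-labelled reference. Three orthogroup sets (interface on host A,
interface on host B, above-ground reference) partition into seven disjoint
Venn regions; interface-only fractions are exact rationals rounded to the
nearest percent. GO Slim category-by-region tables are tested with a plain
Pearson chi-square (no continuity correction; zero-margin rows/columns
dropped with a note; expected counts < 5 listed as caveats). Per-cell
Pearson residuals (O−E)/√E are flagged at |r| > 4; Haberman-adjusted
residuals are available behind a flag. No multiple-testing correction is
applied across tests, matching common practice for this analysis.
"No category" is an explicit row because enrichment of unannotated genes
in interface-unique regions is a biologically meaningful outcome.

## Expression and qPCR

RPKM = 10⁹·C/(N·L) with N the count of reads mapped to the reference in
that library. Cross-library correlation uses Pearson's r on log2(RPKM+1)
by default (raw scale optional; the transform is recorded in the output).
Top-N ranking per Venn region is deterministic with ties broken by id.

qPCR analysis averages technical replicate Ct values per sample and gene;
ΔCt = Ct(target) − Ct(reference), ΔΔCt = ΔCt(treatment) − mean ΔCt(control),
fold = 2^−ΔΔCt, summarised across biological replicates by the geometric
mean. Group comparison is Welch's unequal-variance t-test with
Satterthwaite degrees of freedom, one-tailed, applied on the ΔCt scale —
the approximately normal scale behind 2^−ΔΔCt reporting.

## The synthetic-data generator

The generator emulates the study design at the data level. A pool of
ancestral parasite transcripts (default 150, lengths 250–1200 bp) evolves
by independent per-site substitution into: host homologs for two host
species at divergence 0.20 (a distant monocot/eudicot-scale gap that
places incidental identity near 80 %), a parasite reference library at
0.02 (other libraries of the same species, identity ≈ 98 %), a
non-parasitic control relative at 0.12, and an annotation database at
0.05 carrying kingdom, orthogroup, and GO Slim labels. Substitution-only
evolution keeps the expected pairwise identity analytic (≈ 1−d); an
optional indel rate exists but defaults to 0. The assembly pool is salted
with near-exact host copies (planted contaminants), labelled non-plant
sequences, and unannotatable randoms, giving every unigene a known true
category.

The interface read library draws 83 × 83 bp pairs (insert 250 ± 30) from
parasite transcripts weighted by gamma-Poisson expression
(mean 80, dispersion 0.25), contaminated at fraction f = 0.10 by host-A
reads. Base errors are uniform at 0.004 with positional Phred profiles
(Q38 sagging to Q30); 15 % of reads get a low-quality tail of up to 3/4 of
the read so the survival rule is actually exercised. Orthogroup Venn
membership follows region proportions shaped like the two-host comparison
(53.6 % shared by all three transcriptomes, ~10 % interface-shared, host-A
unique > host-B unique), over a default universe of 3000 orthogroups —
large enough that a planted log-odds +1 enrichment of the no-category row
in an interface-unique region is detectable at the residual > 4 bound with
high power. qPCR tables use 3 biological × 3 technical replicates, Ct noise
sd 0.2, a per-sample loading shift common to both genes (cancelling in
ΔCt), and configurable true folds (defaults 120 and 0.5, the scale of the
verified expansin effects).

What the generator does not model — chimeric mis-assemblies, amplification
length bias, machine-specific error profiles, paralogy within gene
families, real codon structure (transcripts are uniform random, so the
ORF filter drops a realistic-looking fraction of genuine sequences) —
bounds what passing tests show: they validate the decision logic and its
calibration under clean separability, not performance on the messier real
libraries.

## Problem sizes and numerics

Default test and acceptance runs use 40–110 parasite transcripts, 20–30
host transcripts per species, 300–1500 read pairs, 3000-orthogroup GO Slim
tables, and 20–100 seeded replicates per recovery check — sizes chosen so
the full suite exercises every stage in about a minute while keeping
binomial error bars tight enough for 3-standard-error recovery tests. All
randomness flows from a single seed through named generator streams, so
identical configs produce byte-identical FASTA/FASTQ/TSV outputs. Degenerate
inputs (empty sets, zero margins, zero variance, missing labels) raise
errors naming the offending record rather than propagating NaNs.
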