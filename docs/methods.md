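# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic cohort generator does and does
not emulate, and the design choices made where the underlying methods
description left the design open.

## Coordinates and formats

All external interfaces use 1-based inclusive genomic coordinates
(matching SAM/GTF and how breakpoints are reported in clinical genomics);
0-based half-open arithmetic is internal only, and the BED-style segment
output converts at the boundary. Gene models store exons in transcription
order; minus-strand genes therefore store descending genomic intervals.
Per-exon CDS phase follows the GTF frame convention: the number of bases
at the exon's 5' edge completing a codon begun upstream. The SAM-lite
reader consumes only QNAME, FLAG, RNAME, POS and the CIGAR-derived
reference length, so SAM text exported from real BAMs parses; a minimal
5-column dialect (QNAME FLAG RNAME POS LENGTH) is accepted for fixtures.

## Fusion discovery

Read pairs are classified against two filter criteria: (1) the two mates
overlap two distinct genes (discordant gene pair); (2) a mate lies wholly
within an intron of a gene that already has criterion-1 support. A
candidate is emitted per gene pair with at least `min_support` discordant
pairs (default 2 — a single pair invites library artifacts; the method
description states no threshold). Gene pairs never linked by a discordant
pair are never called, whatever the coverage shows. A mate inside two
overlapping genes counts for both, with the ambiguity logged.

Breakpoints come from per-nucleotide coverage: the position maximizing
the two-sided mean-coverage difference (a single mean-shift changepoint),
restricted to candidate boundaries in introns and a 10 bp flank into the
adjacent exons, with ties broken to the leftmost position and a
no-breakpoint result (distinct from an error) when the best shift is
below `min_delta` (default 5× the track's median depth, floored at 1).
Because a discordant mate ends, on average, half an insert short of the
junction, raw discordant coverage ramps toward the breakpoint rather than
stepping at it; the changepoint therefore localizes the breakpoint
region, and the reported coordinate is refined to the extreme aligned
base of the supporting mates near the changepoint — the identified read
pairs themselves reveal the fusion point. With noise-free (tiled)
simulation the refined coordinate equals the injected breakpoint exactly.

The donor (5') partner is chosen as the gene whose supporting mates
cluster nearest its transcript start: the donor contributes its 5'
portion, so its evidence sits at low transcript offsets while acceptor
evidence sits past its first retained exon. Frame status is in-frame iff
(donor CDS length up to the breakpoint) mod 3 equals the acceptor exon's
phase; noncoding if either partner lacks a CDS. Junction sequences are
reconstructed as k donor + k acceptor transcript-orientation bases
(minus-strand sides reverse-complemented), and junction-spanning read
sequences that match the reconstruction end-to-end are counted as
additional support — reported, but never required for a call, since the
filter criteria are stated over read pairs.

The candidate gene pair's reported quantities include both the gene
distance and the breakpoint distance; the two need not agree and the
package takes no side on which better describes partner separation.

## Copy number

Windows hold a fixed count of reference reads (default 1000), in the
style of read-count aCGH emulation from exome data; a window boundary
never splits reads tied on the same start coordinate, so non-terminal
windows hold at least, and absent ties exactly, the target count.
Chromosomes with fewer reads than one window collapse to a single
whole-chromosome window with a warning.

Ratios are log2((T + c)/(R + c)) with floor offset c = 0.5, then
median-centered. Median-centering makes profiles invariant to library
size but assumes a majority-neutral genome; a genome-wide aneuploid
sample would be mis-centered, which is a documented limitation. When no
matched normal exists, the pseudo-normal reference is the per-window
median of library-size-normalized unmatched normals, rescaled to the
mean library size; given a single normal it reduces to that normal
exactly.

Segmentation is a simplified circular-binary-segmentation variant: the
boundary maximizing the two-sample t statistic is proposed recursively
and accepted when its permutation p-value (100 permutations, fixed seed
13) falls below `alpha` (default 0.01); adjacent segments with mean
difference below `min_gap` (default 0.1) are merged; both halves of any
accepted split keep at least `min_windows` (default 3) windows. Segment
means equal the mean of member windows by construction. Calls use
conventional thresholds: gain at log2 ≥ +0.3, loss at ≤ −0.3 (none are
stated by the method description). A gene takes the call of its
containing segment; boundary-spanning genes take the overlap-weighted
mean of segment means, re-thresholded. Cohort summaries count gains and
losses per locus across samples.

## Mutation spectra

Substitutions collapse onto the pyrimidine strand (G>A → C>T etc.) into
six classes; each SNV's trinucleotide context is read from the reference,
complemented and swapped for purine references so the context is always
reported 5'→3' on the pyrimidine strand. Variants at chromosome ends or
with ambiguous (non-ACGT) bases in the trinucleotide are excluded with a
logged count. Burden is (SNVs + indels)/capture Mb — `capture_mb` is a
required input because target sizes are design-specific — and both the
combined and SNV-only interpretations of a quoted burden can be read off
the summary, which reports the two counts separately. Samples above 10
mut/Mb are flagged hypermutated (the conventional cutoff; none is stated).
Indels count toward burden but carry no context.

NpCpG C>T prominence is the fraction of context-resolved C>T events whose
3' base is G, flagged above 0.5; with fewer than `min_snvs` SNVs
(default 10) the result is indeterminate rather than an error. At an
exome-scale burden of ~2 mut/Mb a sample has only tens of SNVs, so this
flag is noisy there; the flag-concordance simulation study therefore runs
at an elevated per-sample burden (~1000 SNVs) where the score's sampling
error is small relative to the 0.25-vs-0.55 separation between the
background and enriched expectations. Recurrence reports genes mutated in
at least `min_cases` distinct samples (default 3) and, separately,
identical protein changes recurring across samples.

## Expression

RPKM = 10^9·C/(N·L) with gene length L the union of exon intervals (not
transcript-specific) and N the library size (column sums by default).
Group comparisons use the two-sided Wilcoxon rank-sum test on
log2(x + 1) values: rank-based, hence invariant under monotone
transforms and defensible at 4–5 samples per group; the null is
enumerated exactly for tie-free samples of at most 10 per group and
approximated with tie-corrected normal otherwise, and fully tied data
return p = 1 under the midrank convention. The fusion-sample check
reports group means and fold change always, and attaches the rank-sum
result only when both partitions have at least 2 samples; a 4-versus-1
design yields a descriptive-only report, deliberately.

## Genotype association

Pearson's χ² is the plain O/E sum over the group × genotype grid with
expectations from the margins, df = (r−1)(c−1), upper-tail p, and no
continuity correction (Yates applies to 2×2 only). Zero-margin rows or
columns are dropped with a warning; a table left degenerate raises. With
8 cases against 75 controls the smallest expected count is ≈1.06, below
the conventional validity threshold of 5, so results carry a
small-expected-count warning and an optional Monte-Carlo p (tables drawn
with the observed margins by sequential multivariate hypergeometric
sampling, fixed seed, +1-corrected); the headline number remains the
asymptotic p. Two-significant-figure p-values are rendered both rounded
and truncated, since a printed value can arise from either convention.
Carrier frequency (individuals with ≥1 risk allele) and allele frequency
(risk chromosomes over 2n) are computed and labelled separately; they
differ substantially whenever heterozygotes are common, and the package
never conflates them.

## Synthetic cohort generator

The default universe is 5 chromosomes × 2 Mb of uniform-random sequence —
a 1:10-scale stand-in chosen so whole-cohort simulations run in seconds;
moving to real-genome scale is a configuration change. The default gene
pair sits on chr1 with transcription starts 77.2 kb apart (the fusion
partners' 772 kb separation at scale), the donor breakpoint at the end of
the donor's first exon and the acceptor breakpoint at the start of the
acceptor's second exon, with CDS lengths arranged so the junction is
in-frame. Fusion fragments are paired 101 bp reads (insert 250 ± 30,
mimicking 2 × 101 bp paired-end sequencing) in three classes: concordant
background pairs, discordant junction-flanking pairs, and
junction-spanning reads emitted as raw sequences (a contiguous-alignment
record cannot represent a split read). Tiled placement gives noise-free
coverage whose extreme reads touch the breakpoints exactly.

Depth profiles are negative-binomial (variance m + d·m², dispersion
d = 0.05 by default — Poisson undershoots exome count variance) around
arm-state means: gain 1.5×, loss 0.5×, neutral 1× (recovery studies that
specify |log2| = 1 events pass gain_factor 2.0 explicitly). The default
arm pattern mirrors the cohort's recurrent events: loss of the chr1 p arm
and of chr3/chr4 entirely, gain of chr2 and of the chr5 q arm — analogues
of loss 1p/10/13 and gain 7/17q. Somatic variants arrive at a Poisson
rate of 2.1 mutations/Mb (the cohort's reported non-hypermutated mean;
per-sample counts were not published, so the mean anchors everything)
with 5% indels (the substitution/indel split is unstated; 5% is a typical
exome fraction), class weights dominated by C>T (0.40), T>C (0.25) and
C>A (0.15), and — in enriched samples — each C>T placed at an NpCpG site
with probability 0.4. The genotype cohort is multinomial per group, and
the printed study tables (genotypes and the ten-patient clinical table)
are available verbatim as inputs.

What the generator does not emulate: sequencing errors and base
qualities, alignment artifacts, GC and mappability bias, purity and
subclonality, germline contamination, and real genome composition
(repeats, CpG islands, codon structure). Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated
noise models, not performance on real tumor data.

## Numerical choices

Changepoint ties break to the leftmost position, with a 1e-9 relative
tolerance so exact ties are not decided by floating-point rounding.
Permutation p-values use the (k+1)/(n+1) estimator. The t statistic for
a proposed split treats a zero-variance difference as infinite (any
nonzero mean shift on constant halves is accepted). Empty coverage
regions yield zero tracks, not errors; an all-zero tumor profile is an
error. Sub-seeds for replicate studies are derived as small integer
offsets from the user seed and stay below 2^31.

## Problem sizes used in the studies

Recovery studies run at sizes where the targeted property is
identifiable and the whole suite stays fast: fusion recovery uses 100
replicates of ~12 fusion fragments plus 30 background pairs per gene;
copy-number sign recovery uses 100 replicates of 1000 windows (200 per
chromosome); the NpCpG flag study uses 500 replicates at the power-sized
burden discussed above; the Monte-Carlo χ² uses 100,000 tables. These
are the package's own choices of study size, recorded here so results
are reproducible.

## Known limitations

Interchromosomal fusions are representable in the data model but the
caller's orientation heuristic is tuned for same-chromosome pairs; no
split-read realignment or transcript assembly is attempted. Copy-number
estimation has no GC correction, purity/ploidy model or allele-specific
resolution. Signature analysis stops at the 96-channel matrix (no NMF
deconvolution) and recurrence tallies are descriptive, not significance
tests. The association module fits no covariates and performs no
Hardy-Weinberg or survival analysis.
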