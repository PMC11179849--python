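# Methods

This note documents the models and procedures implemented in `diploscan`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data do and do not demonstrate.

## Phase-to-phase alignment and variant extraction

The unit of analysis is a pair of phase sequences (P0, P1) for one
chromosome of a phased diploid assembly.  Variants are expressed on P0
coordinates: an insertion is sequence present in P1, a deletion is P0
sequence absent from P1, and SNPs/inversions belong to both phases.

**Anchor aligner.**  Anchors are k-mers (default k = 21, 2-bit packed)
occurring exactly once in each sequence; shared unique k-mers are chained by
longest increasing subsequence on both coordinates (patience LIS, leftmost
tie-break, so output is deterministic).  When the forward orientation yields
too few anchors the reverse complement is tried and the block reported on
the minus strand.  Anchor lists above 1000 entries are subsampled 10-fold
before chaining; the lost resolution is recovered during gap closing.
Inter-anchor gaps are first trimmed by exact prefix/suffix matching; a
remaining gap is closed by a global affine-gap alignment
(match 2, mismatch −3, gap open −5, extend −1, via Biopython's
PairwiseAligner) when its longer side is ≤ 10 kb, and left as one
deletion-plus-insertion pair otherwise.  Affine penalties matter here: with
unit costs the optimal path is not unique and can split one biological indel
around a coincidentally matching base, which would break breakpoint-exact
recovery.  A gap whose two sides align in opposite orientation (≥ 2 shared
unique k-mers against the reverse complement and ≥ 90 % identity) is emitted
as a separate minus-strand block; variant extraction reports a minus-strand
block framed by plus-strand neighbours as one inversion whose size is its
reference span.

**Classification.**  Gap events are canonicalised before classification:
each pure insertion/deletion is left-aligned against P0 (the VCF
convention), and deletions that become adjacent after normalisation are
merged, so the reported event set does not depend on which optimal alignment
path was taken.  Events of 1–39 bp are INDELs, ≥ 40 bp are SVs — 40 bp is the
conventional (and admittedly arbitrary) lower bound for calling an event
structural.  An SV insertion whose
sequence matches the adjacent reference segment at ≥ 90 % identity is a
tandem duplication; one matching a non-adjacent interval (exact 31-mer seed,
then ≥ 90 % identity verification) is an interspersed duplication, except
when the matched interval is an annotated TE — TE insertions naturally
match distant copies of their family and are reported as plain insertions.

## TE zygosity, TSDs and LTR dating

**Reciprocal overlap.**  For each TE annotation the deletion with maximal
overlap (ties: leftmost) is examined: the TE is *heterozygous* when the
overlap strictly exceeds 50 % of the deletion length (a deliberate strict
inequality, slightly stricter than the ≥ semantics of `bedtools -F`) and
covers at least 80 % of the TE; *partial* when some
deletion overlaps but below the thresholds; *homozygous* when no deletion
overlaps and the TE lies entirely within alignment-covered reference;
*unresolved* otherwise.

**TSD detection.**  An insertion and its target-site duplication are
rotationally ambiguous: the same haplotype difference can be written with
the duplicated k-mer on either side of the breakpoint.  The detector first
rotates the insertion to its rightmost equivalent placement, then reports
the largest k ≤ max_len (default 20) for which the k-mer 5′ of the
breakpoint equals the terminal k-mer of the inserted sequence, exact match
only (freshly created TSDs are perfect duplications; allowing mismatches
would trade specificity for nothing at the ages of interest).  k < 2 is
reported as not found.  Note that a perfect tandem duplication is, by this
definition, its own "TSD" — TSD lengths are only biologically meaningful
for insertions matched to TEs.

**Insertion age.**  The two LTRs of an intact element are compared over
ungapped alignment columns (edlib global alignment if lengths differ);
with mismatch fraction p, the Jukes–Cantor distance is
d = −(3/4)·ln(1 − 4p/3), undefined (saturation error) at p ≥ 0.75, and the
age is t = d/(2μ).  The substitution model is deliberately the simplest one
consistent with an intra-element comparison; K2P is available behind a flag
and agrees closely at the divergences involved.  μ defaults to
1.3 × 10⁻⁸ substitutions·site⁻¹·year⁻¹, the rate commonly used for
long-terminal-repeat dating in Rosaceae and other plants; it is a
configurable scale factor, not an estimated quantity.  Group contrasts
(heterozygous vs homozygous ages, TE-near vs TE-free expression) use
two-sided Wilcoxon rank-sum tests, reported as unavailable for groups with
n < 3.

## Coding impact

One canonical transcript per gene is assumed (the generator emits one;
with multiple isoforms the most severe effect would be kept, a convention
documented but not exercised by the fixtures).  CDS SNPs are translated in
frame and compared codon-wise (synonymous / missense / stop gained / stop
lost); CDS indels are frameshift iff the affected coding length is not a
multiple of 3, with deletions counted by their coding overlap; variants
spanning a region boundary take the most severe touched region
(CDS > intron > upstream > downstream > intergenic, windows of 1 kb).
Genes wholly contained in a single SV deletion are presence/absence (PAV)
genes, impact HIGH.  Impact mapping: frameshift and stop changes HIGH,
missense and in-frame indels MODERATE, synonymous LOW, non-coding MODIFIER.

## Allele-specific expression

Informative SNPs are coding SNPs with no indel edge closer than 50 bp
(SNPs at exactly 50 bp are kept).  Reads matching the P0 or P1 base are
counted to the respective allele, third alleles discarded, and counts are
aggregated to gene level — per-SNP testing is the main alternative; gene
level is the choice here because replicate overdispersion is a gene-level
phenomenon.  The clustering read filter is likewise applied at gene level:
a gene passes when its total (P0+P1) count is ≥ 10 in every replicate of
every organ.

The ASE test is a beta-binomial test of the pooled P0 fraction against 0.5
per gene × organ.  The overdispersion ρ is estimated per organ by a method
of moments on within-gene, between-replicate variation (a chi-square
statistic around each gene's own pooled fraction, so true ASE signal does
not inflate ρ), floored at 0, where it reduces to the exact binomial test.
This stands in for the negative-binomial regression contrast often used
for ASE: it is self-contained, exact at low counts, and its error
behaviour is verified directly (complete-null false positives ≤ 1 %,
sensitivity ≥ 0.9 at allelic ratio 0.8 with 200× depth and 3 replicates).
FDR is Benjamini–Hochberg at 5 % within organ; "ASE" means significant in
at least one organ.  ASE percentages are truncated, not rounded, to one
decimal (so 579/6182 prints as 9.3); the SV-enrichment proportions are
conventionally rounded.
Profile clustering uses Ward linkage on per-organ mean P0 proportions with
a default cut at k = 4.  Expression for TE-association contrasts is
log₂(1 + CPM) of total gene counts — a monotone substitute for a
regularised log; the subsequent tests are rank-based, so the choice of
monotone transform is immaterial.

## Synthetic diploid generator

The generator *defines* the study conditions for all recovery and
statistical tests.  Phase-0 is the generated reference; every planted edit
goes into phase-1.  "P0-specific" heterozygous TE insertions are realised
as reference-embedded copies deleted from phase-1; "P1-specific" ones as
new phase-1 insertions.  This one-sided construction keeps every truth
coordinate on final P0 coordinates with no lift-over, which is what makes
breakpoint-exact recovery testable.

Defaults (per chromosome, uniform base composition): one multi-exon gene
per 50 kb (three exons, 480 coding bp, ATG…stop, both strands); one TE copy
per 20 kb drawn from a deterministic consensus library (Gypsy 4.0 kb /
Copia 2.5 kb LTR elements, CACTA, MuDR, MITE, LINE, Helitron) written with
a flanking target-site duplication (5 nt for LTR order, 0 otherwise —
the TIR TSD length is not specified by the source and defaults to 0,
configurable); SNPs at 1/350 bp, indels (geometric, 1–39 bp) at 1/921 bp
and SVs at 1/15 432 bp, Poisson counts so realised densities stay within
Poisson noise of the rates.  The SV rate is a *total*: heterozygous TE
events count toward it and the remainder is filled with random
insertions/deletions (93 %), tandem duplications (5 %), inversions (1.5 %)
and interspersed duplications (0.5 %), length log-uniform on 40 bp–10 kb —
mirroring the observed dominance of TE-sized insertions/deletions among
real SVs.  `het_te_fraction` f converts f·R/2 of the R reference copies
into phase-1 deletions and plants the same number of new phase-1
insertions.  LTR ages are drawn uniformly (heterozygous 0.1–5 My,
homozygous 2–12 My — group means near 2.6 and 6.5 My, the regime expected
when unfixed insertions are young and fixed ones old) and
realised by mutating each LTR independently with the per-branch JC
substitution probability, identically in both phases for homozygous copies.

Placement uses rejection sampling (≤ 1000 retries, then a placement error)
with a 20-bp separation between events, and truth records store the
left-aligned representation.  Three further rejections keep truth exact
rather than merely plausible: TE insertion sites are re-drawn if the
detected TSD would not equal the planted length (an accidental sequence
coincidence would otherwise extend the duplication); tandem-duplication
templates are protected from later edits (an edit inside the template makes
the copy's breakpoints ambiguous); inversion segments may not pair their
first base with the complement of their last (which would shift the
breakpoint).  These rules define what "planted with a 5-nt TSD" means —
the duplication is exactly 5 nt, not at least 5.

Allele counts are negative-binomial totals (mean 200, gamma shape 10) split
binomially by each gene's true P0 fraction: 0.5 for most genes, 0.8/0.2 for
a 10 % ASE fraction, and 1.0 for genes deleted from phase-1.

**What the synthetic data do not emulate:** read-level sequencing (mapping
bias, duplicates), realistic base composition and codon usage, nested or
fragmented TEs, segmental duplications beyond the planted classes, and
assembly errors.  Passing recovery tests therefore demonstrates
correctness of the algorithms under clean, collision-free conditions, not
calling performance on real assemblies.

## Problem sizes and numerics

The test suite exercises recovery on a seeded 5-Mb diploid (≈ 19 000
planted events) and the TSD/zygosity/dating analyses on a 2-Mb diploid with
100 LTR-RT loci; the acceptance script re-simulates the 2-Mb case.  These
sizes keep a full run in tens of seconds while leaving every per-event
check exact.  Age-recovery checks compare the *mean* estimate over 40
simulated pairs per age point (0.5–10 My, 1-kb LTRs) to the true age within
20 %: a single 300-bp LTR pair at 0.5 My carries only ~4 expected
substitutions, so per-copy estimates are Poisson-limited and only the mean
is a meaningful 20 %-level check.  All randomness flows from
`numpy.random.default_rng` seeded per run; stage order is fixed, ties are
broken deterministically, and reruns with one config and seed are
byte-identical (verified by manifest checksums).

## Known limitations

- The aligner assumes mostly collinear haplotypes; translocations are out
  of scope and large inversions are only detected when both flanks anchor.
- Interspersed-duplication detection requires an exact 31-mer seed; highly
  diverged dispersed copies are reported as plain insertions.
- The beta-binomial ASE test conditions on total counts and does not model
  gene-level expression differences between organs.
- Real GFF3 inputs with UTR-bearing exons classify UTR positions as genic
  ("intron" bucket), since the effect vocabulary has no UTR term.
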