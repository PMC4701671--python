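# Methods

## The assay and its coordinate model

A poly(A) tag (PAT) is a short cDNA spanning the mRNA–poly(A) junction,
primed with a barcoded, anchored oligo-dT primer. In read orientation a raw
tag is `barcode + T-tract + revcomp(mRNA 3' end)`: the T-tract is the
complement of the poly(A) tail, and the first templated base after the tract
is the complement of the *last* genome-templated base of the transcript.
All internal coordinates are 0-based half-open; GFF3 is read and written
1-based inclusive. A poly(A) site (PAS) is the 0-based coordinate of the
last templated base, reported on the mRNA strand (the opposite of the strand
the read maps to). Offset 0 in all window-based analytics is the site
itself; negative offsets are upstream in transcript sense.

## Tag processing

**Demultiplexing** assigns a read to the unique barcode within
`max_bc_mismatch` (default 0) of its prefix; ties are counted as unassigned
rather than raised. **Trimming** removes the maximal leading run of T,
absorbing an isolated non-T interruption only when it is flanked on both
sides by ≥ 3 T (interruptions are recorded — they are non-A tail bases seen
in mRNA sense); a 3' adapter occurrence (exact suffix overlap ≥ 8 nt) is
removed; reads are rejected when the tract is shorter than `min_t_tract`
(8 nt) or the remaining tag shorter than `min_tag_length` (20 nt).

**Mapping** uses a seed-and-verify full-length search over both strands with
≤ `max_mismatches` (default 1) substitutions, optionally discarding a 5'
prefix of up to `max_clip5` nt (default 20 — sized so tail remnants left by
an interrupted trim can be recovered as soft clips). Candidates are scored
`aligned_length − 4·mismatches`; ties between clip lengths take the smallest
clip, and a score tie between distinct loci is discarded as multimapped —
counts stay integral and conservative. This mapper targets the synthetic
genomes produced here (two 16-mer seeds bound the miss probability at one
substitution); real-genome alignments are ingested as SAM, where soft clips
supply the unaligned prefix and flags the strand.

**Reduction** takes the tag's 5'-most aligned base: the highest footprint
coordinate for '+' mRNA, the lowest for '−'. **Tail extraction** merges the
trimmed tract with any 5' clip whose T-fraction is ≥ 0.5; non-T bases in the
merged tail are counted as non-A, and one or more marks the tail
heteropolymeric.

## Site calling and clustering

PAS are aggregated per (contig, strand, position) with per-library counts.
Two filters, in the order the analysis runs: clustering is performed on the
*unfiltered* site set — single-linkage chaining that starts a new cluster
whenever the gap to the previous site exceeds `max_gap` (24 nt, inclusive at
24, measured between single-base coordinates; cluster spans may exceed
24 nt) — then clusters with fewer than `min_pac_tags` (10) total tags are
removed. Separately, the per-site table keeps sites with ≥ `min_pas_tags`
(10) tags for per-site analytics. A cluster's representative is its
highest-count member, ties resolved to the smallest position. Strands and
contigs are chained independently. The chaining rule is verified in the
test suite against a brute-force transitive closure of the within-24-nt
relation.

## Genic classification

Sites are tested against the union of each gene's transcript features with
precedence UTR3 > UTR3_EXT > CDS > UTR5 > INTRON; introns are derived from
exon gaps. UTR3_EXT is the fixed 25-nt region past the annotated 3'UTR
terminus in transcription direction. Genes on the site's strand are
preferred (SENSE); if none overlap, the overlapping antisense gene
classifies the site with orientation ANTISENSE; more than one gene in the
chosen orientation group — including an extension region against another
gene's feature — yields AMBIGUOUS; no overlap yields UNANNOTATED.
Classifying against the isoform union with a fixed precedence (rather than
one representative transcript) is a design choice of this package, as is
resolving multi-gene overlap to AMBIGUOUS regardless of class agreement:
a single-gene assignment is not defensible there.

Unannotated clusters are linked to the nearest same-strand extended-3'UTR
end at most `near_gene_max_dist` (100 bp) downstream — candidate 3'UTR
extensions. For organellar-style contigs, per-feature abundance adds each
site's counts to *every* overlapping feature (nested parent and child each
report the count; rows are per-feature, not additive), with a per-contig
intergenic row for sites outside all features.

## Signal analytics

Windows of 2W+1 nt (W = 80) are extracted in transcript sense ('−'-strand
windows reverse complemented); sites within W of a contig end are excluded
and counted. The downstream half is genomic sequence — the untemplated tail
is never part of the window. Composition profiles are per-offset base
fractions; motif profiles tally the k-mer (k = 5) starting at every offset
from −W to W−k+1, so each offset column sums to the number of usable sites;
motifs are ranked by total count with lexicographic tie-breaks and reported
in the RNA alphabet. Overlapping occurrences all count, matching an
exhaustive scan.

Signal classification anchors a motif occurrence at its 5'-most base and
requires it fully upstream of the site (start ≤ −k). "In window" means
start offset in [−20, −10]. Classes are assigned in precedence order:
exact in window, 1 mismatch in window, ≤ 1 mismatch outside the window,
2 mismatches in window, none — one class per site, first match wins.
With uniform background the chance of an exact 5-mer hit somewhere in the
11 in-window start offsets is 1 − (1 − 4⁻⁵)¹¹ ≈ 0.0107; planted-signal
recovery tests add this analytic background to the planted rate.

## Expression and differential usage

TPM: `tpm[g,l] = counts[g,l] / library_total[l] × 1e6`; zero-total
libraries are an error.

**Differential expression** uses a self-contained overdispersed count test:
variance `m + α·m²` with a single dispersion α estimated by method of
moments from within-condition residuals pooled across all genes, then a
two-sided Wald test of equal relative abundance on pooled per-condition
proportions, per condition pair. BH-FDR is applied within each pair
(Bonferroni also reported); a gene is "differential in at least one pair"
when any pair's q ≤ α. Genes below a 5-count total floor are excluded.
Under a 2,000-gene Poisson null with 3v3 replicates the empirical type-I
rate at p < 0.05 is ≈ 0.046–0.055; an 8-fold planted change at mean 200 is
detected at q ≤ 0.05 with power ≈ 1.

**Differential PAC usage** compares member tags against the gene's remaining
tags per library. Counts are modeled beta-binomially; the intraclass
correlation ρ is estimated once by pooled method of moments across all
tested PACs and held fixed while per-condition proportions are profiled by
bounded 1-D likelihood maximization, giving a 1-df likelihood-ratio test
(exact binomial profile when ρ degenerates to 0). Only PACs of genes with
≥ 2 PACs above the count floor are tested; pairs with a zero gene total in
a condition are recorded as skipped. BH-FDR runs across all (PAC, pair)
hypotheses. Under a 2,000-PAC beta-binomial null (ρ = 0.02, totals ≈ 300)
the type-I rate is ≈ 0.049–0.054, and planted usage switches 0.3 → 0.7 at
those totals are recovered with ≈ 100% power. Fixing ρ at the pooled
moment estimate rather than maximizing it per hypothesis is deliberate:
with three replicates per condition a per-PAC ρ estimate is unstable and
the resulting LRT poorly calibrated, while the shared estimate is precise.

Log2 ratios use 0.5 pseudo-counts. Significant 5'UTR PACs are additionally
flagged when another same-strand gene's transcript end lies within 250 bp
upstream (their usage signal likely reflects the upstream gene's
expression), and an APA-vs-expression contrast reports each gene's maximum
absolute log2 fold-change across pairs for the all-genes and APA-genes
sets.

## The synthetic experiment

The generator is the package's test bed and defines its study conditions:
12 libraries (TP, TAP, HS, HAS × 3 replicates; media names follow the
growth regimens of the motivating study), default 15,000 reads each, read
length 60, barcodes of 6 nt with pairwise Hamming distance ≥ 2, tails of
12–30 nt (always above the trimming threshold), per-base substitution error
0.001 confined to the templated portion (barcode and tract clean by
default, keeping demultiplexing tests crisp). The nuclear contig holds 50
genes with 5'UTR (60–150 nt), an intron-containing CDS (80% of genes, 1–2
introns), and a 3'UTR (160–340 nt) hosting 1–3 cleavage sites spaced > 30
nt; minor sites appear in 5'UTR/CDS/intron at rate 0.08 each. 60% of UTR
sites carry UGUAA planted with its start 15 nt upstream. Per-gene usage
proportions are Dirichlet draws, redrawn per condition for the 25% of genes
designated condition-dependent; expression weights are log-normal. An
organelle-like contig carries rRNA/tRNA features (8% of reads) whose tails
are heteropolymeric at per-base non-A rate 0.05.

Every planted site gets the local mRNA-sense context `C A A C` at offsets
−3..0. This serves two purposes: it reproduces the observed G+C preference
at the cleavage site flanked by A-richness, and it makes the planted
coordinate identifiable — a templated 3'-terminal A is indistinguishable
from the first tail base after oligo-dT trimming, so exact-coordinate
recovery is only a well-posed target when the site base is non-A.

What the generator does *not* emulate: quality-score variation, indels, PCR
duplicates, internal oligo-dT mispriming, spliced tags (templated portions
are genomic), microheterogeneity around sites, and realistic GC content
(bases are uniform). Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic and arithmetic on reads whose anatomy
matches the assay — not robustness to every artifact of real libraries.

## Known limitation: censored tail bases

Recovered heteropolymeric-tail statistics are biased low relative to the
generative per-base non-A rate q, for structural reasons shared with the
real assay: (i) a non-A within the first 3 tract bases cannot satisfy the
trimming grammar's both-sides T-flank requirement (the read is rejected for
lacking a T-tract), (ii) a non-A abutting the mRNA junction ends up in a
1-nt clip that fails the tail's T-fraction rule, and (iii) tract-edge
positions can never contribute a recoverable non-A yet always count in the
denominator (a deficit of ≈ 6q/L for tail length L). At q = 0.05 and
L = 12–30 the recovered aggregate fraction is ≈ 0.035 versus the planted
≈ 0.05. The simulation-level truth tables record the planted counts, and
the test suite verifies the planted rate is binomial at 0.05 while the
recovered rate reflects this censoring; per-read tail recovery is exact
whenever the tail survives trimming intact.

## Problem sizes and numerics

The acceptance computations use 200,000 reads over 50 genes for recovery, a
5,000-site panel for signal analytics, ~2,000 tailed reads for tail
recovery, and 2,000-hypothesis simulations for test calibration — sizes at
which every targeted quantity's sampling error is well inside its tolerance.
Beta-binomial profiling uses bounded Brent minimization on p ∈ [1e−9,
1−1e−9] with xatol 1e−8; ρ is clipped to [0, 0.95]; BH and Bonferroni come
from statsmodels. All randomness flows from explicit seeds through
numpy Generator streams keyed per stage, so genome, truth and FASTQ outputs
are byte-reproducible.
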