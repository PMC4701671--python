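# patseq

Genome-wide analysis of mRNA polyadenylation from poly(A)-tag sequencing
(PAT-seq) data, modeled on the 3'-end landscape of the green alga
*Chlamydomonas reinhardtii*.

PAT-seq libraries consist of short cDNAs that span the mRNA–poly(A)
junction. Each raw read is

```
barcode + oligo(dT) tract + reverse complement of the mRNA 3' end
```

so that, after demultiplexing and trimming, the 5'-most aligned base of the
tag marks the exact cleavage/polyadenylation site. `patseq` implements the
full analysis from raw reads to biology:

- **Tag processing** — barcode demultiplexing, oligo-dT tract trimming (with
  recovery of non-T interruptions that reveal heteropolymeric tails),
  mapping (built-in unique-best mapper for synthetic genomes, SAM ingestion
  for external aligners), and *reduction* of each alignment to a one-base
  poly(A) site (PAS) coordinate.
- **Site calling** — PAS supported by ≥ 10 tags across libraries are
  retained; all sites are chained into poly(A) site clusters (PACs) by
  single linkage at ≤ 24 nt, and clusters with < 10 tags are removed.
- **Annotation** — each PAS/PAC is classified against the gene models
  (3'UTR, the 25-nt extension past annotated 3'UTR ends, CDS, 5'UTR,
  intron, ambiguous, unannotated), with sense/antisense orientation;
  unannotated PACs within 100 bp downstream of an extended 3'UTR are linked
  to that gene, and per-feature tag abundance is computed for
  organellar-style contigs (rRNA/tRNA features).
- **Signal analytics** — position-by-position base composition and
  exhaustive positional 5-mer motif profiles in ±80-nt windows around
  cleavage sites, plus per-site classification of the UGUAA polyadenylation
  signal (exact / 1-mismatch occurrences with start offsets in the −20..−10
  window, out-of-window matches, 2-mismatch variants).
- **Differential analyses** — tags-per-million (TPM) normalization, a
  shared-dispersion overdispersed count test for differential expression
  across growth conditions, and a beta-binomial likelihood-ratio test for
  differential PAC usage (alternative polyadenylation), both with
  Benjamini–Hochberg FDR.
- **Synthetic data** — a generator that builds a small annotated genome,
  plants cleavage sites with UGUAA signals 10–20 nt upstream,
  condition-dependent usage proportions and organelle-like contigs with
  heteropolymeric tails, then simulates the 12-library experiment
  (4 media conditions × 3 replicates) with full ground truth.

## Worked example

```python
import patseq as ps

cfg = ps.SimConfig(seed=4, n_genes=20, libraries=ps.default_libraries(2000),
                   error_rate=0.0)
sim = ps.simulate_experiment(cfg, "demo")
run = ps.run_pipeline_fastq(sim.fastq_paths.values(), sim.barcodes, sim.genome)

ann = ps.GeneAnnotation.from_gff3(sim.gff_path)
pas, pacs = ps.classify_result(run, ann)

utr3 = pas[(pas.region_class == "UTR3") & (pas.orientation == "SENSE")]
wins, _ = ps.extract_windows(utr3, sim.genome, W=80)
prof = ps.motif_profile(wins, k=5, W=80, top_n=50)
classes = [ps.classify_signal(w) for w in wins]
```

prints, via the pipeline statistics and profiles:

```
reads: 24000  assigned: 24000  trimmed: 23658  mapped: 23657
PAS (unfiltered): 69  PAS (>=10 tags): 54  PACs: 53
sense PAS by region: {'UTR3': 0.927, 'UTR5': 0.049, 'INTRON': 0.024}
top motif: UGUAA  modal start offset: -15
UGUAA exact in -20..-10: 0.579
```

Reading: of 24,000 simulated tag reads, 23,657 map and reduce to single-base
coordinates; 54 sites clear the 10-tag support filter and chain into 53
clusters. 93% of sense-oriented sites fall in annotated 3'UTRs; the most
abundant 5-mer around 3'UTR sites is UGUAA with its modal start 15 nt
upstream of cleavage; and 58% of 3'UTR sites carry an exact UGUAA in the
−20..−10 window — the planted signal recovered on top of the analytic random
background.

A `patseq` console script exposes the same stages
(`simulate`, `demux`, `trim`, `map`, `reduce`, `callpas`, `cluster`,
`annotate`, `signals`, `expr`, `usage`); see `patseq --help`.

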