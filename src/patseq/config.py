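"""Pipeline configuration.

Every analysis constant of the pipeline lives here: the 10-tag support
filters for poly(A) sites (PAS) and clusters (PACs), the 24-nt cluster
chaining distance, the 25-nt 3'UTR extension, the 100-bp nearest-feature
linkage for unannotated clusters, the 250-bp upstream-gene proximity window,
the 5-nt motif scan over +/-80-nt windows, the UGUAA signal and its
-20..-10 search window, and the tag-processing defaults (trimming and
mapping thresholds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

#: Default 3' sequencing-adapter stub searched for (and removed) after the
#: oligo-dT tract; present when short inserts are sequenced through.
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class PipelineConfig:
    # --- site calling / clustering ---
    min_pas_tags: int = 10      #: minimum tags across libraries to keep a PAS
    max_gap: int = 24           #: chain PAS within this distance (nt, inclusive)
    min_pac_tags: int = 10      #: minimum total PATs to keep a PAC
    # --- genic classification ---
    utr3_extension: int = 25    #: nt past an annotated 3'UTR still called UTR3_EXT
    near_gene_max_dist: int = 100   #: bp linkage window for unannotated PACs
    upstream_gene_window: int = 250  #: bp window for upstream-gene proximity flag
    # --- signal / motif analytics ---
    motif_k: int = 5
    motif_window: int = 80      #: half-width W of the site-centred window (nt)
    signal_window: Tuple[int, int] = (-20, -10)  #: start-offset range, inclusive
    signal_motif: str = "TGTAA"  #: DNA spelling of the UGUAA signal
    top_n_motifs: int = 50
    # --- differential tests ---
    fdr_alpha: float = 0.05
    min_gene_count: int = 5     #: total-count floor before testing a gene
    # --- tag processing ---
    min_t_tract: int = 8        #: minimum leading T-run length to accept a read
    min_tag_length: int = 20    #: minimum tag length after trimming
    adapter: str = DEFAULT_ADAPTER
    max_bc_mismatch: int = 0
    max_mismatches: int = 1     #: mapping mismatch tolerance
    max_clip5: int = 20         #: maximum unaligned 5' prefix (tail remnants)
    seed_len: int = 16          #: k-mer seed length of the built-in mapper

    def __post_init__(self) -> None:
        ints = (
            self.min_pas_tags, self.max_gap, self.min_pac_tags,
            self.utr3_extension, self.near_gene_max_dist,
            self.upstream_gene_window, self.motif_k, self.motif_window,
            self.top_n_motifs, self.min_gene_count, self.min_t_tract,
            self.min_tag_length, self.max_bc_mismatch, self.max_mismatches,
            self.max_clip5, self.seed_len,
        )
        if any(v < 0 for v in ints):
            raise ValueError("all thresholds must be >= 0")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        lo, hi = self.signal_window
        if lo > hi or hi > 0:
            raise ValueError("signal_window must be an upstream (negative) range")
        if self.motif_k <= 0 or len(self.signal_motif) == 0:
            raise ValueError("motif parameters must be non-empty")
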