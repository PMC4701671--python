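"""End-to-end orchestration: raw FASTQ -> PAS/PAC tables with annotation.

Glue over the stage modules so tests, the command line and scripts can run
the whole analysis in one call: demultiplex all input FASTQ streams against
the barcode sheet, trim/map/reduce each library, aggregate PAS, chain PACs,
classify both against the gene annotation, and keep the per-stage read
accounting needed for conservation audits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .annotate import GeneAnnotation, UNANNOTATED
from .config import PipelineConfig
from .sequtil import iter_fastq
from .sitecall import call_pas, cluster_pacs
from .tagproc import GenomeIndex, TagStats, TailRecord, demultiplex, process_library


@dataclass
class PipelineResult:
    stats: TagStats
    per_library_stats: Dict[str, TagStats]
    pas_filtered: pd.DataFrame
    pas_unfiltered: pd.DataFrame
    pacs: pd.DataFrame
    pac_members: pd.DataFrame
    pacs_dropped: pd.DataFrame
    tails: List[TailRecord]

    def pac_counts_matrix(self) -> pd.DataFrame:
        lib_cols = [c for c in self.pacs.columns
                    if c not in ("pac_id", "contig", "strand", "start", "end",
                                 "n_members", "representative", "total")]
        return self.pacs.set_index("pac_id")[lib_cols]


def run_pipeline(
    reads: Iterable[Tuple[str, str, str]],
    barcodes: Dict[str, str],
    genome: Dict[str, str],
    config: Optional[PipelineConfig] = None,
    index: Optional[GenomeIndex] = None,
) -> PipelineResult:
    """Demultiplex -> trim -> map -> reduce -> PAS -> PAC for a read stream."""
    cfg = config or PipelineConfig()
    idx = index or GenomeIndex(genome, seed_len=cfg.seed_len)
    by_lib, unassigned = demultiplex(reads, barcodes, cfg.max_bc_mismatch)
    total_stats = TagStats()
    total_stats.n_input = unassigned
    total_stats.n_unassigned = unassigned
    per_lib: Dict[str, TagStats] = {}
    site_rows: List[Tuple[str, str, int, str]] = []
    tails: List[TailRecord] = []
    for lib, lib_reads in by_lib.items():
        rows, lib_tails, stats = process_library(lib, lib_reads, idx, cfg)
        site_rows.extend(rows)
        tails.extend(lib_tails)
        per_lib[lib] = stats
        total_stats.add(stats)
    libraries = list(barcodes)
    pas_filtered, pas_unfiltered = call_pas(
        site_rows, min_pas_tags=cfg.min_pas_tags, libraries=libraries)
    pacs, members, dropped = cluster_pacs(
        pas_unfiltered, max_gap=cfg.max_gap, min_pac_tags=cfg.min_pac_tags)
    return PipelineResult(
        stats=total_stats, per_library_stats=per_lib,
        pas_filtered=pas_filtered, pas_unfiltered=pas_unfiltered,
        pacs=pacs, pac_members=members, pacs_dropped=dropped, tails=tails,
    )


def run_pipeline_fastq(
    fastq_paths: Iterable[str],
    barcodes: Dict[str, str],
    genome: Dict[str, str],
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """As :func:`run_pipeline` but streaming reads from FASTQ files."""
    def stream():
        for path in fastq_paths:
            yield from iter_fastq(path)
    return run_pipeline(stream(), barcodes, genome, config)


def classify_result(
    result: PipelineResult,
    annotation: GeneAnnotation,
    config: Optional[PipelineConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Classify filtered PAS and PAC representatives against the annotation.

    Returns (pas_classified, pacs_classified); unannotated PACs additionally
    get linked_gene / linked_distance columns from nearest-3'UTR linkage.
    """
    cfg = config or PipelineConfig()
    pas = annotation.classify_table(result.pas_filtered)
    pacs = result.pacs.copy()
    pacs["position"] = pacs["representative"]
    pacs = annotation.classify_table(pacs).drop(columns="position")
    linked_gene: List[Optional[str]] = []
    linked_dist: List[Optional[int]] = []
    for _, row in pacs.iterrows():
        if row["region_class"] == UNANNOTATED:
            link = annotation.link_unannotated(
                row["contig"], row["strand"], int(row["representative"]),
                max_dist=cfg.near_gene_max_dist)
        else:
            link = None
        linked_gene.append(link[0] if link else None)
        linked_dist.append(link[1] if link else None)
    pacs["linked_gene"] = linked_gene
    pacs["linked_distance"] = linked_dist
    return pas, pacs
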