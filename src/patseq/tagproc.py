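"""Tag processing: demultiplex, oligo-dT trimming, mapping, site reduction.

A poly(A) tag (PAT) read is ``barcode + T-tract + revcomp(mRNA 3' end)``.
After the barcode is removed and the T-tract stripped, the trimmed tag is the
reverse complement of the transcript's 3' terminus, so the tag's 5'-most
aligned base marks the cleavage/polyadenylation site: the alignment is
reduced to that one-base coordinate (reported on the mRNA strand, the
opposite of the strand the read maps to).

The built-in mapper is an exact / <=m-mismatch full-length search with a
unique-best requirement, intended for the synthetic genomes produced by
:mod:`patseq.synthdata`; alignments against real genomes can be ingested as
SAM instead (soft clips supply the unaligned 5' prefix).

Untemplated tail remnants (the trimmed T-tract plus any T-rich 5' soft clip)
are collected into :class:`TailRecord` objects; non-T read bases within the
tail are reported in mRNA sense as non-A, and a tail with at least one non-A
is flagged heteropolymeric.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pandas as pd
import pysam

from .config import DEFAULT_ADAPTER, PipelineConfig
from .sequtil import revcomp


class TrimReason(str, Enum):
    NO_T_TRACT = "NO_T_TRACT"
    TOO_SHORT = "TOO_SHORT"
    ADAPTER_ONLY = "ADAPTER_ONLY"


class MapReason(str, Enum):
    UNMAPPED = "UNMAPPED"
    MULTIMAPPED = "MULTIMAPPED"
    AMBIGUOUS_CLIP = "AMBIGUOUS_CLIP"


@dataclass
class PolyATag:
    sequence: str
    t_tract_length: int
    tail_non_t_positions: Tuple[Tuple[int, str], ...] = ()
    read_id: str = ""
    library_id: str = ""


@dataclass
class TrimRejection:
    reason: TrimReason
    read_id: str = ""


@dataclass
class TagAlignment:
    contig: str
    tag_strand: str            # strand the read maps to
    mrna_strand: str           # opposite: strand of the source transcript
    start: int                 # 0-based half-open alignment footprint
    end: int
    site_position: int         # 0-based coordinate of the last templated base
    mismatches: int
    clip5_sequence: str
    read_id: str = ""


@dataclass
class MapRejection:
    reason: MapReason
    read_id: str = ""


@dataclass
class TailRecord:
    tail_length: int
    non_a_count: int
    heteropolymeric: bool
    clip_excluded: bool = False
    read_id: str = ""


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Iterable[Tuple[str, str, str]],
    barcodes: Dict[str, str],
    max_bc_mismatch: int = 0,
) -> Tuple[Dict[str, List[Tuple[str, str, str]]], int]:
    """Assign reads to libraries by barcode prefix; strip the barcode.

    A read is assigned only when exactly one barcode lies within
    ``max_bc_mismatch`` of its prefix; ties are counted as unassigned
    (ambiguity is not an exception). Returns (per-library reads, unassigned).
    """
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("barcodes must share one length")
    blen = lengths.pop()
    by_lib: Dict[str, List[Tuple[str, str, str]]] = {lib: [] for lib in barcodes}
    exact = {bc: lib for lib, bc in barcodes.items()}
    if len(exact) != len(barcodes):
        raise ValueError("barcodes must be unique")
    unassigned = 0
    items = list(barcodes.items())
    for rid, seq, qual in reads:
        prefix = seq[:blen]
        if max_bc_mismatch == 0:
            lib = exact.get(prefix)
        elif len(prefix) == blen:
            hits = [
                l for l, bc in items
                if sum(a != b for a, b in zip(prefix, bc)) <= max_bc_mismatch
            ]
            lib = hits[0] if len(hits) == 1 else None
        else:
            lib = None
        if lib is None or len(seq) <= blen:
            unassigned += 1
        else:
            by_lib[lib].append((rid, seq[blen:], qual[blen:]))
    return by_lib, unassigned


# ---------------------------------------------------------------------------
# oligo-dT trimming
# ---------------------------------------------------------------------------

def _scan_t_tract(seq: str) -> Tuple[int, List[Tuple[int, str]]]:
    """Maximal leading T-run; an isolated non-T is absorbed only when flanked
    on both sides by >= 3 T. Returns (tract length, interruptions)."""
    i = 0
    n = len(seq)
    interruptions: List[Tuple[int, str]] = []
    while i < n:
        if seq[i] == "T":
            i += 1
            continue
        if i >= 3 and seq[i - 3:i] == "TTT" and seq[i + 1:i + 4] == "TTT":
            interruptions.append((i, seq[i]))
            i += 1
            continue
        break
    return i, interruptions


def trim_tag(
    seq: str,
    min_t_tract: int = 8,
    min_tag_length: int = 20,
    adapter: str = DEFAULT_ADAPTER,
    min_adapter_overlap: int = 8,
) -> Union[PolyATag, TrimRejection]:
    """Strip the oligo-dT tract (and any 3' adapter) from a demultiplexed read."""
    tract_len, interruptions = _scan_t_tract(seq)
    rest = seq[tract_len:]
    adapter_trimmed = False
    if adapter:
        idx = rest.find(adapter)
        if idx >= 0:
            rest = rest[:idx]
            adapter_trimmed = True
        else:
            for l in range(min(len(adapter), len(rest)), min_adapter_overlap - 1, -1):
                if rest.endswith(adapter[:l]):
                    rest = rest[: len(rest) - l]
                    adapter_trimmed = True
                    break
    if tract_len < min_t_tract:
        return TrimRejection(TrimReason.NO_T_TRACT)
    if not rest and adapter_trimmed:
        return TrimRejection(TrimReason.ADAPTER_ONLY)
    if len(rest) < min_tag_length:
        return TrimRejection(TrimReason.TOO_SHORT)
    return PolyATag(
        sequence=rest,
        t_tract_length=tract_len,
        tail_non_t_positions=tuple(interruptions),
    )


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

class GenomeIndex:
    """Forward-strand k-mer seed index over all contigs.

    Minus-strand alignment is handled by searching the reverse complement of
    the query, so only forward k-mers are stored.
    """

    def __init__(self, genome: Dict[str, str], seed_len: int = 16):
        self.genome = dict(genome)
        self.seed_len = seed_len
        index: Dict[str, List[Tuple[str, int]]] = {}
        for contig, seq in self.genome.items():
            for i in range(len(seq) - seed_len + 1):
                index.setdefault(seq[i:i + seed_len], []).append((contig, i))
        self._index = index

    def candidates(self, q: str, max_mismatches: int) -> List[Tuple[int, str, int]]:
        """Forward full-length alignments of q: list of (mismatches, contig, start)."""
        k = self.seed_len
        if len(q) < k:
            return []
        offsets = [0]
        if len(q) >= 2 * k:
            offsets.append(k)
        seen = set()
        out: List[Tuple[int, str, int]] = []
        for off in offsets:
            for contig, pos in self._index.get(q[off:off + k], ()):
                start = pos - off
                seq = self.genome[contig]
                if start < 0 or start + len(q) > len(seq):
                    continue
                key = (contig, start)
                if key in seen:
                    continue
                seen.add(key)
                ref = seq[start:start + len(q)]
                if ref == q:
                    out.append((0, contig, start))
                    continue
                mm = 0
                for a, b in zip(q, ref):
                    if a != b:
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm <= max_mismatches:
                    out.append((mm, contig, start))
        return out


def map_tag(
    tag: Union[PolyATag, str],
    index: GenomeIndex,
    max_mismatches: int = 1,
    max_clip5: int = 20,
    min_align_len: int = 16,
) -> Union[TagAlignment, MapRejection]:
    """Map a trimmed tag full-length (or minus a 5' prefix up to max_clip5).

    Candidates are scored ``aligned_length - 4 * mismatches``; the best score
    wins, ties between clip lengths go to the smallest clip, and a score tie
    between distinct loci is rejected as MULTIMAPPED. Mapping is independent
    of input order.
    """
    seq = tag.sequence if isinstance(tag, PolyATag) else tag
    rc = revcomp(seq)
    n = len(seq)
    best: Optional[Tuple[int, int, int, List[Tuple[str, str, int]]]] = None
    for clip in range(0, max_clip5 + 1):
        alen = n - clip
        if alen < min_align_len:
            break
        if best is not None and alen <= best[0]:
            break    # even a perfect match cannot beat the current score
        found: List[Tuple[int, str, str, int]] = []
        for mm, contig, start in index.candidates(seq[clip:], max_mismatches):
            found.append((mm, "+", contig, start))
        for mm, contig, start in index.candidates(rc[:alen], max_mismatches):
            found.append((mm, "-", contig, start))
        if found:
            top = max(alen - 4 * mm for mm, *_ in found)
            loci = [(strand, contig, start)
                    for mm, strand, contig, start in found
                    if alen - 4 * mm == top]
            mm_at_top = (alen - top) // 4
            if best is None or top > best[0]:
                best = (top, mm_at_top, clip, loci)
    if best is None:
        return MapRejection(MapReason.UNMAPPED)
    _score, mm, clip, loci = best
    if len(set(loci)) > 1:
        return MapRejection(MapReason.MULTIMAPPED)
    tag_strand, contig, start = loci[0]
    alen = n - clip
    end = start + alen
    mrna_strand = "-" if tag_strand == "+" else "+"
    site = end - 1 if mrna_strand == "+" else start
    return TagAlignment(
        contig=contig, tag_strand=tag_strand, mrna_strand=mrna_strand,
        start=start, end=end, site_position=site, mismatches=mm,
        clip5_sequence=seq[:clip],
    )


def reduce_to_site(aln: TagAlignment) -> Tuple[str, str, int]:
    """One-base reduction: the tag's 5'-most aligned base is the cleavage
    coordinate (highest footprint coordinate for '+' mRNA, lowest for '-')."""
    site = aln.end - 1 if aln.mrna_strand == "+" else aln.start
    return aln.contig, aln.mrna_strand, site


# ---------------------------------------------------------------------------
# tail extraction
# ---------------------------------------------------------------------------

def extract_tail(tag: PolyATag, aln: TagAlignment) -> TailRecord:
    """Untemplated tail: trimmed T-tract plus any 5' clip with T-fraction >= 0.5.

    non_a_count counts non-T read bases in the tail, i.e. non-A bases of the
    poly(A) tail in mRNA sense; one or more makes the tail heteropolymeric.
    """
    tail_len = tag.t_tract_length
    non_a = len(tag.tail_non_t_positions)
    clip = aln.clip5_sequence
    clip_excluded = False
    if clip:
        t_frac = clip.count("T") / len(clip)
        if t_frac >= 0.5:
            tail_len += len(clip)
            non_a += sum(1 for b in clip if b != "T")
        else:
            clip_excluded = True
    return TailRecord(
        tail_length=tail_len,
        non_a_count=non_a,
        heteropolymeric=non_a >= 1,
        clip_excluded=clip_excluded,
        read_id=tag.read_id,
    )


# ---------------------------------------------------------------------------
# per-library processing and stage accounting
# ---------------------------------------------------------------------------

@dataclass
class TagStats:
    """Read-conservation ledger across the processing stages."""
    n_input: int = 0
    n_assigned: int = 0
    n_unassigned: int = 0
    n_trimmed: int = 0
    n_rejected: Dict[str, int] = field(default_factory=dict)
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0

    def add(self, other: "TagStats") -> None:
        self.n_input += other.n_input
        self.n_assigned += other.n_assigned
        self.n_unassigned += other.n_unassigned
        self.n_trimmed += other.n_trimmed
        self.n_mapped += other.n_mapped
        self.n_unmapped += other.n_unmapped
        self.n_multimapped += other.n_multimapped
        for k, v in other.n_rejected.items():
            self.n_rejected[k] = self.n_rejected.get(k, 0) + v

    @property
    def n_rejected_total(self) -> int:
        return sum(self.n_rejected.values())

    def conserved(self) -> bool:
        return (
            self.n_assigned + self.n_unassigned == self.n_input
            and self.n_trimmed + self.n_rejected_total == self.n_assigned
            and self.n_mapped + self.n_unmapped + self.n_multimapped
            == self.n_trimmed
        )


def process_library(
    library_id: str,
    reads: Iterable[Tuple[str, str, str]],
    index: GenomeIndex,
    config: Optional[PipelineConfig] = None,
) -> Tuple[List[Tuple[str, str, int, str]], List[TailRecord], TagStats]:
    """trim -> map -> reduce -> tail for one demultiplexed library.

    Returns (site rows (contig, mrna_strand, position, library), tail records,
    per-stage statistics). ``n_input``/``n_assigned`` are set to the number of
    reads given (demultiplexing is accounted separately).
    """
    cfg = config or PipelineConfig()
    stats = TagStats()
    site_rows: List[Tuple[str, str, int, str]] = []
    tails: List[TailRecord] = []
    for rid, seq, _qual in reads:
        stats.n_input += 1
        stats.n_assigned += 1
        trimmed = trim_tag(
            seq, min_t_tract=cfg.min_t_tract, min_tag_length=cfg.min_tag_length,
            adapter=cfg.adapter,
        )
        if isinstance(trimmed, TrimRejection):
            stats.n_rejected[trimmed.reason.value] = (
                stats.n_rejected.get(trimmed.reason.value, 0) + 1
            )
            continue
        stats.n_trimmed += 1
        trimmed.read_id = rid
        trimmed.library_id = library_id
        aln = map_tag(
            trimmed, index, max_mismatches=cfg.max_mismatches,
            max_clip5=cfg.max_clip5,
        )
        if isinstance(aln, MapRejection):
            if aln.reason is MapReason.MULTIMAPPED:
                stats.n_multimapped += 1
            else:
                stats.n_unmapped += 1
            continue
        stats.n_mapped += 1
        aln.read_id = rid
        contig, strand, pos = reduce_to_site(aln)
        site_rows.append((contig, strand, pos, library_id))
        tails.append(extract_tail(trimmed, aln))
    return site_rows, tails, stats


def sites_to_bed(rows: Sequence[Tuple[str, str, int, str]]) -> pd.DataFrame:
    """Reduced sites as 6-column BED (chrom, site, site+1, library, count, strand)."""
    df = pd.DataFrame(rows, columns=["contig", "strand", "position", "library"])
    g = (df.groupby(["contig", "position", "library", "strand"])
           .size().rename("count").reset_index())
    bed = pd.DataFrame({
        "chrom": g["contig"], "start": g["position"], "end": g["position"] + 1,
        "name": g["library"], "score": g["count"], "strand": g["strand"],
    })
    return bed.sort_values(["chrom", "start", "name"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# SAM interchange
# ---------------------------------------------------------------------------

def write_sam(
    path: str,
    records: Iterable[Tuple[PolyATag, TagAlignment]],
    genome: Dict[str, str],
) -> None:
    """Export alignments as text SAM; the 5' clip becomes a soft clip."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    contigs = list(genome)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for tag, aln in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = tag.read_id or "tag"
            clip = len(aln.clip5_sequence)
            alen = aln.end - aln.start
            if aln.tag_strand == "+":
                a.flag = 0
                a.query_sequence = tag.sequence
                a.cigartuples = ([(4, clip)] if clip else []) + [(0, alen)]
            else:
                a.flag = 16
                a.query_sequence = revcomp(tag.sequence)
                a.cigartuples = [(0, alen)] + ([(4, clip)] if clip else [])
            a.reference_id = contigs.index(aln.contig)
            a.reference_start = aln.start
            a.mapping_quality = 60
            a.set_tag("NM", aln.mismatches)
            a.set_tag("RG", tag.library_id or "NA")
            out.write(a)


def read_sam(path: str) -> Iterator[TagAlignment]:
    """Ingest externally produced alignments (clip5 from soft clips, strand
    from flags); secondary/supplementary/unmapped records are skipped."""
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            tag_strand = "-" if rec.is_reverse else "+"
            cig = rec.cigartuples or []
            if tag_strand == "+":
                clip_len = cig[0][1] if cig and cig[0][0] == 4 else 0
                clip_seq = (rec.query_sequence or "")[:clip_len]
            else:
                clip_len = cig[-1][1] if cig and cig[-1][0] == 4 else 0
                stored = rec.query_sequence or ""
                clip_seq = revcomp(stored[len(stored) - clip_len:]) if clip_len else ""
            start = rec.reference_start
            end = rec.reference_end
            mrna = "-" if tag_strand == "+" else "+"
            yield TagAlignment(
                contig=rec.reference_name, tag_strand=tag_strand,
                mrna_strand=mrna, start=start, end=end,
                site_position=end - 1 if mrna == "+" else start,
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                clip5_sequence=clip_seq, read_id=rec.query_name,
            )
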