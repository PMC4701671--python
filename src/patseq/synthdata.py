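"""Synthetic PAT-seq experiment generator with known ground truth.

Builds a small annotated genome (one nuclear contig of multi-exon genes with
5'UTR / intron-containing CDS / 3'UTR, plus one organelle-like contig with
rRNA- and tRNA-like features), plants cleavage/polyadenylation sites with a
UGUAA signal 10-20 nt upstream of most 3'UTR sites, assigns
condition-dependent usage proportions to each gene's sites, and simulates the
twelve-library tag-read experiment (4 growth conditions x 3 replicates).

Read anatomy mirrors the protocol: each read is

    barcode + T-tract + reverse complement of the mRNA 3' end,

where the T-tract is the reverse complement of a simulated poly(A) tail
(occasional non-A tail bases appear as non-T in the tract) and the templated
portion ends exactly at the planted cleavage site (the last genome-templated
base). Everything is deterministic under a fixed seed.

The generator writes plain-text FASTQ/FASTA/GFF3/TSV so the whole pipeline is
testable without any download, and records per-site, per-library truth tables
so every downstream stage has a recoverable answer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequtil import revcomp, write_fasta, write_fastq

CONDITIONS = ("TP", "TAP", "HS", "HAS")
NUCLEAR_CONTIG = "chr1"
ORGANELLE_CONTIG = "orgC"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SizingError(ValueError):
    """The contig cannot hold the requested number of genes."""


class PlacementError(ValueError):
    """A planted signal edit would cross a feature boundary."""


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    condition: str
    replicate: int
    n_reads: int


def default_libraries(n_reads_per_library: int = 15000) -> List[LibrarySpec]:
    """Twelve libraries: four media conditions in triplicate."""
    return [
        LibrarySpec(f"{c}_{r}", c, r, n_reads_per_library)
        for c in CONDITIONS
        for r in (1, 2, 3)
    ]


@dataclass
class SimConfig:
    seed: int = 0
    # genome layout
    n_genes: int = 50
    contig_length: int = 170_000
    utr5_range: Tuple[int, int] = (60, 150)
    cds_exon_range: Tuple[int, int] = (120, 400)
    intron_range: Tuple[int, int] = (80, 200)
    intron_fraction: float = 0.8       # fraction of genes with >=1 intron
    max_introns: int = 2
    utr3_range: Tuple[int, int] = (160, 340)
    intergenic_range: Tuple[int, int] = (250, 500)
    # organelle contig
    n_organelle_features: int = 6
    organelle_contig_length: int = 14_000
    organelle_read_fraction: float = 0.08
    # planted sites
    sites_per_utr3_range: Tuple[int, int] = (1, 3)
    site_min_spacing: int = 30         # > max_gap so each site is its own PAC
    utr5_site_rate: float = 0.08
    cds_site_rate: float = 0.08
    intron_site_rate: float = 0.08
    fraction_with_signal: float = 0.6
    signal_offset: int = -15           # start offset of the planted UGUAA
    signal_motif: str = "TGTAA"
    apa_gene_fraction: float = 0.25    # genes with condition-dependent usage
    # reads
    barcode_length: int = 6
    tail_length_range: Tuple[int, int] = (12, 30)
    tail_non_a_rate: float = 0.0
    organelle_tail_non_a_rate: float = 0.05
    read_length: int = 60
    error_rate: float = 0.001
    errors_in_tail: bool = False       # substitutions confined to templated part
    libraries: List[LibrarySpec] = field(default_factory=default_libraries)

    def __post_init__(self) -> None:
        for lo, hi in (
            self.utr5_range, self.cds_exon_range, self.intron_range,
            self.utr3_range, self.intergenic_range,
            self.sites_per_utr3_range, self.tail_length_range,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive with lo <= hi")
        for p in (
            self.intron_fraction, self.utr5_site_rate, self.cds_site_rate,
            self.intron_site_rate, self.fraction_with_signal,
            self.tail_non_a_rate, self.organelle_tail_non_a_rate,
            self.error_rate, self.apa_gene_fraction,
            self.organelle_read_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_genes < 0 or self.barcode_length <= 0:
            raise ValueError("counts must be non-negative, barcode length > 0")
        min_tag = self.read_length - self.barcode_length - self.tail_length_range[1]
        if min_tag < 20:
            raise ValueError(
                "read_length leaves <20 nt of templated tag at maximal tail length"
            )

    @property
    def conditions(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for lib in self.libraries:
            if lib.condition not in seen:
                seen.append(lib.condition)
        return tuple(seen)


@dataclass
class SynthGene:
    gene_id: str
    contig: str
    strand: str
    start: int                     # 0-based half-open genomic span
    end: int
    utr5: Tuple[int, int]
    cds_exons: List[Tuple[int, int]]
    introns: List[Tuple[int, int]]
    utr3: Tuple[int, int]


@dataclass
class SynthFeature:
    feature_id: str
    kind: str                      # "rRNA" | "tRNA"
    contig: str
    strand: str
    start: int
    end: int


@dataclass
class SynthAnnotation:
    genes: List[SynthGene]
    features: List[SynthFeature]

    def to_gff3(self) -> str:
        lines = ["##gff-version 3"]
        for g in self.genes:
            c, s = g.contig, g.strand
            lines.append(_gff_line(c, "gene", g.start, g.end, s, f"ID={g.gene_id}"))
            tid = f"{g.gene_id}.t1"
            lines.append(_gff_line(c, "mRNA", g.start, g.end, s,
                                   f"ID={tid};Parent={g.gene_id}"))
            for i, (es, ee) in enumerate(_exon_blocks(g), 1):
                lines.append(_gff_line(c, "exon", es, ee, s,
                                       f"ID={tid}.exon{i};Parent={tid}"))
            lines.append(_gff_line(c, "five_prime_UTR", *g.utr5, s,
                                   f"ID={tid}.utr5;Parent={tid}"))
            phase = 0
            cds = g.cds_exons if s == "+" else list(reversed(g.cds_exons))
            for i, (cs, ce) in enumerate(cds, 1):
                lines.append(_gff_line(c, "CDS", cs, ce, s,
                                       f"ID={tid}.cds;Parent={tid}", phase=phase))
                phase = (3 - ((ce - cs - phase) % 3)) % 3
            lines.append(_gff_line(c, "three_prime_UTR", *g.utr3, s,
                                   f"ID={tid}.utr3;Parent={tid}"))
        for f in self.features:
            lines.append(_gff_line(f.contig, "gene", f.start, f.end, f.strand,
                                   f"ID={f.feature_id}"))
            lines.append(_gff_line(f.contig, f.kind, f.start, f.end, f.strand,
                                   f"ID={f.feature_id}.1;Parent={f.feature_id}"))
        return "\n".join(lines) + "\n"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_gff3())


def _gff_line(contig: str, ftype: str, start: int, end: int, strand: str,
              attrs: str, phase: Optional[int] = None) -> str:
    ph = "." if phase is None else str(phase)
    # internal 0-based half-open -> GFF3 1-based inclusive
    return "\t".join(
        [contig, "patseq_sim", ftype, str(start + 1), str(end), ".", strand, ph, attrs]
    )


def _exon_blocks(g: SynthGene) -> List[Tuple[int, int]]:
    parts = sorted([g.utr5, g.utr3] + list(g.cds_exons))
    merged = [list(parts[0])]
    for s, e in parts[1:]:
        if s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class PlantedSite:
    site_id: str
    gene_id: str                   # gene or organelle feature id
    contig: str
    strand: str
    position: int                  # 0-based coordinate of last templated base
    region_class: str              # UTR3 / UTR5 / CDS / INTRON / ORGANELLE
    has_ugua_signal: bool
    signal_offset: Optional[int]
    usage_by_condition: Dict[str, float]


@dataclass
class SimTruth:
    sites: List[PlantedSite]
    gene_weights: Dict[str, float]
    config: SimConfig

    def sites_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            row = {
                "site_id": s.site_id, "gene_id": s.gene_id, "contig": s.contig,
                "strand": s.strand, "position": s.position,
                "region_class": s.region_class,
                "has_ugua_signal": s.has_ugua_signal,
                "signal_offset": s.signal_offset,
            }
            for c, u in s.usage_by_condition.items():
                row[f"usage_{c}"] = u
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)].copy()


def _rint(rng: np.random.Generator, lohi: Tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def make_genome(config: SimConfig) -> Tuple[Dict[str, str], SynthAnnotation]:
    """Build the random genome and its gene/feature annotation.

    Deterministic under ``config.seed``; raises :class:`SizingError` when the
    nuclear contig cannot hold ``n_genes`` with the configured structure.
    """
    rng = np.random.default_rng([1, config.seed])
    nuclear = _random_seq(rng, config.contig_length)
    organelle = _random_seq(rng, config.organelle_contig_length)

    genes: List[SynthGene] = []
    cursor = 200
    for i in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        utr5_len = _rint(rng, config.utr5_range)
        utr3_len = _rint(rng, config.utr3_range)
        n_introns = (
            int(rng.integers(1, config.max_introns + 1))
            if rng.random() < config.intron_fraction else 0
        )
        exon_lens = [_rint(rng, config.cds_exon_range) for _ in range(n_introns + 1)]
        intron_lens = [_rint(rng, config.intron_range) for _ in range(n_introns)]
        # transcript order: UTR5, exon1, (intron1, exon2, ...), UTR3
        parts: List[Tuple[str, int]] = [("utr5", utr5_len)]
        for j, el in enumerate(exon_lens):
            if j > 0:
                parts.append(("intron", intron_lens[j - 1]))
            parts.append(("cds", el))
        parts.append(("utr3", utr3_len))
        span = sum(l for _, l in parts)
        if cursor + span > config.contig_length - 200:
            raise SizingError(
                f"contig of {config.contig_length} bp too short for "
                f"{config.n_genes} genes (gene {i} does not fit)"
            )
        laid = parts if strand == "+" else list(reversed(parts))
        pos = cursor
        ivals: Dict[str, List[Tuple[int, int]]] = {"utr5": [], "cds": [],
                                                   "intron": [], "utr3": []}
        for kind, length in laid:
            ivals[kind].append((pos, pos + length))
            pos += length
        genes.append(SynthGene(
            gene_id=f"g{i + 1:04d}", contig=NUCLEAR_CONTIG, strand=strand,
            start=cursor, end=cursor + span,
            utr5=ivals["utr5"][0], cds_exons=sorted(ivals["cds"]),
            introns=sorted(ivals["intron"]), utr3=ivals["utr3"][0],
        ))
        cursor += span + _rint(rng, config.intergenic_range)

    features: List[SynthFeature] = []
    ocursor = 200
    for i in range(config.n_organelle_features):
        kind = "rRNA" if i % 2 == 0 else "tRNA"
        length = _rint(rng, (800, 1500) if kind == "rRNA" else (75, 90))
        strand = "+" if rng.random() < 0.5 else "-"
        if ocursor + length > config.organelle_contig_length - 200:
            raise SizingError("organelle contig too short for requested features")
        features.append(SynthFeature(
            feature_id=f"org{i + 1:02d}", kind=kind, contig=ORGANELLE_CONTIG,
            strand=strand, start=ocursor, end=ocursor + length,
        ))
        ocursor += length + _rint(rng, (120, 300))

    genome = {
        NUCLEAR_CONTIG: nuclear.tobytes().decode(),
        ORGANELLE_CONTIG: organelle.tobytes().decode(),
    }
    return genome, SynthAnnotation(genes=genes, features=features)


# ---------------------------------------------------------------------------
# site planting
# ---------------------------------------------------------------------------

def _spaced_offsets(rng: np.random.Generator, lo: int, hi: int, n: int,
                    spacing: int) -> List[int]:
    """n sorted offsets in [lo, hi] pairwise >= spacing apart."""
    slack = (hi - lo) - (n - 1) * spacing
    if slack < 0:
        raise ValueError("interval too small for spaced offsets")
    picks = np.sort(rng.choice(slack + 1, size=n, replace=False if slack + 1 >= n else True))
    return [int(lo + picks[i] + i * spacing) for i in range(n)]


def _mrna_to_genomic(strand: str, pos: int, offset: int) -> int:
    """Genomic index of transcript-sense ``offset`` relative to site ``pos``."""
    return pos + offset if strand == "+" else pos - offset


def _edit_mrna(seq: bytearray, strand: str, pos: int, offset: int,
               bases: str, host: Tuple[int, int]) -> None:
    """Write ``bases`` (mRNA sense, 5'->3' starting at ``offset``) into seq.

    ``host`` is the genomic interval the edit must stay inside.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for k, b in enumerate(bases):
        g = _mrna_to_genomic(strand, pos, offset + k)
        if not host[0] <= g < host[1]:
            raise PlacementError(
                f"edit at genomic {g} crosses feature boundary {host}"
            )
        seq[g] = ord(b if strand == "+" else comp[b])


#: mRNA-sense context written at offsets -3..0 of every planted site: a non-A
#: terminal base (G+C trend at the cleavage site) makes the coordinate
#: identifiable after oligo-dT trimming; the upstream C breaks T-runs.
SITE_CONTEXT = "CAAC"


def plant_sites(
    genome: Dict[str, str],
    annotation: SynthAnnotation,
    config: SimConfig,
) -> Tuple[Dict[str, str], SimTruth]:
    """Plant cleavage sites (and UGUAA signals) into the genome.

    Returns the edited genome and the ground truth. For a configurable
    fraction of UTR sites the sequence is edited so the signal motif starts
    ``signal_offset`` nt upstream of the cleavage site. Usage proportions per
    condition are recorded per gene; genes in the APA fraction draw distinct
    proportions per condition.
    """
    rng = np.random.default_rng([2, config.seed])
    seqs = {c: bytearray(s.encode()) for c, s in genome.items()}
    conditions = config.conditions
    sites: List[PlantedSite] = []
    gene_weights: Dict[str, float] = {}
    serial = 0

    def new_site(gene_id: str, contig: str, strand: str, pos: int,
                 region: str, signal: bool) -> PlantedSite:
        nonlocal serial
        serial += 1
        return PlantedSite(
            site_id=f"S{serial:05d}", gene_id=gene_id, contig=contig,
            strand=strand, position=pos, region_class=region,
            has_ugua_signal=signal,
            signal_offset=config.signal_offset if signal else None,
            usage_by_condition={},
        )

    spacing = config.site_min_spacing
    sig_len = len(config.signal_motif)
    margin5 = -config.signal_offset + sig_len + 1   # room for the signal edit

    for g in annotation.genes:
        seq = seqs[g.contig]
        s3, e3 = g.utr3
        utr3_len = e3 - s3
        lo, hi = margin5, utr3_len - 4
        n_max = (hi - lo) // spacing + 1 if hi >= lo else 0
        n_sites = min(_rint(rng, config.sites_per_utr3_range), max(n_max, 0))
        gene_sites: List[PlantedSite] = []
        if n_sites > 0:
            for off in _spaced_offsets(rng, lo, hi, n_sites, spacing):
                pos = s3 + off if g.strand == "+" else e3 - 1 - off
                signal = bool(rng.random() < config.fraction_with_signal)
                site = new_site(g.gene_id, g.contig, g.strand, pos, "UTR3", signal)
                _edit_mrna(seq, g.strand, pos, -3, SITE_CONTEXT, (s3, e3))
                if signal:
                    _edit_mrna(seq, g.strand, pos, config.signal_offset,
                               config.signal_motif, (s3, e3))
                gene_sites.append(site)
        # optional minor sites in 5'UTR / CDS / intron
        minor: List[Tuple[str, Tuple[int, int], bool]] = []
        if rng.random() < config.utr5_site_rate:
            if g.utr5[1] - g.utr5[0] >= margin5 + 6:
                minor.append(("UTR5", g.utr5,
                              bool(rng.random() < config.fraction_with_signal)))
        if rng.random() < config.cds_site_rate:
            wide = [iv for iv in g.cds_exons if iv[1] - iv[0] >= 40]
            if wide:
                minor.append(("CDS", wide[int(rng.integers(len(wide)))], False))
        if g.introns and rng.random() < config.intron_site_rate:
            wide = [iv for iv in g.introns if iv[1] - iv[0] >= 40]
            if wide:
                minor.append(("INTRON", wide[int(rng.integers(len(wide)))], False))
        for region, (fs, fe), signal in minor:
            flen = fe - fs
            lo_m = margin5 if signal else 5
            off = int(rng.integers(lo_m, flen - 4))
            pos = fs + off if g.strand == "+" else fe - 1 - off
            site = new_site(g.gene_id, g.contig, g.strand, pos, region, signal)
            _edit_mrna(seq, g.strand, pos, -3, SITE_CONTEXT, (fs, fe))
            if signal:
                _edit_mrna(seq, g.strand, pos, config.signal_offset,
                           config.signal_motif, (fs, fe))
            gene_sites.append(site)
        if not gene_sites:
            continue
        # usage proportions over this gene's sites, per condition
        alpha = np.array([4.0 if s.region_class == "UTR3" else 0.4
                          for s in gene_sites])
        if rng.random() < config.apa_gene_fraction:
            per_cond = {c: rng.dirichlet(alpha) for c in conditions}
        else:
            shared = rng.dirichlet(alpha)
            per_cond = {c: shared for c in conditions}
        for i, s in enumerate(gene_sites):
            s.usage_by_condition = {c: float(per_cond[c][i]) for c in conditions}
        gene_weights[g.gene_id] = float(rng.lognormal(0.0, 1.0))
        sites.extend(gene_sites)

    # organelle features: 1-2 sites each (3'-terminal and internal), no signal
    org_w_total = 0.0
    for f in annotation.features:
        seq = seqs[f.contig]
        flen = f.end - f.start
        offs = [4]                                     # transcript 3' end
        if flen >= 4 + spacing + 4:
            offs.append(4 + spacing + int(rng.integers(0, max(flen - spacing - 8, 1))))
            offs[1] = min(offs[1], flen - 5)
        f_sites = []
        for off in offs:
            pos = f.end - 1 - off if f.strand == "+" else f.start + off
            # off measured from transcript 3' terminus toward 5'
            site = new_site(f.feature_id, f.contig, f.strand, pos, "ORGANELLE", False)
            _edit_mrna(seq, f.strand, pos, -3, SITE_CONTEXT, (f.start, f.end))
            f_sites.append(site)
        u = rng.dirichlet(np.full(len(f_sites), 4.0))
        for i, s in enumerate(f_sites):
            s.usage_by_condition = {c: float(u[i]) for c in conditions}
        w = float(rng.lognormal(0.0, 1.0))
        gene_weights[f.feature_id] = w
        org_w_total += w
        sites.extend(f_sites)

    # rescale organelle weights to the configured read share
    nuc_total = sum(w for gid, w in gene_weights.items() if gid.startswith("g"))
    if org_w_total > 0 and nuc_total > 0 and config.organelle_read_fraction > 0:
        f = config.organelle_read_fraction
        scale = (nuc_total * f / (1.0 - f)) / org_w_total
        for fid in [x.feature_id for x in annotation.features]:
            if fid in gene_weights:
                gene_weights[fid] *= scale

    edited = {c: b.decode() for c, b in seqs.items()}
    return edited, SimTruth(sites=sites, gene_weights=gene_weights, config=config)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def make_barcodes(n: int, length: int, rng: np.random.Generator) -> List[str]:
    """n random barcodes with pairwise Hamming distance >= 2."""
    out: List[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 10000:
            raise ValueError("cannot generate barcode set; increase length")
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        if all(sum(a != b for a, b in zip(cand, bc)) >= 2 for bc in out):
            out.append(cand)
    return out


@dataclass
class SimResult:
    outdir: str
    genome: Dict[str, str]
    annotation: SynthAnnotation
    truth: SimTruth
    barcodes: Dict[str, str]               # library_id -> barcode
    fastq_paths: Dict[str, str]
    genome_path: str
    gff_path: str
    counts: pd.DataFrame                   # site x library drawn read counts
    expected: pd.DataFrame                 # site x library expected counts
    tail_stats: pd.DataFrame               # per library: tail bases / non-A


def simulate_reads(
    genome: Dict[str, str],
    truth: SimTruth,
    config: SimConfig,
    outdir: str,
) -> SimResult:
    """Simulate per-library FASTQ files plus truth tables (TSV)."""
    rng = np.random.default_rng([3, config.seed])
    os.makedirs(outdir, exist_ok=True)
    libs = config.libraries
    bcs = make_barcodes(len(libs), config.barcode_length, rng)
    barcodes = {lib.library_id: bc for lib, bc in zip(libs, bcs)}

    sites = truth.sites
    n_sites = len(sites)
    weights = {
        c: np.array([
            truth.gene_weights.get(s.gene_id, 0.0) * s.usage_by_condition.get(c, 0.0)
            for s in sites
        ])
        for c in config.conditions
    }
    # precompute, per site, the maximal templated mRNA suffix and its revcomp
    max_templ = config.read_length - config.barcode_length - config.tail_length_range[0]
    rc_full: List[str] = []
    for s in sites:
        seq = genome[s.contig]
        if s.strand == "+":
            seg = seq[max(0, s.position - max_templ + 1): s.position + 1]
        else:
            seg = revcomp(seq[s.position: s.position + max_templ])
        rc_full.append(revcomp(seg))    # prefix of this = read body for any length

    tlo, thi = config.tail_length_range
    alt = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    counts_mat = np.zeros((n_sites, len(libs)), dtype=int)
    expected_mat = np.zeros((n_sites, len(libs)))
    tail_rows = []
    fastq_paths = {}

    for li, lib in enumerate(libs):
        w = weights[lib.condition]
        total_w = w.sum()
        probs = w / total_w if total_w > 0 else None
        if lib.n_reads > 0 and probs is None:
            raise ValueError("no planted sites with positive weight")
        drawn = (rng.multinomial(lib.n_reads, probs)
                 if lib.n_reads > 0 else np.zeros(n_sites, dtype=int))
        counts_mat[:, li] = drawn
        if probs is not None:
            expected_mat[:, li] = probs * lib.n_reads
        bc = barcodes[lib.library_id]
        records = []
        serial = 0
        tail_bases = 0
        tail_non_a = 0
        for si in np.nonzero(drawn)[0]:
            s = sites[si]
            c = int(drawn[si])
            rate = (config.organelle_tail_non_a_rate
                    if s.contig == ORGANELLE_CONTIG else config.tail_non_a_rate)
            tail_lens = rng.integers(tlo, thi + 1, size=c)
            for L in tail_lens:
                L = int(L)
                if rate > 0:
                    flags = rng.random(L) < rate
                    tail = "".join(
                        alt["A"][int(rng.integers(3))] if f else "A" for f in flags
                    )
                    tail_non_a += int(flags.sum())
                else:
                    tail = "A" * L
                tail_bases += L
                templ_len = config.read_length - config.barcode_length - L
                body = rc_full[si][:templ_len]
                if config.error_rate > 0:
                    n_err = rng.binomial(len(body), config.error_rate)
                    if n_err:
                        b = list(body)
                        for pos in rng.choice(len(body), size=n_err, replace=False):
                            b[pos] = alt[b[pos]][int(rng.integers(3))]
                        body = "".join(b)
                serial += 1
                rid = f"{lib.library_id}.r{serial:06d}|{s.site_id}"
                read = bc + revcomp(tail) + body
                records.append((rid, read, "I" * len(read)))
        path = os.path.join(outdir, f"{lib.library_id}.fastq")
        write_fastq(path, records)
        fastq_paths[lib.library_id] = path
        tail_rows.append({
            "library_id": lib.library_id, "condition": lib.condition,
            "n_reads": int(drawn.sum()), "tail_bases": tail_bases,
            "tail_non_a": tail_non_a,
        })

    site_ids = [s.site_id for s in sites]
    lib_ids = [lib.library_id for lib in libs]
    counts = pd.DataFrame(counts_mat, index=site_ids, columns=lib_ids)
    expected = pd.DataFrame(expected_mat, index=site_ids, columns=lib_ids)
    tail_stats = pd.DataFrame(tail_rows)

    truth.sites_frame().to_csv(os.path.join(outdir, "truth_sites.tsv"),
                               sep="\t", index=False)
    counts.rename_axis("site_id").to_csv(
        os.path.join(outdir, "truth_site_counts.tsv"), sep="\t")
    tail_stats.to_csv(os.path.join(outdir, "truth_tail_stats.tsv"),
                      sep="\t", index=False)
    sheet = pd.DataFrame([
        {"library_id": lib.library_id, "condition": lib.condition,
         "replicate": lib.replicate, "barcode": barcodes[lib.library_id],
         "n_reads": lib.n_reads}
        for lib in libs
    ])
    sheet.to_csv(os.path.join(outdir, "libraries.tsv"), sep="\t", index=False)

    genome_path = os.path.join(outdir, "genome.fa")
    return SimResult(
        outdir=outdir, genome=genome, annotation=None, truth=truth,  # type: ignore
        barcodes=barcodes, fastq_paths=fastq_paths, genome_path=genome_path,
        gff_path=os.path.join(outdir, "annotation.gff3"),
        counts=counts, expected=expected, tail_stats=tail_stats,
    )


def simulate_experiment(config: SimConfig, outdir: str) -> SimResult:
    """Genome + planted sites + reads, written under ``outdir``."""
    genome, annotation = make_genome(config)
    genome, truth = plant_sites(genome, annotation, config)
    result = simulate_reads(genome, truth, config, outdir)
    result.annotation = annotation
    write_fasta(result.genome_path, genome)
    annotation.write(result.gff_path)
    return result


# ---------------------------------------------------------------------------
# stand-alone signal panel (for motif/composition analytics at scale)
# ---------------------------------------------------------------------------

def make_signal_panel(
    n_sites: int,
    fraction_with_signal: float,
    seed: int = 0,
    W: int = 80,
    motif: str = "TGTAA",
    offset: int = -15,
    spacing: int = 200,
) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Random genome with ``n_sites`` spaced sites; a fraction carry the
    signal motif planted at ``offset``. Returns (genome, site table)."""
    rng = np.random.default_rng([4, seed])
    length = n_sites * spacing + 2 * W + 400
    seq = bytearray(_random_seq(rng, length).tobytes())
    has_signal = np.zeros(n_sites, dtype=bool)
    has_signal[rng.permutation(n_sites)[: int(round(n_sites * fraction_with_signal))]] = True
    rows = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in range(n_sites):
        pos = 200 + W + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        if has_signal[i]:
            for k, b in enumerate(motif):
                g = pos + offset + k if strand == "+" else pos - offset - k
                seq[g] = ord(b if strand == "+" else comp[b])
        rows.append({"contig": "panel", "strand": strand, "position": pos,
                     "has_signal": bool(has_signal[i])})
    return {"panel": seq.decode()}, pd.DataFrame(rows)
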