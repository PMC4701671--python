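"""Genic classification of poly(A) sites and clusters.

Sites are tested against the union of a gene's transcript features with
precedence UTR3 > UTR3_EXT > CDS > UTR5 > INTRON, where UTR3_EXT is the
fixed-length region (25 nt) downstream of an annotated 3'UTR terminus in the
transcription direction. Genes on the same strand as the site are preferred
(SENSE); when multiple genes overlap the position within the chosen
orientation group the call is AMBIGUOUS; no overlap at all is UNANNOTATED.

Unannotated clusters can be linked to the nearest extended 3'UTR end on the
same strand within 100 bp downstream (putative 3'UTR extensions), and
per-feature tag abundance is computed for organellar-style contigs whose
annotation carries rRNA/tRNA/gene features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

UTR3 = "UTR3"
UTR3_EXT = "UTR3_EXT"
CDS = "CDS"
UTR5 = "UTR5"
INTRON = "INTRON"
AMBIGUOUS = "AMBIGUOUS"
UNANNOTATED = "UNANNOTATED"

SENSE = "SENSE"
ANTISENSE = "ANTISENSE"
NA = "NA"

_PRECEDENCE = {UTR3: 0, UTR3_EXT: 1, CDS: 2, UTR5: 3, INTRON: 4}


@dataclass
class RegionCall:
    region_class: str
    gene_id: Optional[str]
    orientation: str


@dataclass
class GeneRecord:
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    utr3_terminus: Optional[int] = None   # genomic coord of last transcribed base
    has_utrs: bool = True


class GeneAnnotation:
    """Interval lookup structures built from a GFF3 annotation."""

    def __init__(self, utr3_extension: int = 25):
        self.utr3_extension = utr3_extension
        self.genes: Dict[str, GeneRecord] = {}
        self._trees: Dict[str, IntervalTree] = {}       # genic features
        self._feature_trees: Dict[str, IntervalTree] = {}  # all typed features
        self.features: pd.DataFrame = pd.DataFrame(
            columns=["feature_id", "feature_type", "contig", "strand",
                     "start", "end"])

    # -- construction -------------------------------------------------------

    @classmethod
    def from_gff3(cls, source: str, utr3_extension: int = 25,
                  from_string: bool = False) -> "GeneAnnotation":
        """Load genes/transcripts from a GFF3 file (or literal text)."""
        self = cls(utr3_extension=utr3_extension)
        db = gffutils.create_db(
            source, dbfn=":memory:", from_string=from_string,
            merge_strategy="create_unique", keep_order=True,
        )
        feat_rows = []
        for gene in db.features_of_type("gene"):
            gid = gene.id
            contig, strand = gene.seqid, gene.strand
            g0, g1 = gene.start - 1, gene.end      # to 0-based half-open
            rec = GeneRecord(gene_id=gid, contig=contig, strand=strand,
                             start=g0, end=g1)
            utr5_iv: List[Tuple[int, int]] = []
            cds_iv: List[Tuple[int, int]] = []
            utr3_iv: List[Tuple[int, int]] = []
            intron_iv: List[Tuple[int, int]] = []
            transcripts = list(db.children(gene, featuretype="mRNA", level=1))
            containers = transcripts or [gene]
            for tx in containers:
                exons = sorted(
                    (f.start - 1, f.end)
                    for f in db.children(tx, featuretype="exon")
                )
                for a, b in zip(exons, exons[1:]):
                    if b[0] > a[1]:
                        intron_iv.append((a[1], b[0]))
                for f in db.children(tx, featuretype="five_prime_UTR"):
                    utr5_iv.append((f.start - 1, f.end))
                for f in db.children(tx, featuretype="CDS"):
                    cds_iv.append((f.start - 1, f.end))
                for f in db.children(tx, featuretype="three_prime_UTR"):
                    utr3_iv.append((f.start - 1, f.end))
            if not utr3_iv and not utr5_iv:
                rec.has_utrs = False
                if cds_iv or intron_iv:
                    logger.warning(
                        "gene %s has no UTR features; classifying via CDS/INTRON only",
                        gid,
                    )
            tree = self._trees.setdefault(contig, IntervalTree())
            for kind, ivs in ((UTR5, utr5_iv), (CDS, cds_iv), (UTR3, utr3_iv),
                              (INTRON, intron_iv)):
                for s, e in ivs:
                    if e > s:
                        tree.addi(s, e, (kind, gid, strand))
            if utr3_iv:
                if strand == "+":
                    term = max(e for _s, e in utr3_iv) - 1
                    ext = (term + 1, term + 1 + utr3_extension)
                else:
                    term = min(s for s, _e in utr3_iv)
                    ext = (term - utr3_extension, term)
                rec.utr3_terminus = term
                if ext[1] > ext[0]:
                    tree.addi(max(ext[0], 0), ext[1], (UTR3_EXT, gid, strand))
            self.genes[gid] = rec

        # all typed features (for organellar per-feature abundance)
        for f in db.all_features():
            if f.featuretype in ("exon", "mRNA", "five_prime_UTR",
                                 "three_prime_UTR", "intron"):
                continue
            fid = f.id
            feat_rows.append({
                "feature_id": fid, "feature_type": f.featuretype,
                "contig": f.seqid, "strand": f.strand,
                "start": f.start - 1, "end": f.end,
            })
            tree = self._feature_trees.setdefault(f.seqid, IntervalTree())
            tree.addi(f.start - 1, f.end, (fid, f.featuretype))
        self.features = pd.DataFrame(feat_rows)
        return self

    # -- classification -----------------------------------------------------

    def classify_site(self, contig: str, strand: str, position: int) -> RegionCall:
        """Classify one single-base site against the gene annotation."""
        tree = self._trees.get(contig)
        hits = tree[position] if tree is not None else set()
        per_gene: Dict[str, Tuple[int, str, str]] = {}
        for iv in hits:
            kind, gid, gstrand = iv.data
            rank = _PRECEDENCE[kind]
            cur = per_gene.get(gid)
            if cur is None or rank < cur[0]:
                per_gene[gid] = (rank, kind, gstrand)
        if not per_gene:
            return RegionCall(UNANNOTATED, None, NA)
        sense = {g: v for g, v in per_gene.items() if v[2] == strand}
        group = sense if sense else per_gene
        orientation = SENSE if sense else ANTISENSE
        if len(group) > 1:
            gene_ids = ",".join(sorted(group))
            return RegionCall(AMBIGUOUS, gene_ids, orientation)
        gid, (_rank, kind, _gs) = next(iter(group.items()))
        return RegionCall(kind, gid, orientation)

    def classify_table(self, sites: pd.DataFrame) -> pd.DataFrame:
        """Vector interface: adds region_class / gene_id / orientation columns."""
        calls = [
            self.classify_site(c, s, int(p))
            for c, s, p in zip(sites["contig"], sites["strand"], sites["position"])
        ]
        out = sites.copy()
        out["region_class"] = [c.region_class for c in calls]
        out["gene_id"] = [c.gene_id for c in calls]
        out["orientation"] = [c.orientation for c in calls]
        return out

    # -- linkage of unannotated clusters ------------------------------------

    def link_unannotated(
        self, contig: str, strand: str, position: int,
        max_dist: int = 100,
    ) -> Optional[Tuple[str, int]]:
        """Nearest extended-3'UTR end, same strand, within ``max_dist`` bp
        downstream of the UTR terminus. Returns (gene_id, distance) or None."""
        best: Optional[Tuple[str, int]] = None
        for rec in self.genes.values():
            if rec.contig != contig or rec.strand != strand:
                continue
            if rec.utr3_terminus is None:
                continue
            if strand == "+":
                ext_last = rec.utr3_terminus + self.utr3_extension
                d = position - ext_last
            else:
                ext_first = rec.utr3_terminus - self.utr3_extension
                d = ext_first - position
            if 1 <= d <= max_dist and (best is None or d < best[1]):
                best = (rec.gene_id, d)
        return best

    # -- per-feature abundance ----------------------------------------------

    def feature_abundance(
        self,
        pas: pd.DataFrame,
        contigs: Optional[Sequence[str]] = None,
    ) -> pd.DataFrame:
        """Add each PAS's per-library counts to every feature overlapping it.

        A PAS inside nested features counts toward each (totals are
        per-feature, not additive across nesting); sites outside all features
        go to a per-contig ``intergenic`` row.
        """
        lib_cols = [c for c in pas.columns
                    if c not in ("contig", "strand", "position", "total")]
        rows: Dict[Tuple[str, str, str], Dict[str, int]] = {}
        for _, site in pas.iterrows():
            contig = site["contig"]
            if contigs is not None and contig not in contigs:
                continue
            tree = self._feature_trees.get(contig)
            hits = tree[int(site["position"])] if tree is not None else set()
            keys = ([(contig, fid, ftype) for iv in hits
                     for fid, ftype in [iv.data]]
                    or [(contig, "intergenic", "intergenic")])
            for key in keys:
                acc = rows.setdefault(key, {c: 0 for c in lib_cols})
                for c in lib_cols:
                    acc[c] += int(site[c])
        out_rows = []
        for (contig, fid, ftype), acc in sorted(rows.items()):
            row = {"contig": contig, "feature_id": fid, "feature_type": ftype}
            row.update(acc)
            row["total"] = sum(acc.values())
            out_rows.append(row)
        return pd.DataFrame(out_rows)
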