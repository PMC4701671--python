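"""Shared fixtures: simulated experiments and a hand-built GFF3 annotation."""

from __future__ import annotations

import pytest

import patseq as ps


@pytest.fixture(scope="session")
def clean_cfg():
    """Small error-free experiment config (10 genes, 12 x 500 reads)."""
    return ps.SimConfig(
        seed=1, n_genes=10, libraries=ps.default_libraries(500),
        error_rate=0.0, tail_non_a_rate=0.0, organelle_tail_non_a_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_cfg, tmp_path_factory):
    return ps.simulate_experiment(clean_cfg, str(tmp_path_factory.mktemp("clean_sim")))


@pytest.fixture(scope="session")
def clean_run(clean_sim):
    return ps.run_pipeline_fastq(
        clean_sim.fastq_paths.values(), clean_sim.barcodes, clean_sim.genome)


def _full_libraries(total_reads: int):
    base = total_reads // 12
    libs = ps.default_libraries(base)
    extra = total_reads - base * 12
    first = libs[0]
    libs[0] = ps.LibrarySpec(first.library_id, first.condition,
                             first.replicate, base + extra)
    return libs


@pytest.fixture(scope="session")
def full_sim(tmp_path_factory):
    """50-gene genome, 12 libraries, 200,000 error-free reads."""
    cfg = ps.SimConfig(
        seed=7, n_genes=50, libraries=_full_libraries(200_000),
        error_rate=0.0, tail_non_a_rate=0.0, organelle_tail_non_a_rate=0.0,
    )
    return ps.simulate_experiment(cfg, str(tmp_path_factory.mktemp("full_sim")))


@pytest.fixture(scope="session")
def full_run(full_sim):
    return ps.run_pipeline_fastq(
        full_sim.fastq_paths.values(), full_sim.barcodes, full_sim.genome)


@pytest.fixture(scope="session")
def tail_sim(tmp_path_factory):
    """~2,000 reads with heteropolymeric tails at per-base rate 0.05."""
    cfg = ps.SimConfig(
        seed=11, n_genes=20, libraries=ps.default_libraries(167),
        error_rate=0.0, tail_non_a_rate=0.05, organelle_tail_non_a_rate=0.05,
    )
    return ps.simulate_experiment(cfg, str(tmp_path_factory.mktemp("tail_sim")))


@pytest.fixture(scope="session")
def tail_run(tail_sim):
    return ps.run_pipeline_fastq(
        tail_sim.fastq_paths.values(), tail_sim.barcodes, tail_sim.genome)


def _gff_line(contig, ftype, start, end, strand, attrs):
    # 0-based half-open -> 1-based inclusive
    return "\t".join([contig, "test", ftype, str(start + 1), str(end),
                      ".", strand, ".", attrs])


def _gene(contig, gid, strand, span, exons, utr5, cds, utr3):
    tid = f"{gid}.t"
    lines = [_gff_line(contig, "gene", *span, strand, f"ID={gid}"),
             _gff_line(contig, "mRNA", *span, strand, f"ID={tid};Parent={gid}")]
    for i, iv in enumerate(exons, 1):
        lines.append(_gff_line(contig, "exon", *iv, strand,
                               f"ID={tid}.e{i};Parent={tid}"))
    for iv in utr5:
        lines.append(_gff_line(contig, "five_prime_UTR", *iv, strand,
                               f"ID={tid}.u5;Parent={tid}"))
    for iv in cds:
        lines.append(_gff_line(contig, "CDS", *iv, strand,
                               f"ID={tid}.c;Parent={tid}"))
    for iv in utr3:
        lines.append(_gff_line(contig, "three_prime_UTR", *iv, strand,
                               f"ID={tid}.u3;Parent={tid}"))
    return lines


@pytest.fixture(scope="session")
def fixture_gff():
    """Hand-built annotation exercising every classification case.

    geneA (+) [100,700): UTR5 [100,200), CDS [200,350)+[400,550),
        intron [350,400), UTR3 [550,700) -> extension covers 700..724.
    geneB (-) [800,1400): UTR3 [800,950), CDS [950,1250), UTR5 [1250,1400).
    geneC (+) [2000,2600) / geneD (+) [2500,3100): same-strand overlap,
        C.UTR3 [2400,2600) against D.UTR5 [2500,2650).
    geneE (+) [4000,4600): UTR3 [4400,4600) -> linkage window 4625..4724.
    geneF (-) [5000,5600): UTR3 [5000,5150) -> extension covers 4975..4999.
    geneG (+) [6000,6300): CDS only (no UTR features).
    geneH (+) [7000,7550) and geneI (+) [7700,8300): upstream-gene proximity
        (H 3'UTR terminus 7549; I 5'UTR [7700,7800)).
    """
    L = ["##gff-version 3"]
    L += _gene("t1", "geneA", "+", (100, 700),
               exons=[(100, 350), (400, 700)],
               utr5=[(100, 200)], cds=[(200, 350), (400, 550)],
               utr3=[(550, 700)])
    L += _gene("t1", "geneB", "-", (800, 1400),
               exons=[(800, 1400)],
               utr5=[(1250, 1400)], cds=[(950, 1250)], utr3=[(800, 950)])
    L += _gene("t1", "geneC", "+", (2000, 2600),
               exons=[(2000, 2600)],
               utr5=[(2000, 2100)], cds=[(2100, 2400)], utr3=[(2400, 2600)])
    L += _gene("t1", "geneD", "+", (2500, 3100),
               exons=[(2500, 3100)],
               utr5=[(2500, 2650)], cds=[(2650, 2900)], utr3=[(2900, 3100)])
    L += _gene("t1", "geneE", "+", (4000, 4600),
               exons=[(4000, 4600)],
               utr5=[(4000, 4100)], cds=[(4100, 4400)], utr3=[(4400, 4600)])
    L += _gene("t1", "geneF", "-", (5000, 5600),
               exons=[(5000, 5600)],
               utr5=[(5450, 5600)], cds=[(5150, 5450)], utr3=[(5000, 5150)])
    L += _gene("t1", "geneG", "+", (6000, 6300),
               exons=[(6000, 6300)], utr5=[], cds=[(6000, 6300)], utr3=[])
    L += _gene("t1", "geneH", "+", (7000, 7550),
               exons=[(7000, 7550)],
               utr5=[(7000, 7100)], cds=[(7100, 7350)], utr3=[(7350, 7550)])
    L += _gene("t1", "geneI", "+", (7700, 8300),
               exons=[(7700, 8300)],
               utr5=[(7700, 7800)], cds=[(7800, 8100)], utr3=[(8100, 8300)])
    return "\n".join(L) + "\n"


@pytest.fixture(scope="session")
def fixture_ann(fixture_gff):
    return ps.GeneAnnotation.from_gff3(fixture_gff, from_string=True)
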