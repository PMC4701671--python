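"""Shared sequence and file helpers (FASTA/FASTQ, complements, Hamming)."""

from __future__ import annotations

import os
from typing import Dict, Iterable, Iterator, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from pyfaidx import Fasta

_COMP = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA; U treated as T)."""
    return seq.translate(_COMP)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def to_rna(seq: str) -> str:
    """DNA -> RNA alphabet for display (T->U)."""
    return seq.replace("T", "U").replace("t", "u")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def write_fasta(path: str, seqs: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> Dict[str, str]:
    fa = Fasta(path, as_raw=True, rebuild=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    # drop the .fai side file created by pyfaidx; callers expect plain inputs
    try:
        os.remove(path + ".fai")
    except OSError:
        pass
    return out


def iter_fastq(path: str) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) from a plain-text FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(path: str, records: Iterable[Tuple[str, str, str]]) -> int:
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
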