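"""Sequence analytics around cleavage sites.

Windows of +/-W nt (W = 80 by default) are extracted in transcript sense
around each single-base cleavage site (offset 0 = the site itself; negative
offsets upstream). From these the module computes position-by-position base
composition, exhaustive positional k-mer (5-mer) motif profiles, and a
per-site classification of the UGUAA polyadenylation signal: exact or
1-mismatch occurrences with start offsets in the -20..-10 window, matches
outside the window, and 2-mismatch variants, with the first matching class
winning. Motifs are reported in the RNA alphabet; computation is on DNA.
The downstream half of the window is genomic sequence (the poly(A) tail is
untemplated and never part of the window).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import product
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sequtil import revcomp, to_rna


class SignalClass(str, Enum):
    EXACT_IN_WINDOW = "EXACT_IN_WINDOW"
    ONE_MM_IN_WINDOW = "ONE_MM_IN_WINDOW"
    OUT_OF_WINDOW_LE1MM = "OUT_OF_WINDOW_LE1MM"
    TWO_MM_IN_WINDOW = "TWO_MM_IN_WINDOW"
    NONE = "NONE"


#: classes counted as "signal in window" (exact or single substitution)
IN_WINDOW_ANY = (SignalClass.EXACT_IN_WINDOW, SignalClass.ONE_MM_IN_WINDOW)


def extract_window(
    genome: Mapping[str, str],
    contig: str,
    strand: str,
    position: int,
    W: int = 80,
) -> Optional[str]:
    """2W+1 nt of genomic sequence centred on the site, transcript sense.

    Minus-strand windows are reverse complemented so negative offsets are
    always upstream in the mRNA. Sites within W of a contig end return None.
    """
    seq = genome[contig]
    if position - W < 0 or position + W + 1 > len(seq):
        return None
    win = seq[position - W: position + W + 1]
    return win if strand == "+" else revcomp(win)


def extract_windows(
    sites: pd.DataFrame,
    genome: Mapping[str, str],
    W: int = 80,
) -> Tuple[List[str], int]:
    """Windows for a site table; returns (usable windows, n_excluded)."""
    wins: List[str] = []
    excluded = 0
    for contig, strand, pos in zip(sites["contig"], sites["strand"],
                                   sites["position"]):
        w = extract_window(genome, contig, strand, int(pos), W)
        if w is None:
            excluded += 1
        else:
            wins.append(w)
    return wins, excluded


@dataclass
class CompositionProfile:
    offsets: np.ndarray            # -W .. +W
    fractions: pd.DataFrame        # offset x (A, C, G, U)
    n_sites: int


def composition_profile(windows: Sequence[str], W: int = 80) -> CompositionProfile:
    """Fractional nucleotide content at each offset over usable sites."""
    if not windows:
        raise ValueError("no usable sites for composition profile")
    L = 2 * W + 1
    if any(len(w) != L for w in windows):
        raise ValueError("all windows must have length 2W+1")
    arr = np.frombuffer("".join(windows).encode(), dtype="S1").reshape(len(windows), L)
    offsets = np.arange(-W, W + 1)
    data = {
        rna: (arr == dna.encode()).mean(axis=0)
        for dna, rna in (("A", "A"), ("C", "C"), ("G", "G"), ("T", "U"))
    }
    frame = pd.DataFrame(data, index=pd.Index(offsets, name="offset"))
    return CompositionProfile(offsets=offsets, fractions=frame,
                              n_sites=len(windows))


@dataclass
class MotifProfile:
    k: int
    W: int
    counts: pd.DataFrame           # motif (RNA) x start offset
    ranking: List[str]             # motifs by total count desc, ties lexicographic
    n_sites: int

    def top(self, n: int) -> pd.DataFrame:
        return self.counts.loc[self.ranking[:n]]


def motif_profile(
    windows: Sequence[str],
    k: int = 5,
    W: int = 80,
    top_n: Optional[int] = None,
) -> MotifProfile:
    """Tally the k-mer starting at every offset of every usable window.

    Start offsets run from -W to W-k+1 (each window position contributes
    exactly one k-mer), so column sums all equal the number of usable sites.
    """
    offsets = list(range(-W, W - k + 2))
    counts: Dict[str, np.ndarray] = {}
    n_off = len(offsets)
    for win in windows:
        if len(win) != 2 * W + 1:
            raise ValueError("all windows must have length 2W+1")
        for j in range(n_off):
            kmer = win[j: j + k]
            row = counts.get(kmer)
            if row is None:
                row = counts[kmer] = np.zeros(n_off, dtype=int)
            row[j] += 1
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=offsets)
    frame.index = [to_rna(m) for m in frame.index]
    frame.index.name = "motif"
    frame.columns.name = "offset"
    totals = frame.sum(axis=1)
    order = sorted(frame.index, key=lambda m: (-totals[m], m))
    if top_n is not None:
        frame = frame.loc[order[:top_n]]
    return MotifProfile(k=k, W=W, counts=frame, ranking=order,
                        n_sites=len(windows))


def classify_signal(
    window: str,
    motif: str = "TGTAA",
    signal_window: Tuple[int, int] = (-20, -10),
    W: int = 80,
) -> SignalClass:
    """Classify the best signal-motif occurrence fully upstream of the site.

    Candidate start offsets s satisfy s + k <= 0 (motif entirely upstream);
    in-window means signal_window[0] <= s <= signal_window[1]. The first
    matching class in the precedence order wins.
    """
    k = len(motif)
    lo, hi = signal_window
    exact_in = onemm_in = out_le1 = twomm_in = False
    for s in range(-W, -k + 1):
        j = s + W
        mm = sum(a != b for a, b in zip(window[j: j + k], motif))
        in_win = lo <= s <= hi
        if in_win:
            if mm == 0:
                exact_in = True
            elif mm == 1:
                onemm_in = True
            elif mm == 2:
                twomm_in = True
        elif mm <= 1:
            out_le1 = True
    if exact_in:
        return SignalClass.EXACT_IN_WINDOW
    if onemm_in:
        return SignalClass.ONE_MM_IN_WINDOW
    if out_le1:
        return SignalClass.OUT_OF_WINDOW_LE1MM
    if twomm_in:
        return SignalClass.TWO_MM_IN_WINDOW
    return SignalClass.NONE


def signal_summary(
    classes_by_group: Mapping[str, Sequence[SignalClass]],
) -> pd.DataFrame:
    """Per-group fractions of each signal class (groups = genic regions).

    Fractions sum to 1 within each group; empty groups are omitted (reported
    with n = 0 by the caller if needed).
    """
    rows = []
    for group, classes in classes_by_group.items():
        if not classes:
            continue
        n = len(classes)
        row = {"group": group, "n": n}
        for sc in SignalClass:
            row[sc.value] = sum(1 for c in classes if c is sc) / n
        row["IN_WINDOW_ANY"] = sum(
            1 for c in classes if c in IN_WINDOW_ANY
        ) / n
        rows.append(row)
    return pd.DataFrame(rows)
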