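"""Poly(A) site (PAS) aggregation and cluster (PAC) chaining.

Reduced one-base coordinates are aggregated into PAS with per-library tag
counts. Sites are chained into poly(A) site clusters (PACs) by single
linkage: on each (contig, strand), a new cluster starts whenever the gap to
the previous site exceeds ``max_gap`` (24 nt, inclusive at 24). Clustering
runs on the *unfiltered* PAS set; clusters supported by fewer than
``min_pac_tags`` PATs are then removed. The individually filtered PAS table
(>= ``min_pas_tags`` tags) is kept separately for per-site analytics.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

KEY = ["contig", "strand", "position"]


def call_pas(
    site_rows: Iterable[Tuple[str, str, int, str]],
    min_pas_tags: int = 10,
    libraries: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate reduced coordinates into PAS tables.

    ``site_rows`` are (contig, mrna_strand, position, library) tuples, one per
    mapped tag (or a DataFrame with those columns and an optional ``count``).
    Returns (filtered, unfiltered) tables: one row per distinct
    (contig, strand, position) with per-library counts and ``total``; the
    filtered table keeps ``total >= min_pas_tags``.
    """
    if isinstance(site_rows, pd.DataFrame):
        df = site_rows.copy()
        if "count" not in df.columns:
            df["count"] = 1
    else:
        df = pd.DataFrame(list(site_rows),
                          columns=["contig", "strand", "position", "library"])
        df["count"] = 1
    if df.empty:
        cols = KEY + list(libraries or []) + ["total"]
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    wide = (
        df.pivot_table(index=KEY, columns="library", values="count",
                       aggfunc="sum", fill_value=0)
          .astype(int)
    )
    if libraries is not None:
        wide = wide.reindex(columns=list(libraries), fill_value=0)
    wide.columns.name = None
    wide["total"] = wide.drop(columns=["total"], errors="ignore").sum(axis=1)
    unfiltered = wide.reset_index().sort_values(KEY).reset_index(drop=True)
    filtered = unfiltered[unfiltered["total"] >= min_pas_tags].reset_index(drop=True)
    return filtered, unfiltered


def cluster_pacs(
    unfiltered_pas: pd.DataFrame,
    max_gap: int = 24,
    min_pac_tags: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Chain PAS into PACs and filter on total PAT support.

    Returns (pacs, members, dropped): ``pacs`` holds kept clusters with span,
    representative site (highest-count member, ties to the smallest
    position), per-library count sums and ``total``; ``members`` maps every
    PAS to its cluster id; ``dropped`` lists removed (< ``min_pac_tags``)
    clusters so totals reconcile.
    """
    lib_cols = [c for c in unfiltered_pas.columns if c not in KEY + ["total"]]
    if unfiltered_pas.empty:
        cols = ["pac_id", "contig", "strand", "start", "end", "n_members",
                "representative"] + lib_cols + ["total"]
        empty = pd.DataFrame(columns=cols)
        members = unfiltered_pas.copy()
        members["pac_id"] = pd.Series(dtype=str)
        return empty, members, empty.copy()
    df = unfiltered_pas.sort_values(KEY).reset_index(drop=True)
    cluster_ids = np.zeros(len(df), dtype=int)
    cid = -1
    prev_key: Optional[Tuple[str, str]] = None
    prev_pos = 0
    for i, (contig, strand, pos) in enumerate(
        zip(df["contig"], df["strand"], df["position"])
    ):
        if (contig, strand) != prev_key or pos - prev_pos > max_gap:
            cid += 1
        cluster_ids[i] = cid
        prev_key = (contig, strand)
        prev_pos = pos
    df["_cid"] = cluster_ids

    rows = []
    for c, grp in df.groupby("_cid", sort=True):
        # representative: max total, tie -> smallest position (grp is sorted)
        rep = grp.loc[grp["total"].idxmax(), "position"]
        best = grp["total"].max()
        rep = int(grp.loc[grp["total"] == best, "position"].min())
        row = {
            "_cid": c,
            "contig": grp["contig"].iloc[0],
            "strand": grp["strand"].iloc[0],
            "start": int(grp["position"].min()),
            "end": int(grp["position"].max()) + 1,
            "n_members": len(grp),
            "representative": rep,
        }
        for lc in lib_cols:
            row[lc] = int(grp[lc].sum())
        row["total"] = int(grp["total"].sum())
        rows.append(row)
    pacs = pd.DataFrame(rows)
    pacs["pac_id"] = [f"PAC{int(c) + 1:06d}" for c in pacs["_cid"]]
    members = df.merge(pacs[["_cid", "pac_id"]], on="_cid").drop(columns="_cid")
    keep = pacs["total"] >= min_pac_tags
    order = ["pac_id", "contig", "strand", "start", "end", "n_members",
             "representative"] + lib_cols + ["total"]
    kept = pacs[keep][order].reset_index(drop=True)
    dropped = pacs[~keep][order].reset_index(drop=True)
    return kept, members, dropped


def per_gene_pac_histogram(gene_ids: Iterable[str]) -> pd.Series:
    """Distribution of genes by PAC count, binned 1,2,3,4,5,>5.

    ``gene_ids`` holds one entry per PAC (its assigned gene); genes with no
    PAC do not appear. Fractions sum to 1 (empty input -> empty histogram).
    """
    counts = pd.Series(list(gene_ids)).value_counts()
    if counts.empty:
        return pd.Series(dtype=float)
    bins = ["1", "2", "3", "4", "5", ">5"]
    binned = counts.map(lambda n: str(n) if n <= 5 else ">5")
    hist = binned.value_counts().reindex(bins, fill_value=0)
    return hist / hist.sum()
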