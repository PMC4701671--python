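"""Expression normalization and differential tests.

Expression is normalized to tags per million (tpm): each gene's tag count is
divided by the library total and scaled by 1e6, so every library column sums
to one million.

Differential expression across growth conditions uses a self-contained
overdispersed count test: counts are modeled with a negative-binomial-style
variance ``m + alpha * m**2`` whose dispersion ``alpha`` is estimated once by
method of moments across all genes (shared dispersion), and each condition
pair is compared with a two-sided Wald test of equal relative abundance on
the pooled per-condition proportions. Benjamini-Hochberg FDR is applied per
condition pair (Bonferroni also reported).

Differential poly(A) site (PAC) usage uses a replicate-aware proportion
test: per (PAC, condition pair), member tags vs (gene total - member tags)
are modeled beta-binomially with an intraclass correlation ``rho`` estimated
once by method of moments across all PACs and held fixed while the
proportions are profiled, giving a 1-df likelihood-ratio test (binomial when
``rho`` degenerates to 0). BH-FDR is applied across all (PAC, pair)
hypotheses.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests


@dataclass
class ExpressionTable:
    counts: pd.DataFrame      # gene x library
    tpm: pd.DataFrame         # gene x library, columns sum to 1e6


def tpm_normalize(counts: pd.DataFrame) -> ExpressionTable:
    """Tags per million: tpm[g, l] = counts[g, l] / library_total[l] * 1e6."""
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"zero-total libraries: {bad}")
    return ExpressionTable(counts=counts, tpm=counts / totals * 1e6)


def _pairs(conditions: Sequence[str]) -> List[Tuple[str, str]]:
    return list(combinations(conditions, 2))


def _design_groups(design: Mapping[str, str],
                   libraries: Sequence[str]) -> Dict[str, List[str]]:
    groups: Dict[str, List[str]] = {}
    for lib in libraries:
        try:
            groups.setdefault(design[lib], []).append(lib)
        except KeyError:
            raise ValueError(f"library {lib!r} missing from design") from None
    return groups


# ---------------------------------------------------------------------------
# differential gene expression
# ---------------------------------------------------------------------------

def estimate_nb_dispersion(counts: pd.DataFrame,
                           groups: Mapping[str, Sequence[str]]) -> float:
    """Shared NB dispersion alpha via method of moments on within-condition
    residuals around fitted proportional means (var = m + alpha m^2)."""
    N = counts.sum(axis=0)
    num = 0.0
    den = 0.0
    for cond, libs in groups.items():
        y = counts[list(libs)].to_numpy(float)
        n = N[list(libs)].to_numpy(float)
        p = y.sum(axis=1, keepdims=True) / n.sum()
        m = p * n
        r2 = (y - m) ** 2
        num += float((r2 - m).sum())
        den += float((m ** 2).sum())
    return max(0.0, num / den) if den > 0 else 0.0


def test_gene_de(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    min_total: int = 5,
) -> pd.DataFrame:
    """Per-gene, per-condition-pair overdispersed Wald test with BH-FDR.

    Returns a long table (gene, pair, log2_fc, p_value, fdr_q, bonferroni_p);
    a gene is differentially expressed "in at least one" pair when any
    pair's q <= alpha (see :func:`de_genes`). Genes below the total-count
    floor are excluded before testing.
    """
    groups = _design_groups(design, counts.columns)
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    for cond, libs in groups.items():
        if len(libs) < 2:
            raise ValueError(f"condition {cond!r} has <2 replicates; "
                             "no dispersion estimate possible")
    N = counts.sum(axis=0)
    keep = counts.sum(axis=1) >= min_total
    Y = counts.loc[keep]
    disp = estimate_nb_dispersion(Y, groups)

    frames = []
    for c1, c2 in _pairs(list(groups)):
        l1, l2 = groups[c1], groups[c2]
        y1 = Y[l1].to_numpy(float)
        y2 = Y[l2].to_numpy(float)
        n1 = N[l1].to_numpy(float)
        n2 = N[l2].to_numpy(float)
        s1, s2 = y1.sum(axis=1), y2.sum(axis=1)
        N1, N2 = n1.sum(), n2.sum()
        p1, p2 = s1 / N1, s2 / N2
        m1 = p1[:, None] * n1[None, :]
        m2 = p2[:, None] * n2[None, :]
        v1 = (m1 + disp * m1 ** 2).sum(axis=1) / N1 ** 2
        v2 = (m2 + disp * m2 ** 2).sum(axis=1) / N2 ** 2
        se = np.sqrt(v1 + v2)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), 0.0)
        pvals = 2.0 * norm.sf(np.abs(z))
        lfc = np.log2(((s1 + 0.5) / (N1 + 1.0)) / ((s2 + 0.5) / (N2 + 1.0)))
        q = multipletests(pvals, method="fdr_bh")[1]
        bonf = np.minimum(pvals * len(pvals), 1.0)
        frames.append(pd.DataFrame({
            "gene_id": Y.index, "condition_1": c1, "condition_2": c2,
            "log2_fc": lfc, "p_value": pvals, "fdr_q": q, "bonferroni_p": bonf,
        }))
    return pd.concat(frames, ignore_index=True)


def de_genes(results: pd.DataFrame, alpha: float = 0.05) -> List[str]:
    """Genes with q <= alpha in at least one condition pair."""
    hit = results[results["fdr_q"] <= alpha]
    return sorted(hit["gene_id"].unique())


# ---------------------------------------------------------------------------
# differential PAC usage
# ---------------------------------------------------------------------------

def estimate_icc(ks: Sequence[np.ndarray], ns: Sequence[np.ndarray]) -> float:
    """Pooled method-of-moments intraclass correlation for proportions.

    ``ks``/``ns`` are matched lists of replicate vectors (successes, totals)
    for many (unit, condition) cells; rho is pooled over all cells.
    """
    num = 0.0
    den = 0.0
    for k, n in zip(ks, ns):
        k = np.asarray(k, float)
        n = np.asarray(n, float)
        ok = n > 0
        k, n = k[ok], n[ok]
        if len(n) < 2:
            continue
        ntot = n.sum()
        p = k.sum() / ntot
        if p <= 0 or p >= 1:
            continue
        pq = p * (1 - p)
        resid = ((k - n * p) ** 2 / pq).sum()
        # expectations under binomial/beta-binomial with plug-in p
        e_binom = n.sum() - (n ** 2).sum() / ntot
        c_rho = (n * (n - 1)).sum() - (n ** 2 * (n - 1)).sum() / ntot
        num += resid - e_binom
        den += c_rho
    return float(np.clip(num / den, 0.0, 0.95)) if den > 0 else 0.0


def _bb_loglik(k: np.ndarray, n: np.ndarray, p: float, rho: float) -> float:
    k = np.asarray(k, float)
    n = np.asarray(n, float)
    if rho <= 0:
        lp = np.log(np.maximum(p, 1e-300))
        lq = np.log(np.maximum(1.0 - p, 1e-300))
        ll = np.where(k > 0, k * lp, 0.0) + np.where(n - k > 0, (n - k) * lq, 0.0)
        return float(np.sum(ll))
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return float(np.sum(betaln(k + a, n - k + b) - betaln(a, b)))


def _profile_p(k: np.ndarray, n: np.ndarray, rho: float) -> float:
    """Maximized beta-binomial log likelihood over the proportion p."""
    ksum, nsum = float(np.sum(k)), float(np.sum(n))
    if nsum == 0:
        return 0.0
    if rho <= 0:
        p = ksum / nsum
        return _bb_loglik(k, n, p, 0.0)
    res = minimize_scalar(
        lambda p: -_bb_loglik(k, n, p, rho),
        bounds=(1e-9, 1 - 1e-9), method="bounded",
        options={"xatol": 1e-8},
    )
    return -float(res.fun)


def test_pac_usage(
    pac_counts: pd.DataFrame,
    pac_gene: Mapping[str, str],
    design: Mapping[str, str],
    alpha: float = 0.05,
    min_gene_total: int = 5,
    rho: Optional[float] = None,
) -> pd.DataFrame:
    """Beta-binomial likelihood-ratio test of PAC usage per condition pair.

    ``pac_counts`` is PAC x library; ``pac_gene`` maps each PAC to its gene.
    Only PACs of genes with >= 2 PACs and a total-count floor are tested;
    pairs where a condition's gene total is zero are skipped (recorded with
    ``skipped=True``). Usage = PAC tags / gene tags; BH-FDR over all tested
    (PAC, pair) hypotheses.
    """
    libs = list(pac_counts.columns)
    groups = _design_groups(design, libs)
    genes = pd.Series({p: pac_gene[p] for p in pac_counts.index})
    gene_tot = pac_counts.groupby(genes).transform("sum")
    n_pacs = genes.map(genes.value_counts())
    eligible = (n_pacs >= 2) & (gene_tot.sum(axis=1) >= min_gene_total)
    tested = pac_counts.index[eligible]

    if rho is None:
        ks, ns = [], []
        for pac in tested:
            for cond, cl in groups.items():
                ks.append(pac_counts.loc[pac, cl].to_numpy(float))
                ns.append(gene_tot.loc[pac, cl].to_numpy(float))
        rho = estimate_icc(ks, ns)

    rows = []
    for pac in tested:
        gene = genes[pac]
        for c1, c2 in _pairs(list(groups)):
            l1, l2 = groups[c1], groups[c2]
            k1 = pac_counts.loc[pac, l1].to_numpy(float)
            k2 = pac_counts.loc[pac, l2].to_numpy(float)
            n1 = gene_tot.loc[pac, l1].to_numpy(float)
            n2 = gene_tot.loc[pac, l2].to_numpy(float)
            row = {"pac_id": pac, "gene_id": gene,
                   "condition_1": c1, "condition_2": c2}
            if n1.sum() == 0 or n2.sum() == 0:
                row.update({"usage_1": np.nan, "usage_2": np.nan,
                            "log2_usage_ratio": np.nan, "p_value": np.nan,
                            "skipped": True})
                rows.append(row)
                continue
            ll_null = _profile_p(np.concatenate([k1, k2]),
                                 np.concatenate([n1, n2]), rho)
            ll_alt = _profile_p(k1, n1, rho) + _profile_p(k2, n2, rho)
            lrt = max(0.0, 2.0 * (ll_alt - ll_null))
            u1 = k1.sum() / n1.sum()
            u2 = k2.sum() / n2.sum()
            ratio = (((k1.sum() + 0.5) / (n1.sum() + 0.5))
                     / ((k2.sum() + 0.5) / (n2.sum() + 0.5)))
            row.update({
                "usage_1": u1, "usage_2": u2,
                "log2_usage_ratio": float(np.log2(ratio)),
                "p_value": float(chi2.sf(lrt, 1)), "skipped": False,
            })
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        for c in ("fdr_q", "bonferroni_p", "significant"):
            out[c] = pd.Series(dtype=float)
        out.attrs["rho"] = rho
        return out
    ok = ~out["skipped"]
    out["fdr_q"] = np.nan
    out["bonferroni_p"] = np.nan
    if ok.any():
        p = out.loc[ok, "p_value"].to_numpy()
        out.loc[ok, "fdr_q"] = multipletests(p, method="fdr_bh")[1]
        out.loc[ok, "bonferroni_p"] = np.minimum(p * ok.sum(), 1.0)
    out["significant"] = out["fdr_q"] <= alpha
    out.attrs["rho"] = rho
    return out


# ---------------------------------------------------------------------------
# proximity flag and APA-vs-expression contrast
# ---------------------------------------------------------------------------

def flag_upstream_proximity(
    pacs: pd.DataFrame,
    annotation,
    window: int = 250,
) -> pd.Series:
    """Flag 5'UTR PACs lying within ``window`` bp downstream of another
    same-strand gene's transcript end (likely driven by that gene).

    ``pacs`` needs contig/strand/representative (or position) columns;
    ``annotation`` is a :class:`patseq.annotate.GeneAnnotation`.
    """
    pos_col = "representative" if "representative" in pacs.columns else "position"
    flags = []
    for _, row in pacs.iterrows():
        contig, strand = row["contig"], row["strand"]
        pos = int(row[pos_col])
        own = row.get("gene_id")
        flagged = False
        for rec in annotation.genes.values():
            if rec.contig != contig or rec.strand != strand:
                continue
            if own is not None and rec.gene_id == own:
                continue
            term = rec.utr3_terminus
            if term is None:
                term = rec.end - 1 if strand == "+" else rec.start
            d = pos - term if strand == "+" else term - pos
            if 1 <= d <= window:
                flagged = True
                break
        flags.append(flagged)
    return pd.Series(flags, index=pacs.index, name="near_upstream_gene")


def apa_expression_contrast(
    de_results: pd.DataFrame,
    apa_genes: Iterable[str],
) -> Dict[str, pd.Series]:
    """Per-gene maximum |log2 fold-change| over all condition pairs, for all
    genes vs the alternative-polyadenylation gene set (box-plot input)."""
    max_abs = (de_results.assign(a=de_results["log2_fc"].abs())
               .groupby("gene_id")["a"].max())
    apa = [g for g in set(apa_genes) if g in max_abs.index]
    out = {"all": max_abs}
    if apa:
        out["apa"] = max_abs.loc[sorted(apa)]
    return out
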