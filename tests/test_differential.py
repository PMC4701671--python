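"""tpm normalization, DE and usage tests: examples, calibration, power."""

import numpy as np
import pandas as pd
import pytest

import patseq as ps
from patseq.differential import (apa_expression_contrast, de_genes,
                                 estimate_icc, flag_upstream_proximity,
                                 tpm_normalize)
from patseq.differential import test_gene_de as run_gene_de
from patseq.differential import test_pac_usage as run_pac_usage

LIBS = [f"L{i}" for i in range(6)]
DESIGN = {l: ("A" if i < 3 else "B") for i, l in enumerate(LIBS)}


class TestTpm:
    def test_single_gene_takes_the_million(self):
        counts = pd.DataFrame({"L1": [42]}, index=["g"])
        assert tpm_normalize(counts).tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_simple_split(self):
        counts = pd.DataFrame({"L1": [250, 750]}, index=["a", "b"])
        tpm = tpm_normalize(counts).tpm
        assert list(tpm["L1"]) == [250_000, 750_000]

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.integers(0, 500, (100, 6)) + 1, columns=LIBS)
        tpm = tpm_normalize(counts).tpm
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_library_rejected(self):
        counts = pd.DataFrame({"L1": [5], "L2": [0]}, index=["g"])
        with pytest.raises(ValueError, match="zero-total"):
            tpm_normalize(counts)


class TestGeneDe:
    def test_identical_counts_give_p_one(self):
        counts = pd.DataFrame(np.full((20, 6), 100), columns=LIBS,
                              index=[f"g{i}" for i in range(20)])
        res = run_gene_de(counts, DESIGN)
        assert (res["p_value"] == 1.0).all()
        assert de_genes(res) == []

    def test_count_floor_excludes_low_genes(self):
        counts = pd.DataFrame(
            [[1, 0, 0, 0, 1, 0], [50, 60, 55, 40, 45, 50]],
            columns=LIBS, index=["low", "high"])
        res = run_gene_de(counts, DESIGN, min_total=5)
        assert set(res["gene_id"]) == {"high"}

    def test_single_replicate_refused(self):
        counts = pd.DataFrame([[5, 6]], columns=["L1", "L2"], index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            run_gene_de(counts, {"L1": "A", "L2": "B"})

    def test_null_poisson_type_one_error(self):
        rng = np.random.default_rng(42)
        lam = rng.lognormal(np.log(200), 0.5, 2000)
        counts = pd.DataFrame(rng.poisson(lam[:, None], (2000, 6)),
                              columns=LIBS,
                              index=[f"g{i}" for i in range(2000)])
        res = run_gene_de(counts, DESIGN)
        frac = (res["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_eightfold_change_detected(self):
        rng = np.random.default_rng(7)
        null = rng.poisson(200.0, (500, 6))
        planted = np.hstack([rng.poisson(1600.0, (100, 3)),
                             rng.poisson(200.0, (100, 3))])
        counts = pd.DataFrame(np.vstack([null, planted]), columns=LIBS,
                              index=[f"g{i}" for i in range(600)])
        res = run_gene_de(counts, DESIGN)
        planted_ids = {f"g{i}" for i in range(500, 600)}
        hits = set(res[(res["fdr_q"] <= 0.05)]["gene_id"]) & planted_ids
        assert len(hits) >= 95

    def test_bh_q_values_monotone_in_p(self):
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(rng.poisson(100, (300, 6)), columns=LIBS,
                              index=[f"g{i}" for i in range(300)])
        res = run_gene_de(counts, DESIGN).sort_values("p_value")
        assert (np.diff(res["fdr_q"].to_numpy()) >= -1e-12).all()
        assert (res["bonferroni_p"] >= res["p_value"] - 1e-12).all()


def _two_pac_matrix(rng, n_genes, p1, p2, depth=300):
    """Genes with two PACs; first PAC usage p1 in A, p2 in B."""
    rows, gene = {}, {}
    for i in range(n_genes):
        n = rng.poisson(depth, 6) + 1
        k = np.concatenate([rng.binomial(n[:3], p1), rng.binomial(n[3:], p2)])
        rows[f"P{i}a"], rows[f"P{i}b"] = k, n - k
        gene[f"P{i}a"] = gene[f"P{i}b"] = f"G{i}"
    mat = pd.DataFrame(rows).T
    mat.columns = LIBS
    return mat, gene


class TestPacUsage:
    def test_equal_usage_no_excess_calls(self):
        rng = np.random.default_rng(5)
        mat, gene = _two_pac_matrix(rng, 200, 0.5, 0.5)
        res = run_pac_usage(mat, gene, DESIGN)
        assert res["significant"].mean() <= 0.05

    def test_lone_pac_not_tested(self):
        mat = pd.DataFrame({l: [10] for l in LIBS}, index=["solo"])
        res = run_pac_usage(mat, {"solo": "G"}, DESIGN)
        assert res.empty

    def test_zero_condition_total_skipped(self):
        mat = pd.DataFrame(
            [[5, 6, 4, 0, 0, 0], [7, 3, 6, 0, 0, 0]], columns=LIBS,
            index=["Pa", "Pb"])
        res = run_pac_usage(mat, {"Pa": "G", "Pb": "G"}, DESIGN)
        assert res["skipped"].all()

    def test_usage_sums_to_one_over_gene(self):
        rng = np.random.default_rng(19)
        mat, gene = _two_pac_matrix(rng, 30, 0.3, 0.6)
        res = run_pac_usage(mat, gene, DESIGN)
        ok = res[~res["skipped"]]
        paired = ok.pivot_table(index=["gene_id"], columns=ok["pac_id"].str[-1],
                                values="usage_1")
        assert np.allclose(paired["a"] + paired["b"], 1.0)

    def test_null_beta_binomial_type_one_error(self):
        rng = np.random.default_rng(42)
        rows, gene = {}, {}
        for i in range(2000):
            n = rng.poisson(300, 6) + 1
            p = rng.uniform(0.2, 0.8)
            rho = 0.02
            a, b = p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho
            k = rng.binomial(n, rng.beta(a, b, 6))
            rows[f"P{i}a"], rows[f"P{i}b"] = k, n - k
            gene[f"P{i}a"] = gene[f"P{i}b"] = f"G{i}"
        mat = pd.DataFrame(rows).T
        mat.columns = LIBS
        res = run_pac_usage(mat, gene, DESIGN)
        first = res[res["pac_id"].str.endswith("a")]
        frac = (first["p_value"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_usage_switch_power(self):
        rng = np.random.default_rng(7)
        null_mat, null_gene = _two_pac_matrix(rng, 300, 0.5, 0.5)
        sw_mat, sw_gene = _two_pac_matrix(rng, 20, 0.3, 0.7)
        sw_mat.index = [i.replace("P", "S") for i in sw_mat.index]
        sw_gene = {k.replace("P", "S"): v + "s" for k, v in sw_gene.items()}
        mat = pd.concat([null_mat, sw_mat])
        res = run_pac_usage(mat, {**null_gene, **sw_gene}, DESIGN)
        hits = res[(res["pac_id"].str.startswith("S"))
                   & (res["pac_id"].str.endswith("a"))
                   & (res["fdr_q"] <= 0.05)]
        assert hits["pac_id"].nunique() >= 18   # >= 90% of 20 planted

    def test_icc_recovered_from_replicates(self):
        rng = np.random.default_rng(31)
        ks, ns = [], []
        rho = 0.05
        for _ in range(3000):
            n = rng.poisson(400, 3) + 1
            p = rng.uniform(0.3, 0.7)
            a, b = p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho
            ks.append(rng.binomial(n, rng.beta(a, b, 3)))
            ns.append(n)
        assert estimate_icc(ks, ns) == pytest.approx(rho, rel=0.25)


class TestFlagsAndContrast:
    def test_upstream_gene_proximity_boundaries(self, fixture_ann):
        pacs = pd.DataFrame({
            "contig": "t1", "strand": ["+", "+", "-"],
            "position": [7749, 7800, 7749],      # geneH terminus at 7549
            "gene_id": ["geneI", "geneI", None],
        })
        flags = flag_upstream_proximity(pacs, fixture_ann, window=250)
        assert list(flags) == [True, False, False]

    def test_apa_contrast_medians_agree_without_expression_change(self):
        rng = np.random.default_rng(13)
        counts = pd.DataFrame(rng.poisson(300, (400, 6)), columns=LIBS,
                              index=[f"g{i}" for i in range(400)])
        res = run_gene_de(counts, DESIGN)
        apa = [f"g{i}" for i in range(0, 400, 10)]
        dists = apa_expression_contrast(res, apa)
        m_all = dists["all"].median()
        m_apa = dists["apa"].median()
        assert abs(m_all - m_apa) < 0.1

    def test_empty_apa_set_returns_only_all(self):
        res = pd.DataFrame({"gene_id": ["a"], "log2_fc": [0.5]})
        assert set(apa_expression_contrast(res, [])) == {"all"}
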