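"""RLE normalisation, NB exact test calibration/power, BH adjustment and
DEG selection rules; includes an independent cross-check against the
edgeR exact test run through Rscript."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allohe import (
    CultivarDesign,
    GenomeLayout,
    NoiseModel,
    TruthSet,
    bh_adjust,
    consensus_degs,
    nb_test,
    rle_size_factors,
    top_ranked_intersection,
)
from allohe.simulate import simulate_expression


def _null_matrix(n_genes=2000, seed=0):
    layout = GenomeLayout(n_chromosomes=4, genes_per_chromosome=n_genes // 4)
    designs = [CultivarDesign("a", "AAA"), CultivarDesign("b", "ABB")]
    truth = TruthSet(seed=0, gene_dosage={})
    m, sheet = simulate_expression(designs, truth, NoiseModel(), seed=seed, layout=layout)
    ga = sheet.loc[sheet["cultivar"] == "b", "sample"].tolist()
    gb = sheet.loc[sheet["cultivar"] == "a", "sample"].tolist()
    return m, ga, gb


class TestRleSizeFactors:
    def test_identical_columns_unit_factors(self):
        m = pd.DataFrame({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        assert rle_size_factors(m).tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=500) + 1
        m = pd.DataFrame({"s1": base, "s2": base, "s3": 2 * base})
        f = rle_size_factors(m)
        assert f["s3"] / f["s1"] == pytest.approx(2.0, rel=1e-6)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.poisson(50, size=(300, 5)) + 1)
        f = rle_size_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_scaling_contract(self):
        # multiplying one sample by c multiplies its factor by c relative
        # to every other sample (the per-gene geometric-mean reference
        # itself absorbs c^(1/m), so only factor ratios are identifiable)
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.poisson(80, size=(400, 4)) + 1, columns=list("abcd"))
        f0 = rle_size_factors(m)
        m2 = m.copy()
        m2["c"] = m2["c"] * 3
        f1 = rle_size_factors(m2)
        for other in "abd":
            assert (f1["c"] / f1[other]) / (f0["c"] / f0[other]) == pytest.approx(
                3.0, rel=1e-9
            )
        # normalised counts of untouched samples are unchanged up to the
        # common rescaling
        assert f1["a"] / f1["b"] == pytest.approx(f0["a"] / f0["b"], rel=1e-9)

    def test_no_common_gene_error(self):
        m = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="filter"):
            rle_size_factors(m)


class TestNbTest:
    def test_null_type_i_error_within_binomial_ci(self):
        from scipy.stats import binom as binom_dist

        m, ga, gb = _null_matrix(seed=10)
        res = nb_test(m, rle_size_factors(m), ga, gb)
        n = len(res)
        hits = int((res["pvalue"] < 0.05).sum())
        lo, hi = binom_dist.interval(0.99, n, 0.05)
        assert lo <= hits <= hi

    def test_power_on_eightfold_change(self):
        layout = GenomeLayout(n_chromosomes=1, genes_per_chromosome=500)
        eff = {f"chr01g{i:04d}": 3.0 for i in range(30)}
        truth = TruthSet(
            seed=0, gene_dosage={}, de_effects=eff,
            redundancy={g: "uncompensated" for g in eff},
        )
        designs = [CultivarDesign("a", "AAA"), CultivarDesign("b", "ABB")]
        m, sheet = simulate_expression(designs, truth, NoiseModel(), seed=6, layout=layout)
        ga = sheet.loc[sheet["cultivar"] == "b", "sample"].tolist()
        gb = sheet.loc[sheet["cultivar"] == "a", "sample"].tolist()
        res = nb_test(m, rle_size_factors(m), ga, gb).set_index("gene_id")
        assert (res.loc[list(eff), "qvalue"] < 0.05).all()
        assert (res.loc[list(eff), "logFC"] > 1.5).all()

    def test_label_swap_negates_logfc_keeps_p(self):
        m, ga, gb = _null_matrix(n_genes=200, seed=4)
        f = rle_size_factors(m)
        r1 = nb_test(m, f, ga, gb)
        r2 = nb_test(m, f, gb, ga)
        np.testing.assert_allclose(r1["logFC"], -r2["logFC"], atol=1e-12)
        np.testing.assert_allclose(r1["pvalue"], r2["pvalue"], rtol=1e-9)

    def test_all_zero_gene_flagged(self):
        m, ga, gb = _null_matrix(n_genes=100, seed=5)
        m.iloc[0] = 0
        res = nb_test(m, rle_size_factors(m.iloc[1:]).reindex(m.columns).fillna(1.0), ga, gb)
        # recompute factors on nonzero genes; first gene must be p=1
        assert res.iloc[0]["pvalue"] == 1.0
        assert res.iloc[0]["status"] == "all_zero"

    def test_single_replicate_rejected(self):
        m, ga, gb = _null_matrix(n_genes=100, seed=5)
        with pytest.raises(ValueError):
            nb_test(m, rle_size_factors(m), ga[:1], gb)

    def test_agrees_with_edger_exact_test(self, tmp_path):
        # independent oracle: Bioconductor edgeR (common dispersion,
        # RLE normalisation) on the same matrix
        layout = GenomeLayout(n_chromosomes=1, genes_per_chromosome=300)
        eff = {f"chr01g{i:04d}": (1.5 if i % 2 else -1.5) for i in range(20)}
        truth = TruthSet(
            seed=0, gene_dosage={}, de_effects=eff,
            redundancy={g: "uncompensated" for g in eff},
        )
        designs = [CultivarDesign("a", "AAA"), CultivarDesign("b", "ABB")]
        m, sheet = simulate_expression(designs, truth, NoiseModel(), seed=5, layout=layout)
        ga = sheet.loc[sheet["cultivar"] == "b", "sample"].tolist()
        gb = sheet.loc[sheet["cultivar"] == "a", "sample"].tolist()
        res = nb_test(m, rle_size_factors(m), ga, gb).set_index("gene_id")

        counts_path = tmp_path / "counts.tsv"
        m[gb + ga].to_csv(counts_path, sep="\t")
        script = tmp_path / "edger.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f'm <- as.matrix(read.delim("{counts_path}", row.names=1))\n'
            f'group <- factor(rep(c("a","b"), c({len(gb)}, {len(ga)})))\n'
            "y <- DGEList(counts=m, group=group)\n"
            'y <- calcNormFactors(y, method="RLE")\n'
            "y <- estimateCommonDisp(y)\n"
            'et <- exactTest(y, pair=c("a","b"))\n'
            "write.table(data.frame(gene=rownames(et$table), p=et$table$PValue,"
            ' lfc=et$table$logFC), "'
            + str(tmp_path / "edger.tsv")
            + '", sep="\\t", row.names=FALSE, quote=FALSE)\n'
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, timeout=300
        )
        ed = pd.read_csv(tmp_path / "edger.tsv", sep="\t").set_index("gene")
        from scipy.stats import spearmanr

        common = res.index.intersection(ed.index)
        rho = spearmanr(res.loc[common, "pvalue"], ed.loc[common, "p"]).statistic
        assert rho > 0.95
        fc_corr = np.corrcoef(res.loc[common, "logFC"], ed.loc[common, "lfc"])[0, 1]
        assert fc_corr > 0.95


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, float("nan")])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_monotone_in_sorted_p(self, ps):
        q = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert ((q >= np.asarray(ps) - 1e-12) & (q <= 1 + 1e-12)).all()


def _result(genes, ps, fcs):
    return pd.DataFrame(
        {"gene_id": genes, "pvalue": ps, "qvalue": ps, "logFC": fcs}
    )


class TestConsensusDegs:
    def test_three_of_three_required(self):
        genes = ["g1", "g2", "g3"]
        r1 = _result(genes, [0.01, 0.01, 0.5], [1, -1, 1])
        r2 = _result(genes, [0.02, 0.01, 0.5], [1, -1, 1])
        r3 = _result(genes, [0.03, 0.9, 0.5], [1, -1, 1])
        assert consensus_degs([r1, r2, r3]) == ["g1"]  # g2 only 2/3

    def test_sign_discordance_excluded(self):
        genes = ["g1"]
        r1 = _result(genes, [0.01], [1.0])
        r2 = _result(genes, [0.01], [-1.0])
        assert consensus_degs([r1, r2]) == []
        assert consensus_degs([r1, r2], require_sign_concordance=False) == ["g1"]

    def test_universe_mismatch_rejected(self):
        r1 = _result(["g1"], [0.01], [1.0])
        r2 = _result(["g2"], [0.01], [1.0])
        with pytest.raises(ValueError, match="universe"):
            consensus_degs([r1, r2])

    def test_consensus_bounded_by_min_comparison(self, expression_dataset):
        from allohe import compare_cultivars

        ds = expression_dataset
        sheet = ds.sample_sheet
        f = rle_size_factors(ds.counts)
        results = [
            compare_cultivars(ds.counts, sheet, "allo1", ref, size_factors=f)
            for ref in ("auto1", "auto2", "auto3")
        ]
        cons = consensus_degs(results)
        per = [int((r["qvalue"] <= 0.05).sum()) for r in results]
        assert len(cons) <= min(per)
        # designed effect genes dominate the consensus
        truth_effects = set(ds.truth.de_effects)
        assert len(truth_effects & set(cons)) >= 0.9 * len(truth_effects)


class TestTopRankedIntersection:
    def test_identical_rankings_full_overlap(self):
        r = _result([f"g{i}" for i in range(10)], np.linspace(0.001, 0.9, 10), np.ones(10))
        assert len(top_ranked_intersection(r, r, k=5)) == 5

    def test_disjoint_top_sets_empty(self):
        r1 = _result(["a", "b", "c", "d"], [0.01, 0.02, 0.8, 0.9], np.ones(4))
        r2 = _result(["a", "b", "c", "d"], [0.8, 0.9, 0.01, 0.02], np.ones(4))
        assert top_ranked_intersection(r1, r2, k=2) == []

    def test_invariant_below_rank_k(self):
        genes = [f"g{i}" for i in range(20)]
        ps = np.linspace(0.001, 0.5, 20)
        r1 = _result(genes, ps, np.ones(20))
        shuffled = r1.iloc[[*range(10), *np.random.default_rng(0).permutation(range(10, 20))]]
        assert top_ranked_intersection(r1, r1, k=10) == top_ranked_intersection(
            r1, shuffled, k=10
        )

    def test_k_clamped_with_warning(self):
        r = _result(["a", "b"], [0.1, 0.2], [1, 1])
        with pytest.warns(UserWarning, match="clamp"):
            out = top_ranked_intersection(r, r, k=5)
        assert out == ["a", "b"]
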