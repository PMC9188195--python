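"""Differential abundance, moderation, TREAT, gene-set scores, overlaps."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plaquemap import synthetic as syn
from plaquemap.omics import (
    bh_fdr,
    build_design,
    classify_differential,
    differential_analysis,
    eigen_weighted_score,
    estimate_surrogates,
    extract_signature,
    filter_detection,
    filter_low_expression,
    fit_linear_model,
    hypergeometric_overlap,
    leading_edge_score,
    leading_edge_union,
    median_scale,
    moderate_variance,
    moderated_t_test,
    normalize_internal_standard,
    paired_differences,
    running_sum_enrichment,
    sum_technical_replicates,
    treat_test,
)

from _oracles import hand_bh, hypergeom_tail_enumeration


class TestNormalization:
    def test_log2_ratio_examples(self):
        areas = pd.DataFrame({"s1": [200.0, 100.0]}, index=["a", "b"])
        std = pd.DataFrame({"s1": [100.0]}, index=["IS"])
        out = normalize_internal_standard(areas, std, {"a": "IS", "b": "IS"})
        assert out.loc["a", "s1"] == pytest.approx(1.0)
        assert out.loc["b", "s1"] == pytest.approx(0.0)

    def test_matches_elementwise_oracle(self, rng):
        areas = pd.DataFrame(rng.uniform(10, 1e5, (20, 6)),
                             index=[f"a{i}" for i in range(20)],
                             columns=[f"s{j}" for j in range(6)])
        std = pd.DataFrame(rng.uniform(100, 1e4, (2, 6)), index=["I1", "I2"],
                           columns=areas.columns)
        smap = {f"a{i}": ("I1" if i % 2 else "I2") for i in range(20)}
        out = normalize_internal_standard(areas, std, smap)
        for f in areas.index:
            for s in areas.columns:
                assert out.loc[f, s] == pytest.approx(
                    np.log2(areas.loc[f, s] / std.loc[smap[f], s])
                )

    def test_nonpositive_standard_rejected(self):
        areas = pd.DataFrame({"s1": [200.0]}, index=["a"])
        std = pd.DataFrame({"s1": [0.0]}, index=["IS"])
        with pytest.raises(ValueError, match="positive"):
            normalize_internal_standard(areas, std, {"a": "IS"})


class TestFilters:
    def test_detection_boundary_75pct(self):
        # 7/10 detected (70% < 75%) removed; 8/10 (80%) kept
        row7 = [1.0] * 7 + [np.nan] * 3
        row8 = [1.0] * 8 + [np.nan] * 2
        m = pd.DataFrame([row7, row8], index=["seven", "eight"])
        kept = filter_detection(m, 0.75)
        assert list(kept.index) == ["eight"]

    def test_fully_detected_unchanged(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 8)))
        assert filter_detection(m).equals(m)

    def test_matches_counting_oracle(self, rng):
        m = pd.DataFrame(rng.normal(size=(40, 12)))
        m = m.mask(rng.random((40, 12)) < 0.3)
        kept = filter_detection(m, 0.75)
        for f in m.index:
            expected = m.loc[f].notna().sum() / 12 >= 0.75
            assert (f in kept.index) == expected

    def test_low_expression_boundary_more_than_ten(self):
        # "more than ten reads" in >= min_samples samples: 11 counts, 10 doesn't
        counts = pd.DataFrame(
            {"s1": [11, 10], "s2": [11, 11], "s3": [11, 11], "s4": [0, 0]},
            index=["kept", "dropped"],
        )
        out = filter_low_expression(counts, min_samples=3)
        assert list(out.index) == ["kept"]

    def test_all_zero_gene_removed(self):
        counts = pd.DataFrame({"s1": [0], "s2": [0]}, index=["zero"])
        assert filter_low_expression(counts, min_samples=1).empty

    def test_median_scale_zeroes_medians(self, rng):
        m = pd.DataFrame(rng.normal(5, 2, size=(31, 6)))
        out = median_scale(m)
        assert np.allclose(out.median(axis=0), 0.0)

    def test_median_scale_shift_invariant(self, rng):
        m = pd.DataFrame(rng.normal(size=(15, 4)))
        shifted = m.copy()
        shifted[2] = shifted[2] + 3.7
        assert np.allclose(median_scale(m).to_numpy(), median_scale(shifted).to_numpy())

    def test_sum_technical_replicates(self):
        counts = pd.DataFrame({"r1": [1, 2], "r2": [3, 4], "r3": [10, 20]})
        out = sum_technical_replicates(counts, ["m1", "m1", "m2"])
        assert out["m1"].tolist() == [4, 6]
        assert out["m2"].tolist() == [10, 20]


class TestLinearModel:
    def test_two_groups_coef_is_mean_difference(self):
        meta = pd.DataFrame({"genotype": ["WT"] * 3 + ["KI"] * 3},
                            index=[f"s{i}" for i in range(6)])
        values = pd.DataFrame([[1.0, 2.0, 3.0, 5.0, 6.0, 7.0]], index=["f1"],
                              columns=meta.index)
        design = build_design(meta, ["genotype"])
        fit = fit_linear_model(values, design, "genotype_KI")
        assert fit.coef[0] == pytest.approx(4.0)

    def test_orthogonal_covariate_leaves_coef_unchanged(self):
        meta = pd.DataFrame(
            {"genotype": ["WT", "WT", "KI", "KI"], "batch": ["a", "b", "a", "b"]},
            index=[f"s{i}" for i in range(4)],
        )
        values = pd.DataFrame([[1.0, 2.0, 4.0, 5.0]], index=["f1"], columns=meta.index)
        base = fit_linear_model(values, build_design(meta, ["genotype"]), "genotype_KI")
        with_cov = fit_linear_model(
            values, build_design(meta, ["genotype", "batch"]), "genotype_KI"
        )
        assert with_cov.coef[0] == pytest.approx(base.coef[0])

    def test_zero_noise_recovers_planted_effects_exactly(self):
        truth = syn.random_omics_truth(seed=31, n_features=30, n_affected=10, noise_sd=0.0)
        values, meta, _ = syn.make_analyte_dataset(truth)
        fit = fit_linear_model(values, build_design(meta, ["genotype", "batch", "sex"]),
                               "genotype_KI")
        assert np.abs(fit.coef - truth.true_log2fc).max() < 1e-10

    def test_rank_deficient_design_names_columns(self):
        meta = pd.DataFrame(
            {"genotype": ["WT", "WT", "KI", "KI"], "copy": ["WT", "WT", "KI", "KI"]},
            index=list("abcd"),
        )
        with pytest.raises(ValueError, match="collinear"):
            build_design(meta, ["genotype", "copy"])

    def test_missing_values_complete_case(self):
        meta = pd.DataFrame({"genotype": ["WT"] * 4 + ["KI"] * 4},
                            index=[f"s{i}" for i in range(8)])
        row = [1.0, 1.0, np.nan, 1.0, 3.0, 3.0, 3.0, np.nan]
        values = pd.DataFrame([row], index=["f1"], columns=meta.index)
        fit = fit_linear_model(values, build_design(meta, ["genotype"]), "genotype_KI")
        assert fit.coef[0] == pytest.approx(2.0)
        assert fit.df_resid[0] == 4  # 6 obs - 2 params


class TestModeration:
    def _fit(self, sigma2, df=4.0):
        from plaquemap.omics import LinearFit

        n = len(sigma2)
        return LinearFit(
            features=pd.Index([f"f{i}" for i in range(n)]),
            coef=np.ones(n),
            stdev_unscaled=np.full(n, 0.5),
            sigma2=np.asarray(sigma2, float),
            df_resid=np.full(n, df),
        )

    def test_identical_variances_unshrunk(self):
        mod = moderate_variance(self._fit([2.0] * 50))
        assert np.allclose(mod.s2_post, 2.0, rtol=1e-6)

    def test_moderated_between_featurewise_and_pooled(self, rng):
        s2 = stats.chi2.rvs(4, size=200, random_state=1) / 4 * 3.0
        mod = moderate_variance(self._fit(s2))
        pooled = mod.s2_prior
        between = ((mod.s2_post >= np.minimum(s2, pooled) - 1e-12)
                   & (mod.s2_post <= np.maximum(s2, pooled) + 1e-12))
        assert between.all()

    def test_treat_zero_threshold_equals_moderated_t(self, rng):
        truth = syn.random_omics_truth(seed=32, n_features=80, n_affected=20)
        values, meta, _ = syn.make_analyte_dataset(truth)
        mod = moderate_variance(
            fit_linear_model(values, build_design(meta, ["genotype", "batch", "sex"]),
                             "genotype_KI")
        )
        p_treat = treat_test(mod, lfc=0.0)["p"].to_numpy()
        p_mod = moderated_t_test(mod)["p"].to_numpy()
        assert np.nanmax(np.abs(p_treat - p_mod)) < 1e-12

    def test_treat_interior_null_p_near_one(self):
        fit = self._fit([0.01] * 20, df=10)
        fit.coef = np.full(20, 0.01)  # far inside |lfc| <= log2(1.2)
        mod = moderate_variance(fit)
        p = treat_test(mod, lfc=np.log2(1.2))["p"]
        assert (p > 0.95).all()

    def test_treat_matches_reference_tail_formula(self):
        # fixed tiny fit; evaluate the two-tail TREAT formula independently
        fit = self._fit([1.0, 4.0, 0.25], df=6.0)
        fit.coef = np.array([1.5, -0.4, 0.9])
        mod = moderate_variance(fit)
        lfc = np.log2(1.2)
        out = treat_test(mod, lfc=lfc)
        se = mod.stdev_unscaled * np.sqrt(mod.s2_post)
        for i in range(3):
            a = abs(mod.coef[i])
            expected = stats.t.sf((a - lfc) / se[i], mod.df_total[i]) + stats.t.sf(
                (a + lfc) / se[i], mod.df_total[i]
            )
            assert out["p"].iloc[i] == pytest.approx(min(expected, 1.0), rel=1e-12)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestLimmaOracle:
    """Cross-check moderation and TREAT against the reference R implementation."""

    def test_moderated_and_treat_match_limma(self, tmp_path, rng):
        n_feat, n_per = 60, 5
        meta = pd.DataFrame(
            {"genotype": ["WT"] * n_per + ["KI"] * n_per},
            index=[f"s{i}" for i in range(2 * n_per)],
        )
        true_sd = rng.lognormal(0, 0.6, n_feat)  # heteroscedastic features
        values = pd.DataFrame(
            rng.normal(0, 1, (n_feat, 2 * n_per)) * true_sd[:, None]
            + np.outer(rng.normal(0, 0.5, n_feat), (meta.genotype == "KI").astype(float)),
            index=[f"g{i}" for i in range(n_feat)],
            columns=meta.index,
        )
        values.to_csv(tmp_path / "m.csv")
        rcode = f"""
        suppressMessages(library(limma))
        m <- as.matrix(read.csv("{tmp_path}/m.csv", row.names=1))
        design <- cbind(Intercept=1, KI=rep(c(0,1), each={n_per}))
        fit <- lmFit(m, design)
        eb <- eBayes(fit)
        tr <- treat(fit, lfc=log2(1.2))
        out <- data.frame(t=eb$t[,2], p=eb$p.value[,2], p_treat=tr$p.value[,2],
                          s2post=eb$s2.post, dfprior=eb$df.prior)
        write.csv(out, "{tmp_path}/limma.csv")
        """
        (tmp_path / "run.R").write_text(rcode)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.csv", index_col=0)

        design = build_design(meta, ["genotype"])
        mod = moderate_variance(fit_linear_model(values, design, "genotype_KI"))
        ours_t = moderated_t_test(mod)
        ours_treat = treat_test(mod, lfc=np.log2(1.2))
        assert mod.df_prior == pytest.approx(ref["dfprior"].iloc[0], rel=1e-6)
        assert np.allclose(mod.s2_post, ref["s2post"], rtol=1e-8)
        assert np.allclose(ours_t["t"], ref["t"], rtol=1e-8)
        assert np.allclose(ours_t["p"], ref["p"], rtol=1e-8)
        assert np.allclose(ours_treat["p"], ref["p_treat"], rtol=1e-8)


class TestFdrAndRules:
    def test_bh_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_and_all_ones(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_bh_matches_hand_oracle(self, rng):
        p = rng.random(50)
        assert np.allclose(bh_fdr(p), hand_bh(p))

    def test_analyte_rule_thresholds(self):
        res = pd.DataFrame(
            {
                "log2fc": [np.log2(1.25), np.log2(1.10), np.log2(1.20)],
                "p": [1e-4, 1e-6, 1e-4],
            },
            index=["pass", "small_fc", "boundary_fc"],
        )
        out = classify_differential(res, "analyte").set_index(res.index)
        assert bool(out.loc["pass", "significant"])
        assert not bool(out.loc["small_fc", "significant"])  # 10% < 20%
        assert not bool(out.loc["boundary_fc", "significant"])  # exactly 20% excluded

    def test_gene_rule_q_boundary_inclusive(self):
        # construct p so that BH q values hit 0.10 exactly for all features
        res = pd.DataFrame({"log2fc": [2.0, 2.0], "p": [0.05, 0.10]})
        out = classify_differential(res, "gene")
        assert np.allclose(out["q"], 0.10)
        assert out["significant"].all()

    def test_signature_extraction_inclusive_at_one(self):
        diff = pd.DataFrame({"log2fc": [1.0, 0.99, 2.5]}, index=["a", "b", "c"])
        assert extract_signature(diff) == ["a", "c"]
        assert extract_signature(diff.iloc[0:0]) == []


class TestSurrogatesAndPairing:
    def test_surrogate_recovers_hidden_batch(self, rng):
        meta = pd.DataFrame({"genotype": ["WT"] * 6 + ["KI"] * 6},
                            index=[f"s{i}" for i in range(12)])
        hidden = np.array([0, 1] * 6, float)
        values = pd.DataFrame(
            rng.normal(0, 0.1, (100, 12)) + np.outer(rng.normal(0, 2, 100), hidden),
            columns=meta.index,
        )
        sv = estimate_surrogates(values, build_design(meta, ["genotype"]), n_sv=1)
        corr = np.corrcoef(sv["SV1"], hidden)[0, 1]
        assert abs(corr) > 0.99

    def test_paired_differences_balanced(self):
        meta = pd.DataFrame(
            {
                "subject_id": ["m1", "m1", "m2", "m2"],
                "methoxy_status": ["neg", "pos", "neg", "pos"],
            },
            index=["a", "b", "c", "d"],
        )
        values = pd.DataFrame({"a": [1.0], "b": [3.0], "c": [2.0], "d": [5.0]},
                              index=["f1"])
        diffs, _ = paired_differences(values, meta, "subject_id", "methoxy_status",
                                      ("neg", "pos"))
        assert diffs.loc["f1", "m1"] == pytest.approx(2.0)
        assert diffs.loc["f1", "m2"] == pytest.approx(3.0)

    def test_unbalanced_subjects_skipped(self):
        meta = pd.DataFrame(
            {"subject_id": ["m1", "m1", "m2"], "methoxy_status": ["neg", "pos", "neg"]},
            index=["a", "b", "c"],
        )
        values = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [9.0]}, index=["f1"])
        diffs, _ = paired_differences(values, meta, "subject_id", "methoxy_status",
                                      ("neg", "pos"))
        assert list(diffs.columns) == ["m1"]


class TestGeneSetScores:
    def test_single_gene_fallback(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"g{i}" for i in range(5)])
        score = eigen_weighted_score(expr, ["g2"], allow_single=True)
        assert np.allclose(score.scores, expr.loc["g2"] - expr.loc["g2"].mean())
        with pytest.raises(ValueError, match="single"):
            eigen_weighted_score(expr, ["g2"])

    def test_two_correlated_genes_equal_weights(self, rng):
        base = rng.normal(size=10)
        expr = pd.DataFrame({"s%d" % i: [base[i], base[i]] for i in range(10)},
                            index=["g1", "g2"])
        score = eigen_weighted_score(expr, ["g1", "g2"])
        assert score.weights["g1"] == pytest.approx(score.weights["g2"])
        centered_mean = (expr - expr.mean(axis=1).to_numpy()[:, None]).mean(axis=0)
        assert np.allclose(score.scores, centered_mean)

    def test_scores_invariant_to_gene_and_sample_order(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 7)), index=[f"g{i}" for i in range(8)],
                            columns=[f"s{j}" for j in range(7)])
        genes = ["g1", "g3", "g5", "g6"]
        a = eigen_weighted_score(expr, genes)
        b = eigen_weighted_score(expr.iloc[::-1, ::-1], genes[::-1])
        assert np.allclose(a.scores.sort_index(), b.scores.sort_index())

    def test_matches_pc1_projection_up_to_positive_scale(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 9)), index=[f"g{i}" for i in range(15)])
        genes = [f"g{i}" for i in range(0, 12)]
        score = eigen_weighted_score(expr, genes)
        sub = expr.loc[genes]
        centered = sub - sub.mean(axis=1).to_numpy()[:, None]
        # dense eigen-decomposition oracle on the gene-gene covariance
        cov = centered.to_numpy() @ centered.to_numpy().T
        w, v = np.linalg.eigh(cov)
        pc1 = v[:, -1] @ centered.to_numpy()
        r = np.corrcoef(score.scores, pc1)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-10)


class TestEnrichment:
    def test_top_k_set_positive_es_full_leading_edge(self):
        ranked = pd.Series(np.linspace(5, -5, 10), index=[f"g{i}" for i in range(10)])
        res = running_sum_enrichment(ranked, ["g0", "g1", "g2"])
        assert res.es > 0
        assert sorted(res.leading_edge) == ["g0", "g1", "g2"]
        assert res.leading_edge_mean_t == pytest.approx(ranked[:3].mean())

    def test_interleaved_set_near_zero_es(self):
        stats_ = np.linspace(4, -4, 20)
        ranked = pd.Series(stats_, index=[f"g{i}" for i in range(20)])
        res = running_sum_enrichment(ranked, [f"g{i}" for i in range(0, 20, 2)])
        assert abs(res.es) < 0.3

    def test_leading_edge_subset_of_set(self, rng):
        ranked = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        genes = [f"g{i}" for i in rng.choice(30, size=8, replace=False)]
        res = running_sum_enrichment(ranked, genes)
        assert set(res.leading_edge) <= set(genes)

    def test_union_rule_across_comparisons(self):
        from plaquemap.omics import EnrichmentResult

        r1 = EnrichmentResult("s", 0.5, ["a", "b"], 1.0)
        r2 = EnrichmentResult("s", 0.4, ["b", "c"], 1.0)
        union = leading_edge_union([r1, r2])
        assert union == ["a", "b", "c"]
        t1 = pd.Series({"a": 2.0, "b": 4.0, "c": 0.0})
        assert leading_edge_score(t1, union) == pytest.approx(2.0)

    def test_mean_t_examples(self):
        t = pd.Series({"a": 2.0, "b": 4.0})
        assert leading_edge_score(t, ["a", "b"]) == pytest.approx(3.0)
        assert leading_edge_score(t, ["b"]) == pytest.approx(4.0)


class TestHypergeometric:
    def test_zero_overlap_p_one(self):
        assert hypergeometric_overlap(0, 5, 5, 20) == pytest.approx(1.0)

    def test_full_overlap_counting(self):
        assert hypergeometric_overlap(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_matches_enumeration_small_universe(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 21))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeometric_overlap(k, K, n, N) == pytest.approx(
                hypergeom_tail_enumeration(k, K, n, N), rel=1e-10
            )

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(6, 5, 5, 10)


class TestPipelinePresets:
    def test_planted_effects_recovered(self):
        truth = syn.random_omics_truth(seed=33, n_features=150, n_affected=15,
                                       effect_log2fc=1.5, noise_sd=0.2)
        values, meta, _ = syn.make_analyte_dataset(truth)
        res = differential_analysis(values, meta, ["genotype", "batch", "sex"],
                                    "genotype_KI", rule="analyte")
        affected = res.iloc[truth.affected_features]
        assert affected["significant"].mean() >= 0.9
        null = res.iloc[15:]
        assert null["significant"].mean() < 0.1
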