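import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secretomics import synthdata
from secretomics.atlas import (
    TissueAtlas,
    benjamini_hochberg,
    embed_tsne,
    enrichment_score,
    enrichment_scores,
    EnrichmentResult,
    moderated_ttest,
    pairwise_tissue_de,
    read_atlas,
    relative_expression,
    squeeze_variances,
    write_atlas,
)

from _oracles import bh_step_up


def build_atlas(means, sd=0.3, reps=3, seed=0, adipose=("WAT", "BAT")):
    """means: genes x tissues array; first two tissues are adipose."""
    rng = np.random.default_rng(seed)
    means = np.asarray(means, dtype=float)
    n_genes, n_tissues = means.shape
    tissues = list(adipose) + [f"T{i:02d}" for i in range(n_tissues - 2)]
    cols = pd.MultiIndex.from_tuples(
        [(t, j + 1) for t in tissues for j in range(reps)]
    )
    vals = rng.normal(np.repeat(means, reps, axis=1), sd)
    return TissueAtlas(
        values=pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                            columns=cols),
        adipose_tissues=adipose,
    )


class TestModeratedT:
    def test_reduces_to_ordinary_t_with_zero_prior(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(5, 1, (20, 3)), rng.normal(4, 1, (20, 4))
        out = moderated_ttest(a, b, prior_df=0)
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(out["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(out["p"], ref.pvalue, rtol=1e-8)

    def test_log2fc_is_mean_difference(self):
        a = np.array([[10.0, 10.0, 10.0]])
        b = np.array([[4.0, 4.0, 4.2]])
        out = moderated_ttest(a, b)
        assert out["log2fc"].iloc[0] == pytest.approx(10.0 - (4.0 + 4.0 + 4.2) / 3, abs=1e-9)

    def test_shrinkage_pulls_variances_together(self):
        rng = np.random.default_rng(1)
        s2 = stats.chi2.rvs(4, size=500, random_state=2) / 4
        post, d0, s0 = squeeze_variances(s2, df=4)
        assert d0 > 0
        assert post.std() < s2.std()
        assert s0 == pytest.approx(1.0, rel=0.2)

    def test_matches_limma_on_fixture(self, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same values."""
        rng = np.random.default_rng(3)
        a = rng.normal(8, 1, (40, 3))
        b = rng.normal(7, 1, (40, 3))
        mat = np.hstack([a, b])
        csv = tmp_path / "m.csv"
        pd.DataFrame(mat).to_csv(csv, index=False)
        out = tmp_path / "limma.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{csv}"))
            design <- cbind(Intercept=1, Diff=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(t=fit$t[, "Diff"], p=fit$p.value[, "Diff"],
                                 lfc=fit$coefficients[, "Diff"],
                                 d0=fit$df.prior, s0=fit$s2.prior),
                      "{out}", row.names=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        if r.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {r.stderr[:200]}")
        ref = pd.read_csv(out)
        got = moderated_ttest(a, b)
        np.testing.assert_allclose(got["log2fc"], ref["lfc"], rtol=1e-8)
        assert got["df_prior"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=0.05)
        np.testing.assert_allclose(got["t"], ref["t"], rtol=0.02)
        # p-values inherit the (slightly different) moment fits of the
        # prior df, which small p's amplify
        np.testing.assert_allclose(got["p"], ref["p"], rtol=0.15, atol=1e-4)

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            moderated_ttest(np.ones((3, 1)), np.ones((3, 3)))


def test_bh_matches_step_up_oracle():
    rng = np.random.default_rng(4)
    for _ in range(5):
        p = rng.uniform(size=rng.integers(3, 40))
        np.testing.assert_allclose(benjamini_hochberg(p), bh_step_up(p), rtol=1e-12)
    # published-style worked list
    p = np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.2, 0.8])
    np.testing.assert_allclose(benjamini_hochberg(p), bh_step_up(p), rtol=1e-12)


class TestPairwiseDE:
    def test_planted_gene_significant(self):
        means = np.full((50, 10), 5.0)
        means[0, :2] += 6.0  # planted: +6 log2 in both adipose tissues
        atlas = build_atlas(means, sd=0.3, seed=5)
        lfc, p, sig = pairwise_tissue_de(atlas, "T00", gene="g0")
        assert sig
        assert lfc == pytest.approx(6.0, abs=0.6)

    def test_null_gene_not_significant(self):
        means = np.full((50, 10), 5.0)
        for seed in range(5):
            atlas = build_atlas(means, sd=0.3, seed=seed)
            de = pairwise_tissue_de(atlas, "T03")
            assert not de["significant"].any()

    def test_rejects_adipose_as_other(self):
        atlas = build_atlas(np.full((5, 5), 5.0))
        with pytest.raises(ValueError):
            pairwise_tissue_de(atlas, "BAT")
        with pytest.raises(ValueError):
            pairwise_tissue_de(atlas, "nope")


class TestEnrichmentScore:
    def test_worked_example_76_of_86(self):
        res = EnrichmentResult(gene="Adipoq-like", n_enriched=76, n_comparisons=86)
        assert round(res.score_percent, 1) == 88.4

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            EnrichmentResult(gene="x", n_enriched=5, n_comparisons=4)

    def test_identical_expression_scores_zero(self):
        atlas = build_atlas(np.full((30, 10), 5.0), sd=0.3, seed=6)
        res = enrichment_score(atlas, "g0")
        assert res.n_comparisons == 8
        assert res.score_percent == 0.0

    def test_all_significant_scores_100(self):
        means = np.full((30, 10), 5.0)
        means[0, :2] += 8.0
        atlas = build_atlas(means, sd=0.2, seed=7)
        res = enrichment_score(atlas, "g0")
        assert res.score_percent == 100.0

    def test_planted_above_80_exchangeable_below_10(self):
        cfg = synthdata.SynthConfig(seed=7, n_atlas_genes=120,
                                    n_adipose_genes=12, n_adipokines=3,
                                    n_tissues=30, n_proteins=60)
        atlas, truth = synthdata.simulate_atlas(cfg)
        scores = enrichment_scores(atlas, mode="combined")
        planted = truth["planted"].to_numpy()
        assert (scores.loc[planted, "score_percent"] > 80).all()
        assert (scores.loc[~planted, "score_percent"] < 10).all()

    def test_monotone_in_adipose_expression(self):
        """Raising a gene's adipose values never lowers its count."""
        means = np.full((40, 10), 5.0)
        means[0, :2] += 4.2  # near the fold-change boundary
        atlas = build_atlas(means, sd=0.3, seed=8)
        base = enrichment_score(atlas, "g0").n_enriched
        boosted = TissueAtlas(values=atlas.values.copy(),
                              adipose_tissues=atlas.adipose_tissues)
        cols = [c for c in boosted.values.columns if c[0] in ("WAT", "BAT")]
        boosted.values.loc["g0", cols] += 3.0
        assert enrichment_score(boosted, "g0").n_enriched >= base

    def test_modes(self):
        means = np.full((30, 10), 5.0)
        means[0, 0] += 8.0  # white-only enrichment
        atlas = build_atlas(means, sd=0.2, seed=9)
        white = enrichment_score(atlas, "g0", mode="white").score_percent
        brown = enrichment_score(atlas, "g0", mode="brown").score_percent
        any_m = enrichment_score(atlas, "g0", mode="any").score_percent
        assert white == 100.0
        assert brown == 0.0
        assert any_m == 100.0
        with pytest.raises(ValueError):
            enrichment_scores(atlas, mode="purple")


class TestRelativeExpression:
    def test_single_tissue_gene(self):
        means = np.full((1, 5), -40.0)  # ~0 on linear scale
        means[0, 2] = 10.0
        atlas = build_atlas(means, sd=0.01, seed=10)
        out = relative_expression(atlas)
        tissue = atlas.tissues[2]
        assert out.loc["g0", tissue] == pytest.approx(1.0, abs=1e-3)
        assert out.loc["g0", "top_tissue"] == tissue

    def test_uniform_gene(self):
        atlas = build_atlas(np.full((1, 8), 5.0), sd=0.0, seed=11)
        out = relative_expression(atlas)
        fractions = out.drop(columns="top_tissue").loc["g0"]
        assert np.allclose(fractions, 1 / 8)
        # exact tie -> first tissue in name order
        assert out.loc["g0", "top_tissue"] == sorted(atlas.tissues)[0]

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(12)
        atlas = build_atlas(rng.normal(5, 1, (20, 6)), sd=0.3, seed=13)
        out = relative_expression(atlas)
        for g in ["g0", "g7"]:
            means = {t: np.exp2(atlas.tissue_values(t).loc[g]).mean()
                     for t in atlas.tissues}
            total = sum(means.values())
            for t in atlas.tissues:
                assert out.loc[g, t] == pytest.approx(means[t] / total, rel=1e-9)

    def test_profiles_sum_to_one(self):
        rng = np.random.default_rng(14)
        atlas = build_atlas(rng.normal(5, 2, (30, 7)), seed=15)
        out = relative_expression(atlas).drop(columns="top_tissue")
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)


class TestTsne:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(16)
        prof = pd.DataFrame(rng.dirichlet(np.ones(8), size=60))
        with pytest.warns(UserWarning, match="perplexity"):
            a = embed_tsne(prof, seed=1)
        with pytest.warns(UserWarning, match="perplexity"):
            b = embed_tsne(prof, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_orthogonal_groups_separate(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(17)
        n = 60
        prof = np.zeros((2 * n, 10))
        prof[:n, 0] = 1.0
        prof[n:, 5] = 1.0
        prof += rng.uniform(0, 0.05, prof.shape)
        prof /= prof.sum(axis=1, keepdims=True)
        coords = embed_tsne(pd.DataFrame(prof), perplexity=20.0, seed=2)
        labels = np.repeat([0, 1], n)
        assert silhouette_score(coords.to_numpy(), labels) > 0.5

    def test_duplicated_rows_land_close(self):
        rng = np.random.default_rng(18)
        prof = rng.dirichlet(np.ones(6), size=90)
        prof[1] = prof[0]
        coords = embed_tsne(pd.DataFrame(prof), perplexity=15.0, seed=3).to_numpy()
        d_dup = np.linalg.norm(coords[0] - coords[1])
        spread = np.linalg.norm(coords - coords.mean(axis=0), axis=1).mean()
        assert d_dup < 0.2 * spread

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            embed_tsne(pd.DataFrame([[np.nan, 1.0]] * 10))


def test_atlas_round_trip(tmp_path, small_config):
    atlas, _ = synthdata.simulate_atlas(small_config)
    write_atlas(atlas, tmp_path / "a.csv", tmp_path / "side.csv")
    back = read_atlas(tmp_path / "a.csv", tmp_path / "side.csv")
    np.testing.assert_allclose(back.values.to_numpy(), atlas.values.to_numpy(),
                               rtol=1e-9)
    assert tuple(back.adipose_tissues) == tuple(atlas.adipose_tissues)
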