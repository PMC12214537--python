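"""Modulation score, rank-AUC scoring, bulk scores, preranked ES, group tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from flowsc import (
    CONTRACTILE_GENES,
    MODULATED_GENES,
    ExpressionMatrix,
    GeneSetCollection,
    ValidationError,
    auc_signature_score,
    bulk_signature_score,
    compare_groups,
    generate_bulk_cohort,
    lognormalize,
    preranked_enrichment,
    significance_band,
    signature_from_markers,
    top_markers,
    vsmc_modulation_score,
    wilcoxon_markers,
)
from conftest import make_counts


def expr_from_dense(dense, genes):
    ds = make_counts(np.zeros_like(dense, dtype=int), genes=genes)
    return ExpressionMatrix(
        values=sp.csr_matrix(np.asarray(dense, dtype=float)),
        gene_ids=ds.gene_ids,
        cell_ids=ds.cell_ids,
        cell_meta=ds.cell_meta,
        normalization="logCP10K",
    )


ALL_SIG = MODULATED_GENES + CONTRACTILE_GENES


class TestModulationScore:
    def test_all_zero_cell_scores_one(self):
        dense = np.zeros((12, 3))
        score = vsmc_modulation_score(expr_from_dense(dense, ALL_SIG))
        np.testing.assert_allclose(score, 1.0, atol=1e-12)

    def test_modulated_two_contractile_zero_scores_three(self):
        dense = np.zeros((12, 1))
        dense[:7, 0] = 2.0  # every modulated gene at 2 -> mean 2
        score = vsmc_modulation_score(expr_from_dense(dense, ALL_SIG))
        assert score.iloc[0] == pytest.approx(3.0, abs=1e-12)

    def test_missing_genes_count_as_zero_with_warning(self, caplog):
        # only Lum present at 7.0 -> modulated mean 1.0 -> score 2
        dense = np.array([[7.0]])
        with caplog.at_level("WARNING", logger="flowsc"):
            score = vsmc_modulation_score(expr_from_dense(dense, ["Lum"]))
        assert score.iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert any("absent" in r.message for r in caplog.records)

    def test_monotone_in_each_list(self):
        rng = np.random.default_rng(0)
        dense = rng.uniform(0, 3, size=(12, 1))
        base = vsmc_modulation_score(expr_from_dense(dense, ALL_SIG)).iloc[0]
        up = dense.copy()
        up[2, 0] += 1.0  # a modulated gene
        assert vsmc_modulation_score(expr_from_dense(up, ALL_SIG)).iloc[0] > base
        down = dense.copy()
        down[9, 0] += 1.0  # a contractile gene
        assert vsmc_modulation_score(expr_from_dense(down, ALL_SIG)).iloc[0] < base

    def test_overlapping_lists_rejected(self):
        expr = expr_from_dense(np.zeros((12, 1)), ALL_SIG)
        with pytest.raises(ValidationError):
            vsmc_modulation_score(expr, modulated=["Lum"], contractile=["Lum", "Acta2"])

    def test_no_signature_genes_present_rejected(self):
        expr = expr_from_dense(np.zeros((2, 1)), ["A", "B"])
        with pytest.raises(ValidationError):
            vsmc_modulation_score(expr)


def brute_force_auc(values, member_mask, top_frac):
    """Step-by-step recovery-curve integration for one cell."""
    import math

    G = len(values)
    k = math.ceil(top_frac * G)
    order = sorted(range(G), key=lambda i: (-values[i], i))
    hits = 0
    area = 0
    for r in range(k):
        if member_mask[order[r]]:
            hits += 1
        area += hits
    m = int(np.sum(member_mask))
    max_area = sum(min(r + 1, m) for r in range(k))
    return area / max_area


class TestAucScore:
    def test_set_at_top_scores_one_below_topk_scores_zero(self):
        genes = [f"g{i}" for i in range(100)]
        dense = np.arange(100, 0, -1, dtype=float).reshape(-1, 1)
        expr = expr_from_dense(dense, genes)
        assert auc_signature_score(expr, ["g0", "g1", "g2"], top_frac=0.05).iloc[0] == 1.0
        assert auc_signature_score(expr, ["g90", "g99"], top_frac=0.05).iloc[0] == 0.0

    def test_matches_brute_force_on_random_cells(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(200)]
        dense = rng.poisson(2.0, size=(200, 20)).astype(float)
        expr = expr_from_dense(dense, genes)
        members = rng.choice(200, 15, replace=False)
        mask = np.zeros(200, dtype=bool)
        mask[members] = True
        got = auc_signature_score(expr, [genes[i] for i in members], top_frac=0.1)
        for c in range(20):
            want = brute_force_auc(dense[:, c], mask, 0.1)
            assert got.iloc[c] == pytest.approx(want, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(80)]
        dense = rng.uniform(0, 5, size=(80, 6))
        members = [genes[i] for i in range(0, 30, 3)]
        a = auc_signature_score(expr_from_dense(dense, genes), members)
        b = auc_signature_score(expr_from_dense(np.exp(dense), genes), members)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_absent_set_scores_zero_with_warning(self, caplog):
        expr = expr_from_dense(np.ones((4, 2)), ["a", "b", "c", "d"])
        with caplog.at_level("WARNING", logger="flowsc"):
            score = auc_signature_score(expr, ["zz"])
        assert (score == 0).all()

    def test_bad_inputs_rejected(self):
        expr = expr_from_dense(np.ones((4, 2)), ["a", "b", "c", "d"])
        with pytest.raises(ValidationError):
            auc_signature_score(expr, [])
        with pytest.raises(ValidationError):
            auc_signature_score(expr, ["a"], top_frac=0.0)


class TestBulkScore:
    def test_identical_samples_score_zero(self):
        expr = pd.DataFrame(
            np.tile([[5.0, 6.0, 7.0]], (4, 1)),
            columns=["A", "B", "C"],
            index=[f"s{i}" for i in range(4)],
        )
        meta = pd.DataFrame({"group": ["x"] * 4}, index=expr.index)
        from flowsc import BulkDataset

        bulk = BulkDataset(expr=expr, sample_meta=meta)
        np.testing.assert_allclose(bulk_signature_score(bulk, ["A", "B"]), 0.0, atol=1e-12)

    def test_matches_brute_force_z_then_mean(self):
        bulk = generate_bulk_cohort(6, [f"S{i}" for i in range(10)], 0.7, seed=2)
        sig = [f"S{i}" for i in range(10)]
        got = bulk_signature_score(bulk, sig)
        sub = bulk.expr[sig].to_numpy()
        z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
        np.testing.assert_allclose(got.to_numpy(), z.mean(axis=1), atol=1e-12)

    def test_invariant_to_non_signature_genes(self):
        bulk = generate_bulk_cohort(6, ["S0", "S1", "S2"], 0.7, seed=3)
        full = bulk_signature_score(bulk, ["S0", "S1", "S2"])
        from flowsc import BulkDataset

        trimmed = BulkDataset(
            expr=bulk.expr[["S0", "S1", "S2"]], sample_meta=bulk.sample_meta
        )
        np.testing.assert_allclose(
            full.to_numpy(), bulk_signature_score(trimmed, ["S0", "S1", "S2"]).to_numpy(),
            atol=1e-12,
        )

    def test_planted_cohort_separates_groups_paired(self):
        sig = [f"S{i}" for i in range(25)]
        bulk = generate_bulk_cohort(20, sig, effect_size=1.0, seed=4)
        df = bulk.sample_meta.copy()
        df["score"] = bulk_signature_score(bulk, sig)
        res = compare_groups(df, "score", paired=True)
        assert res["p"] < 0.01
        adv = df[df.group == "advanced"]["score"].mean()
        early = df[df.group == "early"]["score"].mean()
        assert adv > early

    def test_too_few_present_genes_rejected(self):
        bulk = generate_bulk_cohort(3, ["S0"], 0.5, seed=1)
        with pytest.raises(ValidationError):
            bulk_signature_score(bulk, ["S0", "NOPE"])


@pytest.fixture(scope="module")
def marker_table():
    rng = np.random.default_rng(1)
    dense = rng.poisson(rng.uniform(0.5, 4.0, size=(60, 1)), size=(60, 90))
    dense[:10, :30] *= 5
    expr = lognormalize(make_counts(dense))
    labels = np.array(["hot"] * 30 + ["cold"] * 60)
    return wilcoxon_markers(expr, labels)


class TestSignatureFromMarkers:
    def test_equals_top_markers_restricted(self, marker_table):
        got = signature_from_markers(marker_table, "hot", 50)
        want = top_markers(marker_table, n=50)["hot"]
        assert got == want

    def test_unknown_cluster_rejected(self, marker_table):
        with pytest.raises(ValidationError):
            signature_from_markers(marker_table, "missing", 10)


def brute_force_es(stats_desc, member_mask, weight=1.0):
    """Position-by-position running sum on an already-sorted list."""
    w = np.abs(stats_desc) ** weight
    denom = w[member_mask].sum()
    miss = 1.0 / (len(stats_desc) - member_mask.sum())
    run, best = 0.0, 0.0
    for i in range(len(stats_desc)):
        run += w[i] / denom if member_mask[i] else -miss
        if abs(run) > abs(best):
            best = run
    return best


class TestPrerankedEnrichment:
    def test_top_block_scores_one(self):
        ranked = pd.Series(np.linspace(5, 0.1, 50), index=[f"g{i}" for i in range(50)])
        out = preranked_enrichment(ranked, [f"g{i}" for i in range(5)], n_perm=50, seed=0)
        assert out["ES"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out["p"].iloc[0] < 0.05

    def test_sign_flips_when_ranking_reversed(self):
        rng = np.random.default_rng(0)
        stats_ = pd.Series(
            np.sort(rng.normal(size=60))[::-1], index=[f"g{i}" for i in range(60)]
        )
        top = [f"g{i}" for i in range(8)]
        fwd = preranked_enrichment(stats_, top, n_perm=20, seed=0)["ES"].iloc[0]
        rev = preranked_enrichment(-stats_, top, n_perm=20, seed=0)["ES"].iloc[0]
        assert fwd > 0 > rev

    def test_matches_brute_force_on_20_gene_toy(self):
        rng = np.random.default_rng(4)
        vals = np.sort(rng.normal(scale=2, size=20))[::-1]
        ranked = pd.Series(vals, index=[f"g{i}" for i in range(20)])
        members = [f"g{i}" for i in [1, 4, 5, 11, 17]]
        mask = np.isin(ranked.index.to_numpy(), members)
        got = preranked_enrichment(ranked, members, n_perm=10, seed=0)["ES"].iloc[0]
        want = brute_force_es(vals, mask)
        assert got == pytest.approx(want, abs=1e-12)

    def test_null_permutation_p_uniform(self):
        rng = np.random.default_rng(9)
        vals = np.sort(rng.normal(size=150))[::-1]
        ranked = pd.Series(vals, index=[f"g{i}" for i in range(150)])
        ps = []
        for rep in range(200):
            members = [f"g{i}" for i in rng.choice(150, 8, replace=False)]
            out = preranked_enrichment(ranked, members, n_perm=99, seed=rep)
            ps.append(out["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collection_gets_bh_fdr(self):
        ranked = pd.Series(np.linspace(3, 0.1, 40), index=[f"g{i}" for i in range(40)])
        coll = GeneSetCollection({"top": ["g0", "g1", "g2"], "rand": ["g5", "g20", "g35"]})
        out = preranked_enrichment(ranked, coll, n_perm=200, seed=1)
        assert list(out["set"]) == ["top", "rand"]
        from flowsc import bh_adjust

        np.testing.assert_allclose(out["fdr"], bh_adjust(out["p"].to_numpy()), atol=1e-12)

    def test_tiny_overlap_rejected(self):
        ranked = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with pytest.raises(ValidationError):
            preranked_enrichment(ranked, ["a", "zz"], n_perm=10)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        df = pd.DataFrame({"score": [1.0, 2, 3, 4] * 2, "group": ["a"] * 4 + ["b"] * 4})
        res = compare_groups(df, "score")
        assert res["band"] == "n.s."

    @pytest.mark.parametrize(
        "p,band",
        [(0.2, "n.s."), (0.03, "*"), (0.004, "**"), (3e-4, "***"), (2e-5, "****")],
    )
    def test_band_convention(self, p, band):
        assert significance_band(p) == band

    def test_two_group_p_matches_scipy(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {"score": rng.normal(size=40), "group": ["a"] * 20 + ["b"] * 20}
        )
        res = compare_groups(df, "score")
        want = stats.mannwhitneyu(
            df.score[:20], df.score[20:], alternative="two-sided"
        ).pvalue
        assert res["p"] == pytest.approx(want, abs=1e-12)

    def test_three_group_kruskal(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"score": rng.normal(size=60), "group": ["a"] * 20 + ["b"] * 20 + ["c"] * 20}
        )
        res = compare_groups(df, "score")
        want = stats.kruskal(df.score[:20], df.score[20:40], df.score[40:]).pvalue
        assert res["test"] == "kruskal_wallis"
        assert res["p"] == pytest.approx(want, abs=1e-12)

    def test_paired_matches_scipy_wilcoxon(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=15)
        b = a + rng.normal(0.5, 1.0, size=15)
        df = pd.DataFrame(
            {
                "score": np.concatenate([a, b]),
                "group": ["x"] * 15 + ["y"] * 15,
                "pair_id": list(range(15)) * 2,
            }
        )
        res = compare_groups(df, "score", paired=True)
        want = stats.wilcoxon(a, b).pvalue
        assert res["p"] == pytest.approx(want, abs=1e-12)

    def test_small_group_excluded_then_error(self):
        df = pd.DataFrame({"score": [1.0, 2.0, 3.0], "group": ["a", "a", "b"]})
        with pytest.raises(ValidationError):
            compare_groups(df, "score")
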