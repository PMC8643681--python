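"""Synthetic counts, the DE statistic, DEG filtering and set algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plectoneme.expression import (
    CONTRAST_NAMES,
    SyntheticExpressionDesign,
    build_contrasts,
    filter_degs,
    fpkm,
    generate_synthetic_counts,
    simple_de_test,
    size_factors,
    top_n_anticorrelation,
    zscore_rows,
)


class TestGenerator:
    def test_zero_effect_makes_every_gene_null_in_distribution(self):
        d = SyntheticExpressionDesign(n_genes=200, effect_size_log2=0.0, seed=1)
        counts, truth = generate_synthetic_counts(d)
        assert (truth["true_log2fc"] == 0.0).all()

    def test_deterministic_given_seed(self):
        d = SyntheticExpressionDesign(n_genes=300, seed=7)
        c1, t1 = generate_synthetic_counts(d)
        c2, t2 = generate_synthetic_counts(d)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_shifts_recovered_within_sampling_error(self):
        d = SyntheticExpressionDesign(
            n_genes=2000, dispersion=0.05, n_replicates=4, seed=3
        )
        counts, truth = generate_synthetic_counts(d)
        sr = truth["gene_class"] == "supercoiling_responsive"
        gy = counts.filter(like="gyrAB_")
        y1 = counts.filter(like="Y119F_")
        observed = np.log2(gy.mean(axis=1) + 0.5) - np.log2(y1.mean(axis=1) + 0.5)
        # planted log2 shifts of the supercoiling class average to the effect
        err = (observed[sr.to_numpy()] - truth.loc[sr.to_numpy(), "true_log2fc"].to_numpy())
        assert abs(err.mean()) < 3 * err.std() / np.sqrt(len(err))

    def test_class_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SyntheticExpressionDesign(class_fractions=(0.5, 0.1, 0.1))


class TestDETest:
    def test_identical_groups_are_calibrated(self):
        d = SyntheticExpressionDesign(n_genes=1000, effect_size_log2=0.0, seed=11)
        counts, _ = generate_synthetic_counts(d)
        de = simple_de_test(counts, "gyrAB", "Y119F")
        frac = (de["pvalue"] < 0.05).mean()
        assert 0.02 < frac < 0.08
        # fold changes centered on zero (no systematic shift between groups)
        assert abs(de["log2FoldChange"].median()) < 0.1

    def test_planted_fourfold_gene_detected(self):
        d = SyntheticExpressionDesign(n_genes=500, effect_size_log2=2.0, seed=13)
        counts, truth = generate_synthetic_counts(d)
        de = simple_de_test(counts, "gyrAB", "Y119F").set_index("gene_id")
        sr = truth[truth["gene_class"] == "supercoiling_responsive"]
        high = sr.merge(
            de["baseMean"].reset_index(), on="gene_id"
        ).query("baseMean > 100")
        hits = de.loc[high["gene_id"]]
        signed_ok = np.sign(hits["log2FoldChange"]) == np.sign(
            high.set_index("gene_id")["true_log2fc"]
        )
        assert signed_ok.all()
        assert (hits["padj"] < 0.05).mean() >= 0.9

    def test_bh_identity_for_single_gene(self):
        counts = pd.DataFrame(
            {
                "A_1": [10], "A_2": [14], "B_1": [40], "B_2": [36],
            },
            index=pd.Index(["g1"], name="gene_id"),
        )
        de = simple_de_test(counts, "B", "A")
        assert de["padj"].iloc[0] == pytest.approx(de["pvalue"].iloc[0])

    def test_all_zero_gene_is_filtered(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(50, size=(3, 8)),
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
            columns=[f"A_{i}" for i in range(1, 5)] + [f"B_{i}" for i in range(1, 5)],
        )
        counts.loc["g2"] = 0
        de = simple_de_test(counts, "B", "A").set_index("gene_id")
        assert bool(de.loc["g2", "filtered"])
        assert np.isnan(de.loc["g2", "log2FoldChange"])

    def test_bh_adjustment_is_monotone(self):
        d = SyntheticExpressionDesign(n_genes=400, seed=5)
        counts, _ = generate_synthetic_counts(d)
        de = simple_de_test(counts, "gyrAB", "Ag").dropna(subset=["pvalue"])
        by_p = de.sort_values("pvalue")
        assert by_p["padj"].is_monotonic_increasing

    def test_size_factors_undo_library_scaling(self):
        d = SyntheticExpressionDesign(n_genes=500, effect_size_log2=0.0, seed=2)
        counts, _ = generate_synthetic_counts(d)
        scaled = counts.copy()
        scaled.iloc[:, 0] = (scaled.iloc[:, 0] * 3).astype(int)
        sf = size_factors(scaled)
        assert sf.iloc[0] / sf.iloc[1] == pytest.approx(3.0, rel=0.05)


class TestFilterDegs:
    def make(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "log2FoldChange", "padj", "baseMean"]
        )

    def test_strict_boundary_exclusion(self):
        table = self.make([("g1", np.log2(1.25), 0.01, 10.0)])
        assert filter_degs(table) == set()

    def test_toy_table(self):
        table = self.make(
            [
                ("up", 1.0, 0.001, 50.0),
                ("down", -0.9, 0.04, 80.0),
                ("weak_fc", 0.1, 0.001, 10.0),
                ("weak_p", 2.0, 0.2, 10.0),
                ("nan", np.nan, np.nan, 0.0),
            ]
        )
        assert filter_degs(table) == {"up", "down"}

    def test_relaxed_thresholds_admit_everything_tested(self):
        table = self.make([("a", 0.5, 0.5, 1.0), ("b", -3.0, 0.99, 1.0)])
        assert filter_degs(table, fc_threshold=1e-9, padj_threshold=1.0) == {"a", "b"}

    @given(
        fc1=st.floats(1.01, 3.0), fc2=st.floats(1.01, 3.0),
        p1=st.floats(0.001, 0.5), p2=st.floats(0.001, 0.5),
    )
    def test_monotone_in_both_thresholds(self, fc1, fc2, p1, p2):
        table = self.make(
            [(f"g{i}", lfc, p, 1.0)
             for i, (lfc, p) in enumerate([(0.2, 0.01), (1.4, 0.03), (-2.0, 0.2),
                                           (0.9, 0.06), (-0.4, 0.001)])]
        )
        loose = filter_degs(table, min(fc1, fc2), max(p1, p2))
        tight = filter_degs(table, max(fc1, fc2), min(p1, p2))
        assert tight <= loose


class TestContrasts:
    def test_srg_recovery_with_planted_classes(self):
        d = SyntheticExpressionDesign(seed=17)
        counts, truth = generate_synthetic_counts(d)
        tables = {
            "gyrAB_vs_Ag": simple_de_test(counts, "gyrAB", "Ag"),
            "Y119F_vs_Ag": simple_de_test(counts, "Y119F", "Ag"),
            "gyrAB_vs_Y119F": simple_de_test(counts, "gyrAB", "Y119F"),
        }
        res = build_contrasts(tables)
        true_sr = set(truth.loc[truth["gene_class"] == "supercoiling_responsive", "gene_id"])
        assert len(res.srg_set & true_sr) / len(true_sr) >= 0.9
        assert res.srg_set == res.deg_sets["gyrAB_vs_Y119F"]
        # burden genes shift equally in both gyrase strains: excluded from SRGs
        burden = set(truth.loc[truth["gene_class"] == "burden_responsive", "gene_id"])
        assert len(res.srg_set & burden) <= 0.1 * len(burden)

    def test_identical_tables_make_all_overlaps_equal(self):
        table = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2FoldChange": [2.0, -2.0, 0.0],
                "padj": [0.001, 0.001, 0.9],
                "baseMean": [10.0, 10.0, 10.0],
            }
        )
        res = build_contrasts({k: table for k in CONTRAST_NAMES})
        assert all(v == 2 for v in res.overlap_counts.values())

    def test_empty_tables_give_empty_sets(self):
        empty = pd.DataFrame(
            columns=["gene_id", "log2FoldChange", "padj", "baseMean"]
        )
        res = build_contrasts({k: empty for k in CONTRAST_NAMES})
        assert res.srg_set == set()
        assert all(v == 0 for v in res.overlap_counts.values())

    def test_universe_mismatch_reports_ids(self):
        base = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2FoldChange": [0, 0],
             "padj": [1.0, 1.0], "baseMean": [1, 1]}
        )
        other = base[base["gene_id"] == "a"]
        tables = {k: base for k in CONTRAST_NAMES} | {"gyrAB_vs_Y119F": other}
        with pytest.raises(ValueError, match="b"):
            build_contrasts(tables)


class TestTransforms:
    def test_fpkm_definition(self):
        assert fpkm(np.array([100]), np.array([1000]), 10**6)[0] == 100.0
        assert fpkm(np.array([0]), np.array([500]), 10**6)[0] == 0.0

    def test_fpkm_scales_inversely_with_depth(self):
        counts = np.array([100, 7, 33])
        lengths = np.array([1000, 200, 4000])
        np.testing.assert_allclose(
            fpkm(counts, lengths, 2 * 10**6), fpkm(counts, lengths, 10**6) / 2
        )

    def test_fpkm_rejects_zero_length(self):
        with pytest.raises(ValueError):
            fpkm(np.array([1]), np.array([0]), 100)

    def test_zscore_rows(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_rows(m)
        np.testing.assert_allclose(
            z.iloc[0], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)]
        )  # population-SD convention
        np.testing.assert_allclose(z.iloc[1], 0.0)
        np.testing.assert_allclose(z.iloc[0].mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.iloc[0].std(ddof=0), 1.0)

    def test_zscore_requires_two_samples(self):
        with pytest.raises(ValueError):
            zscore_rows(pd.DataFrame([[1.0]]))


class TestTopNAnticorrelation:
    def make_tables(self, n=40, seed=0):
        # upregulated genes: positive fold changes, as in a top-N of an
        # upregulated set
        rng = np.random.default_rng(seed)
        ids = [f"g{i}" for i in range(n)]
        lfc = rng.uniform(0.2, 4.0, n)
        table = pd.DataFrame({"gene_id": ids, "log2FoldChange": lfc})
        return table

    def test_perfect_anticorrelation(self):
        table = self.make_tables()
        ref = table.assign(log2FoldChange=-table["log2FoldChange"])
        count, detail = top_n_anticorrelation(table, ref, n=30)
        assert count == 30

    def test_self_reference_gives_zero(self):
        table = self.make_tables()
        top = table.sort_values("log2FoldChange", ascending=False).head(30)
        assert (top["log2FoldChange"] > 0).all()  # fixture sanity
        count, _ = top_n_anticorrelation(table, table, n=30)
        assert count == 0

    def test_constructed_26_of_30(self):
        table = self.make_tables(n=60, seed=3)
        top = table.sort_values("log2FoldChange", ascending=False).head(30)
        ref = table.copy()
        flipped = top["gene_id"].iloc[:26]
        ref["log2FoldChange"] = np.abs(ref["log2FoldChange"])
        ref.loc[ref["gene_id"].isin(flipped), "log2FoldChange"] *= -1
        count, _ = top_n_anticorrelation(table, ref, n=30)
        assert count == 26

    def test_missing_genes_are_reported_not_counted(self):
        table = self.make_tables(n=10)
        ref = table.iloc[:5].assign(log2FoldChange=-1.0)
        count, detail = top_n_anticorrelation(table, ref, n=10)
        assert count == 5
        assert (~detail["in_reference"]).sum() == 5
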