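"""Gene weights, the competitive t-test and multi-tissue aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from tissuesets import io, weights

TISSUES = ["t1", "t2", "t3", "t4", "t5"]


def expr_table(rows, genes, tissues=TISSUES):
    return io.ExpressionTable(pd.DataFrame(rows, index=genes, columns=tissues))


def ihc_records(*rows):
    rec = pd.DataFrame(
        rows, columns=["gene", "tissue", "cell_type", "level", "reliability"]
    )
    return io.IHCTable(rec)


def welch_log_p_oracle(m, c):
    """Closed-form one-sided Welch p via the regularized incomplete beta.

    Independent of the implementation's t.logsf route: the t statistic and
    Welch-Satterthwaite df are recomputed from scratch and the upper-tail
    probability evaluated as I_x(df/2, 1/2)/2 with x = df/(df + t^2).
    """
    m = np.asarray(m, float)
    c = np.asarray(c, float)
    v1, v2 = m.var(ddof=1), c.var(ddof=1)
    n1, n2 = m.size, c.size
    se = v1 / n1 + v2 / n2
    t = (m.mean() - c.mean()) / math.sqrt(se)
    df = se**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    tail = 0.5 * special.betainc(df / 2.0, 0.5, df / (df + t * t))
    p = tail if t >= 0 else 1.0 - tail
    return math.log(p)


class TestFoldChange:
    def test_constant_gene_has_fold_change_one(self):
        e = weights.expression_fold_change(expr_table([[3.0] * 5], ["G1"]))
        assert (e.loc["G1"] == 1.0).all()

    def test_single_spike_gene(self):
        e = weights.expression_fold_change(expr_table([[10, 0, 0, 0, 0]], ["G1"]))
        assert e.loc["G1"].tolist() == [5.0, 0, 0, 0, 0]

    def test_missing_cell_gives_zero_and_dilutes_mean(self):
        # missing counts as 0 in the denominator mean: mean = 8/5
        tab = expr_table([[np.nan, 2, 2, 2, 2]], ["G1"])
        e = weights.expression_fold_change(tab)
        assert e.at["G1", "t1"] == 0.0
        assert e.at["G1", "t2"] == pytest.approx(2 / (8 / 5))

    def test_all_zero_gene_gives_zero_everywhere(self):
        e = weights.expression_fold_change(expr_table([[0.0] * 5], ["G1"]))
        assert (e.loc["G1"] == 0.0).all()

    def test_single_tissue_table_rejected(self):
        with pytest.raises(ValueError, match="single-tissue"):
            weights.expression_fold_change(
                io.ExpressionTable(pd.DataFrame({"t1": [1.0]}, index=["G1"]))
            )


class TestIHCActivity:
    @pytest.mark.parametrize(
        "level,expected", [("Low", 1), ("Medium", 1), ("High", 1), ("Not detected", 0)]
    )
    def test_single_record_level(self, level, expected):
        a = weights.ihc_activity(
            ihc_records(("G1", "liver", "", level, "")), ["G1"], ["liver"]
        )
        assert a.at["G1", "liver"] == expected

    def test_no_record_defaults_to_active(self):
        a = weights.ihc_activity(ihc_records(), ["G1"], ["liver"])
        assert a.at["G1", "liver"] == 1

    def test_multiple_cell_types_collapse_by_max(self):
        a = weights.ihc_activity(
            ihc_records(
                ("G1", "liver", "hepatocyte", "Not detected", ""),
                ("G1", "liver", "bile duct", "Low", ""),
            ),
            ["G1"],
            ["liver"],
        )
        assert a.at["G1", "liver"] == 1

    def test_reliability_filter_drops_records(self):
        a = weights.ihc_activity(
            ihc_records(("G1", "liver", "", "Not detected", "Uncertain")),
            ["G1"],
            ["liver"],
            drop_reliability=["Uncertain"],
        )
        # the only record is dropped, so the pair falls back to a = 1
        assert a.at["G1", "liver"] == 1


class TestGeneWeights:
    def test_weight_is_product_of_components(self):
        expr = expr_table([[10, 0, 0, 0, 0], [2, 2, 2, 2, 2]], ["G1", "G2"])
        ihc = ihc_records(("G1", "t1", "", "High", ""), ("G2", "t1", "", "Not detected", ""))
        gw = weights.gene_weights(expr, ihc)
        assert gw.w.at["G1", "t1"] == 5.0  # e=5, a=1
        assert gw.w.at["G2", "t1"] == 0.0  # e=1, a=0
        assert gw.w.at["G2", "t2"] == 1.0  # no IHC record -> a=1
        pd.testing.assert_frame_equal(gw.w, gw.e * gw.a.astype(float))

    def test_not_detected_forces_zero_despite_high_expression(self):
        expr = expr_table([[100, 1, 1, 1, 1]], ["G1"])
        gw = weights.gene_weights(expr, ihc_records(("G1", "t1", "", "Not detected", "")))
        assert gw.w.at["G1", "t1"] == 0.0


class TestSetWeight:
    def test_identical_samples_give_minus_log_half(self):
        r = weights.set_weight([1, 2, 3], [1, 2, 3])
        assert not r.degenerate
        assert r.weight == pytest.approx(-math.log(0.5), rel=1e-12)

    def test_shifted_member_matches_closed_form_oracle(self):
        r = weights.set_weight([5, 6, 7], [1, 2, 3])
        assert r.log_p == pytest.approx(welch_log_p_oracle([5, 6, 7], [1, 2, 3]), rel=1e-12)

    def test_wrong_direction_gives_small_weight(self):
        r = weights.set_weight([1, 2, 3], [5, 6, 7])
        assert 0 <= r.weight < -math.log(0.5)

    @pytest.mark.parametrize("m,c", [([1.0], [1, 2, 3]), ([1, 2, 3], [4.0])])
    def test_short_vector_is_degenerate(self, m, c):
        r = weights.set_weight(m, c)
        assert r.degenerate and math.isnan(r.weight)

    def test_both_zero_variance_is_degenerate(self):
        r = weights.set_weight([2, 2, 2], [1, 1, 1])
        assert r.degenerate

    def test_one_zero_variance_is_fine(self):
        r = weights.set_weight([2, 2, 2], [1, 1.5, 2])
        assert not r.degenerate

    def test_pooled_matches_scipy_ttest(self):
        rng = np.random.default_rng(5)
        m, c = rng.normal(1, 1, 8), rng.normal(0, 1, 30)
        r = weights.set_weight(m, c, variance="pooled")
        p_ref = stats.ttest_ind(m, c, equal_var=True, alternative="greater").pvalue
        assert math.exp(r.log_p) == pytest.approx(p_ref, rel=1e-10)

    def test_welch_matches_scipy_ttest(self):
        rng = np.random.default_rng(6)
        m, c = rng.normal(1, 2, 8), rng.normal(0, 1, 30)
        r = weights.set_weight(m, c, variance="welch")
        p_ref = stats.ttest_ind(m, c, equal_var=False, alternative="greater").pvalue
        assert math.exp(r.log_p) == pytest.approx(p_ref, rel=1e-10)

    def test_log_base_10_rescales_weight(self):
        r_e = weights.set_weight([5, 6, 7], [1, 2, 3])
        r_10 = weights.set_weight([5, 6, 7], [1, 2, 3], log_base=10)
        assert r_10.weight == pytest.approx(r_e.weight / math.log(10), rel=1e-12)

    def test_huge_separation_stays_finite(self):
        # log-space evaluation: p underflows double precision (exp(log_p)
        # rounds to 0) but -log p must stay finite and large
        m = np.linspace(100, 101, 5000)
        c = np.linspace(0, 1, 5000)
        r = weights.set_weight(m, c)
        assert np.isfinite(r.weight) and r.weight > 1e4
        assert math.exp(r.log_p) == 0.0

    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=20),
        st.floats(0.1, 50),
    )
    def test_monotone_in_member_shift(self, member, shift):
        member = np.asarray(member)
        complement = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        base = weights.set_weight(member, complement)
        shifted = weights.set_weight(member + shift, complement)
        if not (base.degenerate or shifted.degenerate):
            assert shifted.weight >= base.weight - 1e-9

    @given(st.floats(0.01, 100))
    def test_scale_invariance(self, c):
        member = np.array([4.0, 5.0, 7.0])
        complement = np.array([1.0, 2.0, 3.0, 3.5])
        base = weights.set_weight(member, complement)
        scaled = weights.set_weight(member * c, complement * c)
        assert scaled.weight == pytest.approx(base.weight, rel=1e-6)


class TestCollectionWeights:
    def make_gw(self, values, genes, tissues):
        w = pd.DataFrame(values, index=genes, columns=tissues, dtype=float)
        a = pd.DataFrame(1, index=genes, columns=tissues, dtype="int8")
        return weights.GeneWeightMatrix(e=w, a=a, w=w)

    def test_equal_group_distributions_give_minus_log_half(self):
        # members and complement hold identical multisets -> t = 0 exactly
        genes = [f"G{i}" for i in range(100)]
        vals = np.concatenate([np.arange(50.0), np.arange(50.0)])
        gw = self.make_gw({"t": vals}, genes, ["t"])
        gsc = io.GeneSetCollection(
            [io.GeneSet("HALF", "", tuple(genes[:50])), io.GeneSet("ALL2", "", tuple(genes[50:]))]
        )
        sw = weights.collection_weights(gw, gsc)
        assert sw.w.at["HALF", "t"] == pytest.approx(-math.log(0.5), rel=1e-9)

    def test_matches_scalar_set_weight_per_set(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(60)]
        gw = self.make_gw(rng.lognormal(size=(60, 2)), genes, ["a", "b"])
        members = tuple(rng.choice(genes, size=12, replace=False))
        gsc = io.GeneSetCollection(
            [io.GeneSet("S", "", members), io.GeneSet("REST", "", tuple(genes))]
        )
        sw = weights.collection_weights(gw, gsc)
        for tissue in ("a", "b"):
            comp = [g for g in genes if g not in members]
            ref = weights.set_weight(
                gw.w.loc[list(members), tissue], gw.w.loc[comp, tissue]
            )
            assert sw.w.at["S", tissue] == pytest.approx(ref.weight, rel=1e-9)

    def test_unmeasured_universe_genes_weigh_zero(self):
        genes = [f"G{i}" for i in range(10)]
        gw = self.make_gw(np.ones((10, 1)) + np.arange(10)[:, None], genes, ["t"])
        # set members partly outside the measured genes
        gsc = io.GeneSetCollection(
            [io.GeneSet("S", "", ("G1", "G2", "X1", "X2")),
             io.GeneSet("BG", "", tuple(genes))]
        )
        sw = weights.collection_weights(gw, gsc)
        member_vals = [gw.w.at["G1", "t"], gw.w.at["G2", "t"], 0.0, 0.0]
        comp = [g for g in genes if g not in ("G1", "G2")]
        ref = weights.set_weight(member_vals, gw.w.loc[comp, "t"])
        assert sw.w.at["S", "t"] == pytest.approx(ref.weight, rel=1e-9)
        assert sw.n_used["S"] == 4

    def test_restrict_to_measured_drops_unknown_genes(self):
        genes = [f"G{i}" for i in range(10)]
        rng = np.random.default_rng(3)
        gw = self.make_gw(rng.lognormal(size=(10, 1)), genes, ["t"])
        gsc = io.GeneSetCollection(
            [io.GeneSet("S", "", ("G1", "G2", "X1", "X2")),
             io.GeneSet("BG", "", tuple(genes))]
        )
        sw = weights.collection_weights(gw, gsc, restrict_to_measured=True)
        assert sw.n_used["S"] == 2

    def test_small_set_flagged_undefined(self):
        genes = [f"G{i}" for i in range(20)]
        rng = np.random.default_rng(4)
        gw = self.make_gw(rng.lognormal(size=(20, 1)), genes, ["t"])
        gsc = io.GeneSetCollection(
            [io.GeneSet("TINY", "", ("G1",)), io.GeneSet("BG", "", tuple(genes))]
        )
        sw = weights.collection_weights(gw, gsc, min_set_size=2)
        assert math.isnan(sw.w.at["TINY", "t"])
        assert sw.flags.at["TINY", "t"] == "too_few_members"

    def test_gene_order_permutation_changes_nothing(self, small_bundle):
        expr, ihc, gsc, _ = small_bundle
        gw = weights.gene_weights(expr, ihc)
        sw1 = weights.collection_weights(gw, gsc)
        perm = np.random.default_rng(0).permutation(len(gw.w))
        gw2 = weights.GeneWeightMatrix(
            e=gw.e.iloc[perm], a=gw.a.iloc[perm], w=gw.w.iloc[perm]
        )
        sw2 = weights.collection_weights(gw2, gsc)
        pd.testing.assert_frame_equal(sw1.w, sw2.w)

    def test_tissue_scale_invariance(self, small_bundle):
        expr, ihc, gsc, _ = small_bundle
        gw = weights.gene_weights(expr, ihc)
        sw1 = weights.collection_weights(gw, gsc)
        scaled = gw.e * 7.5
        gw2 = weights.GeneWeightMatrix(e=scaled, a=gw.a, w=scaled * gw.a.astype(float))
        sw2 = weights.collection_weights(gw2, gsc)
        assert np.allclose(sw1.w.to_numpy(), sw2.w.to_numpy(), rtol=1e-7, equal_nan=True)

    def test_empty_universe_rejected(self):
        gw = self.make_gw(np.ones((2, 1)), ["G1", "G2"], ["t"])
        gsc = io.GeneSetCollection([io.GeneSet("S", "", ("X1", "X2", "X3"))])
        with pytest.raises(ValueError, match="empty gene universe"):
            weights.collection_weights(gw, gsc, restrict_to_measured=True)


class TestMultiTissueWeight:
    def test_minimum_of_components(self, toy_sw):
        mtw = weights.multi_tissue_weight(toy_sw, ["liver", "pancreas", "muscle", "adipose"])
        assert mtw.w["SET_A"] == 1.1

    def test_single_tissue_is_identity(self, toy_sw):
        mtw = weights.multi_tissue_weight(toy_sw, ["liver"])
        pd.testing.assert_series_equal(
            mtw.w, toy_sw.w["liver"], check_names=False
        )

    def test_undefined_component_excludes_set(self, toy_sw):
        mtw = weights.multi_tissue_weight(toy_sw, ["liver", "pancreas"])
        assert "SET_C" not in mtw.w.index
        assert "pancreas" in mtw.excluded["SET_C"]

    def test_missing_tissue_named_in_error(self, toy_sw):
        with pytest.raises(ValueError, match="kidney"):
            weights.multi_tissue_weight(toy_sw, ["liver", "kidney"])

    def test_min_weight_shrinks_with_more_tissues(self, toy_sw):
        small = weights.multi_tissue_weight(toy_sw, ["liver", "muscle"])
        big = weights.multi_tissue_weight(toy_sw, ["liver", "muscle", "adipose"])
        common = big.w.index.intersection(small.w.index)
        assert (big.w[common] <= small.w[common] + 1e-15).all()

    def test_mean_aggregator(self, toy_sw):
        mtw = weights.multi_tissue_weight(toy_sw, ["liver", "muscle"], aggregator="mean")
        assert mtw.w["SET_A"] == pytest.approx((3.7 + 5.0) / 2)
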