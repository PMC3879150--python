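"""Replicate averaging, expression filtering, TE fold-change classification,
set overlaps, replicate QC and TE-change clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from riboupr import (
    average_replicates,
    build_expression_table,
    classify_regulation,
    cluster_te_changes,
    compute_te,
    filter_low_expression,
    overlap_sets,
    regulated_set,
    replicate_correlation,
)

COND_MAP = {"w1": "WT", "w2": "WT", "m1": "mut", "m2": "mut"}


def table(fp_rows, mrna_rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(fp_rows))]
    cols = list(COND_MAP)
    fp = pd.DataFrame(fp_rows, index=genes, columns=cols, dtype=float)
    mr = pd.DataFrame(mrna_rows, index=genes, columns=cols, dtype=float)
    return build_expression_table(fp, mr, COND_MAP, "WT")


class TestAveraging:
    def test_two_replicates(self):
        rpkm = pd.DataFrame({"a": [10.0], "b": [20.0]}, index=["g"])
        out = average_replicates(rpkm, {"c": ["a", "b"]})
        assert out.loc["g", "c"] == 15.0

    def test_single_replicate_passthrough(self):
        rpkm = pd.DataFrame({"a": [7.0]}, index=["g"])
        out = average_replicates(rpkm, {"c": ["a"]})
        assert out.loc["g", "c"] == 7.0

    def test_matches_columnwise_mean_oracle(self):
        rng = np.random.default_rng(1)
        rpkm = pd.DataFrame(rng.random((100, 4)), columns=list(COND_MAP))
        out = average_replicates(rpkm, {"WT": ["w1", "w2"], "mut": ["m1", "m2"]})
        expected = np.stack(
            [(rpkm["w1"] + rpkm["w2"]) / 2, (rpkm["m1"] + rpkm["m2"]) / 2], axis=1
        )
        assert np.allclose(out.to_numpy(), expected, atol=1e-15)

    def test_unknown_sample_rejected(self):
        rpkm = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError):
            average_replicates(rpkm, {"c": ["a", "nope"]})


class TestExpressionFilter:
    def test_below_threshold_in_reference_excluded(self):
        expr = table([[9.9, 9.9, 50, 50]], [[50, 50, 50, 50]])
        assert not expr.pass_filter["footprint"].loc["g0", "mut"]

    def test_exactly_at_threshold_included(self):
        expr = table([[10.0, 10.0, 10.0, 10.0]], [[10.0, 10.0, 10.0, 10.0]])
        assert expr.pass_filter["footprint"].loc["g0", "mut"]
        assert expr.pass_filter["te"].loc["g0", "mut"]

    def test_mixed_fixture_matches_bruteforce_scan(self):
        rng = np.random.default_rng(2)
        fp = rng.uniform(0, 30, size=(200, 4))
        mr = rng.uniform(0, 30, size=(200, 4))
        expr = table(fp, mr)
        for i in range(200):
            want = (fp[i, :2].mean() >= 10) and (fp[i, 2:].mean() >= 10)
            assert bool(expr.pass_filter["footprint"].iloc[i, 0]) == want

    def test_raising_threshold_never_adds_genes(self):
        rng = np.random.default_rng(3)
        expr = table(rng.uniform(0, 40, (150, 4)), rng.uniform(0, 40, (150, 4)))
        higher = filter_low_expression(expr, 20.0)
        for axis in ("footprint", "mrna", "te"):
            gained = higher.pass_filter[axis] & ~expr.pass_filter[axis]
            assert not gained.any().any()

    def test_negative_threshold_rejected(self):
        expr = table([[10] * 4], [[10] * 4])
        with pytest.raises(ValueError):
            filter_low_expression(expr, -1)


class TestTE:
    def test_te_is_footprint_over_mrna(self):
        fp = pd.DataFrame({"c": [30.0]}, index=["g"])
        mr = pd.DataFrame({"c": [60.0]}, index=["g"])
        assert compute_te(fp, mr).loc["g", "c"] == 0.5

    def test_equal_signals_give_unity(self):
        fp = pd.DataFrame({"c": [42.0]}, index=["g"])
        assert compute_te(fp, fp).loc["g", "c"] == 1.0

    def test_zero_mrna_flagged_not_propagated(self):
        fp = pd.DataFrame({"c": [30.0]}, index=["g"])
        mr = pd.DataFrame({"c": [0.0]}, index=["g"])
        assert math.isnan(compute_te(fp, mr).loc["g", "c"])

    def test_te_fold_change_identity(self):
        """log2 TE FC == log2 footprint FC - log2 mRNA FC, to 1e-12."""
        rng = np.random.default_rng(4)
        expr = table(rng.uniform(10, 500, (300, 4)), rng.uniform(10, 500, (300, 4)))
        lhs = expr.log2fc["te"]["mut"]
        rhs = expr.log2fc["footprint"]["mut"] - expr.log2fc["mrna"]["mut"]
        mask = lhs.notna()
        assert mask.any()
        assert np.allclose(lhs[mask], rhs[mask], atol=1e-12)


class TestClassification:
    def test_exact_boundary_is_unchanged(self):
        # log2 FC exactly 0.6: the strict rule leaves the gene unchanged
        fp = [[100.0, 100.0, 100.0 * 2**0.6, 100.0 * 2**0.6]]
        expr = table(fp, [[100.0] * 4])
        calls = classify_regulation(expr)
        row = calls[(calls.gene_id == "g0") & (calls.axis == "footprint")]
        assert row.direction.item() == "unchanged"

    def test_1p52_fold_is_up(self):
        fp = [[100.0, 100.0, 152.0, 152.0]]
        expr = table(fp, [[100.0] * 4])
        calls = classify_regulation(expr)
        row = calls[(calls.gene_id == "g0") & (calls.axis == "footprint")]
        assert row.direction.item() == "up"
        assert row.log2fc.item() == pytest.approx(math.log2(1.52))

    def test_te_1p6_fold_is_up(self):
        # TE 1.0 -> 1.6: log2 change ~ 0.678 > 0.6
        expr = table([[100.0, 100.0, 160.0, 160.0]], [[100.0] * 4])
        calls = classify_regulation(expr)
        row = calls[(calls.gene_id == "g0") & (calls.axis == "te")]
        assert row.log2fc.item() == pytest.approx(math.log2(1.6))
        assert row.direction.item() == "up"

    def test_strong_translational_induction_called_up(self):
        """A HAC1-like gene with a 12-fold footprint increase at flat mRNA is
        footprint-up and TE-up."""
        expr = table([[50.0, 50.0, 600.0, 600.0]], [[80.0] * 4])
        calls = classify_regulation(expr)
        for axis in ("footprint", "te"):
            row = calls[(calls.gene_id == "g0") & (calls.axis == axis)]
            assert row.direction.item() == "up"

    def test_directions_partition_passing_genes(self):
        rng = np.random.default_rng(6)
        expr = table(rng.uniform(0, 400, (250, 4)), rng.uniform(0, 400, (250, 4)))
        calls = classify_regulation(expr)
        for axis in ("footprint", "mrna", "te"):
            passing = set(expr.pass_filter[axis].index[expr.pass_filter[axis]["mut"]])
            sub = calls[(calls.axis == axis) & (calls.condition == "mut")]
            assert set(sub.gene_id) == passing
            assert not sub.gene_id.duplicated().any()

    def test_unknown_reference_rejected(self):
        fp = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            build_expression_table(fp, fp, {"a": "WT"}, "nope")


class TestOverlap:
    def test_counts(self):
        assert overlap_sets({"a", "b", "c"}, {"b", "c", "d"}) == (3, 3, 2)

    def test_disjoint(self):
        assert overlap_sets({"a"}, {"b"}) == (1, 1, 0)

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(7)
        a = {f"id{i}" for i in rng.integers(0, 1000, 500)}
        b = {f"id{i}" for i in rng.integers(0, 1000, 500)}
        brute = sum(1 for x in a for y in b if x == y)
        assert overlap_sets(a, b) == (len(a), len(b), brute)


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        rpkm = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert replicate_correlation(rpkm, ("a", "b")) == pytest.approx(1.0)

    def test_inverse_trend(self):
        # log2 of one replicate is the negation trend of the other
        x = np.array([1.0, 2.0, 4.0, 8.0])
        rpkm = pd.DataFrame({"a": x, "b": 16.0 / x})
        assert replicate_correlation(rpkm, ("a", "b")) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(3, 1, 2000)
        rpkm = pd.DataFrame(
            {"a": rng.poisson(mu) + 0.0, "b": rng.poisson(mu) + 0.0}
        )
        r = replicate_correlation(rpkm, ("a", "b"))
        mask = (rpkm["a"] > 0) & (rpkm["b"] > 0)
        x, y = np.log2(rpkm["a"][mask]), np.log2(rpkm["b"][mask])
        manual = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_constant_vector_flagged(self):
        rpkm = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            assert math.isnan(replicate_correlation(rpkm, ("a", "b")))


class TestClustering:
    def frame(self, rows, genes):
        return pd.DataFrame(rows, index=genes, columns=["c1", "c2", "c3"], dtype=float)

    def test_identical_rows_merge_first_at_zero(self):
        mat = self.frame([[1, 2, 3], [1, 2, 3], [3, 1, 2]], ["a", "b", "c"])
        res = cluster_te_changes(mat)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_three_row_hand_worked_merge_order(self):
        # a ~ b (r=1, d=0); c anti-correlates with both (d=2);
        # average linkage: merge {a,b} at 0, then with c at (2+2)/2 = 2
        mat = self.frame([[1, 2, 3], [2, 4, 6], [3, 2, 1]], ["a", "b", "c"])
        res = cluster_te_changes(mat)
        assert {int(res.linkage[0][0]), int(res.linkage[0][1])} == {0, 1}
        assert res.linkage[0][2] == pytest.approx(0.0, abs=1e-12)
        assert res.linkage[1][2] == pytest.approx(2.0, abs=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        mat = self.frame(rng.normal(size=(12, 3)), [f"g{i:02d}" for i in range(12)])
        shuffled = mat.sample(frac=1.0, random_state=1)
        a = cluster_te_changes(mat)
        b = cluster_te_changes(shuffled)
        assert a.leaf_order == b.leaf_order
        assert np.allclose(a.linkage, b.linkage)

    def test_restriction_to_regulated_genes(self):
        mat = self.frame([[0.1, 0.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.2, 0.0]],
                         ["a", "b", "c"])
        res = cluster_te_changes(mat, min_abs_log2=0.6)
        assert res.gene_ids == ["b", "c"]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_te_changes(self.frame([[1, 2, 3]], ["a"]))


@given(st.floats(min_value=10.0, max_value=1e4))
def test_filter_monotone_in_threshold(threshold):
    rng = np.random.default_rng(10)
    expr = table(rng.uniform(0, 2e4, (50, 4)), rng.uniform(0, 2e4, (50, 4)))
    higher = filter_low_expression(expr, threshold)
    base = filter_low_expression(expr, 10.0)
    for axis in ("footprint", "mrna", "te"):
        assert not (higher.pass_filter[axis] & ~base.pass_filter[axis]).any().any()
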