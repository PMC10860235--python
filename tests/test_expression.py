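"""Expression filtering, differential testing and specific-gene calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcoskg import expression, simulate
from pcoskg.config import SimConfig


def textbook_t_pvalue(a, b):
    """Independent oracle: equal-variance two-sample t from the formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


class TestFilterLowExpression:
    @pytest.mark.parametrize(
        "row_mean,kept",
        [(0.05, False), (0.1, True), (0.15, True)],
    )
    def test_threshold_boundary(self, row_mean, kept):
        X = pd.DataFrame({"s1": [row_mean], "s2": [row_mean]}, index=["g"])
        out = expression.filter_low_expression(X, threshold=0.1)
        assert ("g" in out.index) == kept

    def test_all_zero_matrix_warns_empty(self):
        X = pd.DataFrame(np.zeros((3, 4)), index=list("abc"))
        with pytest.warns(UserWarning):
            out = expression.filter_low_expression(X, 0.1)
        assert out.empty

    def test_samples_unchanged(self, toy_matrix):
        out = expression.filter_low_expression(toy_matrix, 0.1)
        assert list(out.columns) == list(toy_matrix.columns)
        assert set(out.index) == {"g1", "g2", "g4"}


class TestDifferentialTest:
    def test_agrees_with_textbook_formula(self, rng):
        X = pd.DataFrame(
            rng.lognormal(1, 0.5, (50, 8)),
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{i}" for i in range(8)],
        )
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=X.columns)
        res = expression.differential_test(X, labels, "A", "B")
        for g in X.index:
            expected = textbook_t_pvalue(X.loc[g][:4], X.loc[g][4:])
            assert res.loc[g, "p_value"] == pytest.approx(expected, abs=1e-10)

    def test_fold_change_is_mean_ratio(self):
        X = pd.DataFrame([[10.0, 10, 10, 4, 4, 4]], index=["g"],
                         columns=list("abcdef"))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=X.columns)
        res = expression.differential_test(X, labels, "A", "B")
        assert res.loc["g", "fold_change"] == pytest.approx(2.5)

    def test_identical_values_convention(self):
        X = pd.DataFrame([[5.0] * 6], index=["g"], columns=list("abcdef"))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=X.columns)
        res = expression.differential_test(X, labels, "A", "B")
        assert res.loc["g", "p_value"] == 1.0
        assert res.loc["g", "fold_change"] == 1.0

    def test_zero_variance_unequal_means(self):
        X = pd.DataFrame([[2.0, 2, 2, 1, 1, 1]], index=["g"], columns=list("abcdef"))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=X.columns)
        res = expression.differential_test(X, labels, "A", "B")
        assert res.loc["g", "p_value"] == 0.0
        assert res.loc["g", "fold_change"] == pytest.approx(2.0)

    def test_zero_denominator_gives_infinite_fold(self):
        X = pd.DataFrame([[3.0, 4, 5, 0, 0, 0]], index=["g"], columns=list("abcdef"))
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=X.columns)
        res = expression.differential_test(X, labels, "A", "B")
        assert np.isinf(res.loc["g", "fold_change"])

    def test_small_group_rejected(self, toy_matrix):
        labels = pd.Series(["A", "B", "B", "B", "B", "B"], index=toy_matrix.columns)
        with pytest.raises(ValueError, match=">= 2 samples"):
            expression.differential_test(toy_matrix, labels, "A", "B")

    def test_planted_effect_detected(self, rng):
        # 8x effect with small noise at n=4/group must clear p < 0.05
        base = rng.lognormal(2, 0.1, (20, 8))
        base[:, 4:] *= 8.0
        X = pd.DataFrame(base, index=[f"g{i}" for i in range(20)],
                         columns=[f"s{i}" for i in range(8)])
        labels = pd.Series(["B"] * 4 + ["A"] * 4, index=X.columns)
        res = expression.differential_test(X, labels, "A", "B")
        assert (res["p_value"] < 0.05).all()
        assert (res["fold_change"] > 2).all()


class TestCallDifferentiated:
    def _d(self, p, fc):
        return pd.DataFrame({"p_value": [p], "fold_change": [fc]}, index=["g"])

    @pytest.mark.parametrize(
        "d1,d2,included",
        [
            ((0.04, 2.5), (0.8, 1.0), True),   # hit in d1 only
            ((0.04, 1.5), (0.04, 1.5), False),  # fold-change condition fails
            ((0.06, 3.0), (0.06, 3.0), False),  # p condition fails
            ((0.8, 1.0), (0.01, 0.4), True),    # down-regulation hit in d2
            ((0.05, 3.0), (0.5, 1.0), False),   # p boundary is strict
            ((0.04, 2.0), (0.5, 1.0), False),   # fc upper boundary is strict
            ((0.04, 0.5), (0.5, 1.0), False),   # fc lower boundary is strict
        ],
    )
    def test_threshold_logic(self, d1, d2, included):
        got = expression.call_differentiated(self._d(*d1), self._d(*d2))
        assert (got == {"g"}) == included

    def test_mismatched_gene_sets_rejected(self):
        d1 = pd.DataFrame({"p_value": [0.01], "fold_change": [3.0]}, index=["g1"])
        d2 = pd.DataFrame({"p_value": [0.01], "fold_change": [3.0]}, index=["g2"])
        with pytest.raises(ValueError):
            expression.call_differentiated(d1, d2)


class TestCallSpecific:
    def test_planted_recovery(self, small_config):
        X, labels, truth = simulate.generate_expression(small_config)
        X = expression.filter_low_expression(X)
        na = expression.call_specific(X, labels, "NA")
        assert len(na & truth.specific_na) >= 8

    def test_gene_highest_in_nm_excluded(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            rng.lognormal(1, 0.05, (5, 12)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(12)],
        )
        labels = pd.Series(["NM"] * 4 + ["NA"] * 4 + ["HA"] * 4, index=X.columns)
        X.loc["g0", labels[labels == "NM"].index] *= 50  # strong NM gene
        assert "g0" not in expression.call_specific(X, labels, "NA")
        assert "g0" not in expression.call_specific(X, labels, "HA")

    def test_specific_sets_disjoint(self, expression_data):
        X, labels, _ = expression_data
        na = expression.call_specific(X, labels, "NA")
        ha = expression.call_specific(X, labels, "HA")
        assert not na & ha

    def test_filter_then_test_commutes(self, expression_data):
        X, labels, _ = expression_data
        filtered = expression.filter_low_expression(X, 0.1)
        d_after = expression.differential_test(filtered, labels, "NA", "NM")
        d_before = expression.differential_test(X, labels, "NA", "NM").loc[
            filtered.index
        ]
        pd.testing.assert_frame_equal(d_after, d_before)


class TestMergeAndNormalize:
    def test_gene_intersection(self, rng):
        genes1 = [f"g{i}" for i in range(100)]
        genes2 = [f"g{i}" for i in range(50, 150)]
        X1 = pd.DataFrame(rng.lognormal(1, 1, (100, 4)), index=genes1,
                          columns=[f"a{i}" for i in range(4)])
        X2 = pd.DataFrame(rng.lognormal(1, 1, (100, 4)), index=genes2,
                          columns=[f"b{i}" for i in range(4)])
        lab1 = pd.Series(["NM"] * 4, index=X1.columns)
        lab2 = pd.Series(["PCOS"] * 4, index=X2.columns)
        merged, labels = expression.merge_and_normalize([X1, X2], [lab1, lab2])
        assert len(merged) == 50
        assert merged.shape[1] == 8
        assert len(labels) == 8

    def test_identical_sorted_columns(self, rng):
        X = pd.DataFrame(rng.lognormal(1, 1, (60, 5)),
                         index=[f"g{i}" for i in range(60)],
                         columns=[f"s{i}" for i in range(5)])
        lab = pd.Series(["NM"] * 5, index=X.columns)
        merged, _ = expression.merge_and_normalize([X], [lab])
        sorted_cols = np.sort(merged.to_numpy(), axis=0)
        for j in range(1, sorted_cols.shape[1]):
            assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_rank_order_preserved_merging_with_self(self, rng):
        X = pd.DataFrame(rng.lognormal(1, 1, (40, 3)),
                         index=[f"g{i}" for i in range(40)],
                         columns=["s1", "s2", "s3"])
        lab = pd.Series(["NM"] * 3, index=X.columns)
        merged, _ = expression.merge_and_normalize([X, X], [lab, lab])
        for pre in ("ds1", "ds2"):
            for s in ("s1", "s2", "s3"):
                orig = X[s].rank().sort_index()
                new = merged[f"{pre}:{s}"].rank().sort_index()
                assert (orig.to_numpy() == new.to_numpy()).all()

    def test_empty_intersection_rejected(self, rng):
        X1 = pd.DataFrame(rng.lognormal(1, 1, (5, 2)), index=list("abcde"),
                          columns=["s1", "s2"])
        X2 = pd.DataFrame(rng.lognormal(1, 1, (5, 2)), index=list("fghij"),
                          columns=["t1", "t2"])
        lab = pd.Series(["NM"] * 2)
        with pytest.raises(ValueError, match="shared"):
            expression.merge_and_normalize(
                [X1, X2],
                [pd.Series(["NM"] * 2, index=X1.columns),
                 pd.Series(["NM"] * 2, index=X2.columns)],
            )
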