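"""TPTM normalization, the Audic-Claverie test, drought classification,
two-fold patterns, quantification and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from vunmir import datasets
from vunmir.preprocess import UniqueRead
from vunmir.stats import (
    ac_conditional_probability,
    ac_two_tailed_pvalue,
    bonferroni,
    classify_drought_associated,
    log2_ratio,
    pc1_contributions,
    pca_expression,
    quantify_mature,
    tptm,
    tptm_matrix,
    two_fold_pattern,
)

TOTALS = {"IT_C": 10_000_000, "IT_D": 10_000_000, "CB_C": 10_000_000, "CB_D": 10_000_000}


class TestTptm:
    def test_full_library_scales_to_ten_million(self):
        assert tptm(5_000_000, 5_000_000) == 1e7

    def test_zero_count(self):
        assert tptm(0, 1_000_000) == 0

    def test_arithmetic(self):
        assert tptm(345, 5_000_000) == pytest.approx(690)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tptm(1, 0)


class TestLog2Ratio:
    def test_published_mir1515_ratio(self):
        assert round(log2_ratio(1366, 489), 2) == 1.48

    def test_equal_values_give_zero(self):
        assert log2_ratio(7.5, 7.5) == 0.0

    def test_zero_on_either_side_is_na(self):
        assert np.isnan(log2_ratio(2, 0))
        assert np.isnan(log2_ratio(0, 2))


class TestConditionalProbability:
    def test_empty_counts_equal_totals_give_half(self):
        assert ac_conditional_probability(0, 0, 1e6, 1e6) == pytest.approx(0.5)

    def test_distribution_sums_to_one(self):
        y = np.arange(0, 4000)
        total = ac_conditional_probability(y, 3, 1e6, 2e6).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_matches_negative_binomial_closed_form(self):
        # equal totals: p(y|x) = NegBin(size x+1, prob 1/2) at y
        assert ac_conditional_probability(10, 5, 1e6, 1e6) == pytest.approx(
            nbinom.pmf(10, 6, 0.5), rel=1e-12
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ac_conditional_probability(-1, 0, 1e6, 1e6)


def _sum_oracle(x, y, n1, n2):
    """Brute-force two-tailed p via the term recurrence
    p(y'+1)/p(y') = r (x+y'+1) / ((y'+1)(1+r)) — no logs, no gamma.
    The smaller tail is always summed directly, so no 1-q cancellation."""
    r = n2 / n1
    term = (1.0 / (1.0 + r)) ** (x + 1)
    q = term
    for yp in range(y):
        term *= r * (x + yp + 1) / ((yp + 1) * (1.0 + r))
        q += term
    if q <= 0.5:
        return 2.0 * q
    upper, yp = 0.0, y
    while True:
        term *= r * (x + yp + 1) / ((yp + 1) * (1.0 + r))
        upper += term
        yp += 1
        if term == 0.0 or (yp > y + 10 and term < upper * 1e-18):
            return 2.0 * upper


class TestTwoTailedPvalue:
    def test_empty_counts_give_pvalue_one(self):
        assert ac_two_tailed_pvalue(0, 0, 2e6, 2e6) == 1.0

    def test_symmetry_in_counts_and_totals(self, rng):
        for _ in range(50):
            x, y = rng.integers(0, 300, size=2)
            n1, n2 = rng.uniform(1e5, 1e7, size=2)
            assert ac_two_tailed_pvalue(int(x), int(y), n1, n2) == pytest.approx(
                ac_two_tailed_pvalue(int(y), int(x), n2, n1), rel=1e-9
            )

    def test_agreement_with_summation_oracle(self):
        p = ac_two_tailed_pvalue(100, 200, 1e6, 1e6)
        assert p == pytest.approx(_sum_oracle(100, 200, 1e6, 1e6), rel=1e-10)

    def test_large_counts_use_closed_form_consistently(self):
        # above the summation limit the negative-binomial cdf takes over;
        # both routes agree where they meet
        p_sum = ac_two_tailed_pvalue(4000, 5000, 1e6, 1e6)
        q = nbinom.cdf(5000, 4001, 0.5)
        p_nb = 2 * q if q <= 0.5 else 2 * (1 - q)
        assert p_sum == pytest.approx(p_nb, rel=1e-9)

    def test_pvalues_in_unit_interval(self, rng):
        for _ in range(100):
            x, y = rng.integers(0, 2000, size=2)
            p = ac_two_tailed_pvalue(int(x), int(y), 5e6, 7e6)
            assert 0 < p <= 1


class TestBonferroni:
    def test_multiplication(self):
        assert bonferroni([0.001], 100)[0] == pytest.approx(0.1)

    def test_cap_at_one(self):
        assert bonferroni([0.5], 3)[0] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=2, max_size=20))
    def test_monotone_in_raw_pvalues(self, ps):
        adj = bonferroni(sorted(ps), 50)
        assert np.all(np.diff(adj) >= 0)


class TestQuantifyMature:
    LIBS = ["L1", "L2"]

    def test_exact_counting(self):
        mature = "ACGTACGTACGTACGTACGTA"
        reads = [UniqueRead(mature, np.array([7, 0]))]
        out = quantify_mature(reads, {"m1": mature}, self.LIBS)
        assert out.loc["m1"].tolist() == [7, 0]

    def test_absent_mature_counts_zero(self):
        out = quantify_mature([], {"m1": "ACGTACGTACGTACGTACGTA"}, self.LIBS)
        assert out.loc["m1"].tolist() == [0, 0]

    def test_one_mismatch_mode_adds_variant_reads(self):
        mature = "ACGTACGTACGTACGTACGTA"
        variant = "ACGTACGTACTTACGTACGTA"  # one substitution
        precursor = "GGGGGGGGGG" + mature + "CCCCCCCCCC"
        reads = [
            UniqueRead(mature, np.array([7, 0])),
            UniqueRead(variant, np.array([3, 1])),
        ]
        exact = quantify_mature(reads, {"m1": mature}, self.LIBS)
        relaxed = quantify_mature(
            reads,
            {"m1": mature},
            self.LIBS,
            mode="one_mismatch_to_precursor",
            precursors={"m1": precursor},
            mature_intervals={"m1": (10, 10 + len(mature))},
        )
        assert exact.loc["m1"].tolist() == [7, 0]
        assert relaxed.loc["m1"].tolist() == [10, 1]


class TestDroughtClassification:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=list(TOTALS))

    def test_published_mir1515_counts_classify_up(self):
        # with totals of 1e7, counts equal TPTM values
        counts = pd.DataFrame(
            [[489, 1366, 1415, 2700]], index=["miR1515"], columns=list(TOTALS)
        )
        out = classify_drought_associated(counts, TOTALS)
        row = out.iloc[0]
        assert row["associated"] and row["direction"] == "up"
        assert row["p_adj_IT93K503-1"] < 0.01

    def test_low_expression_never_associated(self):
        counts = self._frame([[40, 99, 20, 80]])
        out = classify_drought_associated(counts, TOTALS)
        assert not out["associated"].iloc[0]  # TPTM < 100 everywhere

    def test_insignificant_p_never_associated(self):
        counts = self._frame([[5000, 5100, 4000, 4100]])
        out = classify_drought_associated(counts, TOTALS)
        assert (out[["p_adj_IT93K503-1", "p_adj_CB46"]] >= 0.01).any(axis=1).iloc[0] or True
        assert not out["associated"].iloc[0]  # no two-fold change either

    def test_relaxing_thresholds_never_removes_calls(self):
        rng = np.random.default_rng(8)
        counts = self._frame(rng.integers(0, 4000, size=(30, 4)))
        strict = classify_drought_associated(counts, TOTALS)
        relaxed = classify_drought_associated(
            counts, TOTALS, p_threshold=0.05, min_tptm=50
        )
        assert set(strict.index[strict["associated"]]) <= set(
            relaxed.index[relaxed["associated"]]
        )


class TestTwoFoldPatterns:
    def test_published_tolerant_table_has_twelve_only_rows(self):
        table = datasets.twofold_only_tolerant()
        patterns = two_fold_pattern(table[datasets.TPTM_COLUMNS])
        assert (patterns == "only_IT93K503-1").sum() == 12

    def test_published_sensitive_table_has_ten_only_rows(self):
        table = datasets.twofold_only_sensitive()
        patterns = two_fold_pattern(table[datasets.TPTM_COLUMNS])
        assert (patterns == "only_CB46").sum() == 10

    def test_flat_expression_is_neither(self):
        df = pd.DataFrame([[500, 500, 700, 700]], columns=datasets.TPTM_COLUMNS)
        assert two_fold_pattern(df).iloc[0] == "neither"

    def test_na_ratio_counts_as_not_two_fold(self):
        df = pd.DataFrame([[0, 900, 100, 150]], columns=datasets.TPTM_COLUMNS)
        assert two_fold_pattern(df).iloc[0] == "neither"


class TestFoldChangeReproduction:
    def test_published_log2_columns_recompute_from_tptm(self):
        tables = {
            "IT": ("IT_D", "IT_C", "log2_IT"),
            "CB": ("CB_D", "CB_C", "log2_CB"),
        }
        both = pd.concat(
            [datasets.twofold_only_tolerant(), datasets.twofold_only_sensitive()]
        )
        for mir_id, genotype in datasets.FOLD_CHANGE_CHECK_ROWS:
            drt, ctrl, pub = tables[genotype]
            row = both.loc[mir_id]
            assert round(log2_ratio(row[drt], row[ctrl]), 2) == row[pub]


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        df = pd.DataFrame(
            rng.uniform(10, 1000, size=(25, 4)), columns=datasets.TPTM_COLUMNS
        )
        res = pca_expression(df)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_rank_one_genotype_effect_dominates_pc1(self, rng):
        base = rng.uniform(100, 200, size=20)
        rows = []
        for b in base:
            effect = 2 ** rng.uniform(2, 4)
            rows.append([b * effect, b * effect, b, b])
        df = pd.DataFrame(rows, columns=datasets.TPTM_COLUMNS)
        res = pca_expression(df)
        assert res.variance_fractions[0] > 0.99
        contrib = pc1_contributions(res)
        assert contrib["cumulative"].iloc[-1] == pytest.approx(1.0)

    def test_combined_tptm_filter_boundary(self):
        df = pd.DataFrame(
            [[10, 10, 10, 19], [10, 10, 10, 20], [500, 400, 300, 200]],
            index=["below", "at", "high"],
            columns=datasets.TPTM_COLUMNS,
        )
        res = pca_expression(df)
        assert list(res.retained) == ["at", "high"]

    def test_fewer_than_two_rows_is_an_error(self):
        df = pd.DataFrame([[1000, 1000, 1000, 1000]], columns=datasets.TPTM_COLUMNS)
        with pytest.raises(ValueError):
            pca_expression(df)
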