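"""Yield tables, concordance metrics, association tests, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pkdpanel import (anova_onset, categorical_association, chi_square_statistic,
                      concordance_metrics, family_history_breakdown,
                      fisher_exact_2x2, multi_variant_rate, percent,
                      variant_spectrum, yield_table)
from pkdpanel.experiments import (reference_cohort_records,
                                  reference_early_onset_records,
                                  reference_family_history_records,
                                  reference_variant_spectrum)


class TestYieldTable:
    def test_reference_count_structure(self):
        """The 212-proband fixture reproduces its expected yield percentages."""
        yt = yield_table(reference_cohort_records())
        assert yt["all"]["positive_pct"] == 65.1
        assert yt["all"]["pkd1_pct"] == 85.5
        assert yt["all"]["pkd1_t_pct"] == 78.0
        assert yt["all"]["pkd2_pct"] == 14.5
        assert yt["confirmation"]["pkd1_t_pct"] == 89.3
        assert yt["validation"]["positive_pct"] == 100.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            yield_table(pd.DataFrame({"nosology": []}))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            yield_table(pd.DataFrame({"nosology": ["banana"]}))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.sampled_from(
        ["ADPKD-PKD1-T", "ADPKD-PKD1-NT", "ADPKD-PKD2", "PKD-VUS-only", "negative"]),
        min_size=1, max_size=80))
    def test_partition_and_rounding(self, labels):
        """Counts partition the cohort; complementary percentages sum to 100."""
        yt = yield_table(pd.DataFrame({"nosology": labels}))
        col = yt["all"]
        assert col["positive_n"] + col["negative_n"] == col["total"]
        assert col["pkd1_n"] + col["pkd2_n"] == col["positive_n"]
        assert col["pkd1_t_n"] + col["pkd1_nt_n"] == col["pkd1_n"]
        assert abs(col["positive_pct"] + col["negative_pct"] - 100.0) <= 0.1
        if col["pkd1_n"]:
            assert abs(col["pkd1_t_pct"] + col["pkd1_nt_pct"] - 100.0) <= 0.1


class TestFixtureBreakdowns:
    def test_family_history(self):
        fh = family_history_breakdown(reference_family_history_records())
        assert fh["n_no_family_history"] == 45
        assert fh["no_family_history_pct"] == 23.3
        assert fh["positive_pct"] == 68.9
        assert fh["pkd2_pct"] == 16.1

    def test_early_onset_two_variants(self):
        mv = multi_variant_rate(reference_early_onset_records())
        assert (mv["n"], mv["multi_variant_n"]) == (30, 7)
        assert mv["multi_variant_pct"] == 23.3

    def test_variant_spectrum(self):
        sp = variant_spectrum(reference_variant_spectrum())
        assert sp["all"]["n"] == 158
        assert sp["all"]["novel_pct"] == 50.6
        assert sp["all"]["truncating_pct"] == 63.3
        assert sp["all"]["share_PKD1_pct"] == 88.0
        assert sp["PKD1"]["novel_pct"] == 52.5


class TestConcordance:
    def test_false_positive_rate_among_positives(self):
        """221 test positives with 22 unconfirmed give a 10% FP rate."""
        test = {f"s{i}" for i in range(221)}
        gold = {f"s{i}" for i in range(199)}  # 22 unconfirmed, none missed
        res = concordance_metrics(test, gold)
        assert res.unconfirmed == 22
        assert res.false_positive_rate_pct == 10
        assert res.sensitivity_pct == 100

    def test_identical_sets(self):
        res = concordance_metrics({"a", "b"}, {"a", "b"})
        assert res.sensitivity_pct == 100 and res.false_positive_rate_pct == 0

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError, match="gold"):
            concordance_metrics({"a"}, set())

    def test_accuracy_symmetric_sensitivity_not(self):
        universe = {f"u{i}" for i in range(50)}
        test = {f"u{i}" for i in range(10)}
        gold = {f"u{i}" for i in range(5, 20)}
        a = concordance_metrics(test, gold, universe)
        b = concordance_metrics(gold, test, universe)
        assert a.accuracy_pct == b.accuracy_pct
        assert a.sensitivity_pct != b.sensitivity_pct


class TestAssociation:
    def test_small_cell_selects_fisher(self):
        res = categorical_association([[3, 20], [15, 12]])
        assert res.test == "fisher_exact"

    def test_large_cells_select_chi_square(self):
        res = categorical_association([[30, 20], [15, 12]])
        assert res.test == "chi_square"

    def test_identical_proportions_null(self):
        res = categorical_association([[50, 50], [100, 100]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_matches_naive_double_loop(self, rng):
        obs = rng.integers(5, 60, size=(2, 3)).astype(float)
        stat, dof = chi_square_statistic(obs)
        # naive double loop
        row = obs.sum(axis=1)
        col = obs.sum(axis=0)
        total = obs.sum()
        naive = 0.0
        for i in range(2):
            for j in range(3):
                e = row[i] * col[j] / total
                naive += (obs[i, j] - e) ** 2 / e
        assert stat == pytest.approx(naive)
        # independent implementation: scipy without continuity correction
        s2, p2, d2, _ = sps.chi2_contingency(obs, correction=False)
        assert stat == pytest.approx(s2)
        assert d2 == dof

    @pytest.mark.parametrize("table", [[[3, 7], [12, 2]], [[1, 9], [8, 4]],
                                       [[0, 10], [10, 0]], [[4, 4], [4, 4]]])
    def test_fisher_matches_scipy(self, table):
        p = fisher_exact_2x2(np.array(table))
        _, p_ref = sps.fisher_exact(table, alternative="two-sided")
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            categorical_association([[5, 5]])


class TestAnova:
    def test_identical_values_f_zero(self):
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                           "onset_age": [30.0] * 9})
        res = anova_onset(df, "onset_age", "g")
        assert res.f_statistic == 0.0

    def test_hand_computed_toy_table(self):
        """3 groups x 3 values checked against the by-hand decomposition."""
        df = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                           "onset_age": [1.0, 2, 3, 4, 5, 6, 7, 8, 9]})
        # group means 2, 5, 8; grand 5; SSB = 3*(9+0+9)=54; SSW = 2*3=6
        res = anova_onset(df, "onset_age", "g")
        assert res.f_statistic == pytest.approx((54 / 2) / (6 / 6))
        assert res.group_means == {"a": 2.0, "b": 5.0, "c": 8.0}

    def test_matches_scipy_f_oneway(self, rng):
        df = pd.DataFrame({
            "g": ["x"] * 20 + ["y"] * 25 + ["z"] * 15,
            "onset_age": np.concatenate([rng.normal(25, 8, 20),
                                         rng.normal(35, 8, 25),
                                         rng.normal(45, 8, 15)])})
        res = anova_onset(df, "onset_age", "g")
        f_ref, p_ref = sps.f_oneway(*[df.loc[df["g"] == g, "onset_age"]
                                      for g in "xyz"])
        assert res.f_statistic == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_small_group_rejected_by_name(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "onset_age": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="'b'"):
            anova_onset(df, "onset_age", "g")


class TestPercent:
    def test_half_up_rounding(self):
        assert percent(1, 8) == 12.5
        assert percent(25, 28) == 89.3
        assert percent(22, 221, 0) == 10.0
        with pytest.raises(ValueError):
            percent(1, 0)
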