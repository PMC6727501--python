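"""Accuracy tables, chi-square homogeneity, and ROC analysis."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from drgrasch import (
    ConfusionCounts,
    accuracy_table,
    auc_mann_whitney,
    case_correct,
    category_roc,
    category_table,
    item_level_roc,
    pearson_chi2_2x2,
)
from drgrasch.detection import ResidualCell, CaseScore
from drgrasch.evaluation import pearson_chi2_table, roc_points
from drgrasch.rasch import AbilityEstimate


def _score(case_id, year, z_by_item, threshold=2.0):
    cells = [
        ResidualCell(item_id=i, O=0.5, E=0.4, var=0.24, z=z, raw_fee=1.0)
        for i, z in z_by_item.items()
    ]
    flagged = frozenset(i for i, z in z_by_item.items() if z > threshold)
    return CaseScore(
        case_id=case_id,
        drg_code="D1",
        year=year,
        ability=AbilityEstimate(0.0, 0.5, len(cells), True),
        cells=cells,
        outfit_mnsq=float(np.mean([z**2 for z in z_by_item.values()])),
        flagged_items=flagged,
        case_flagged=bool(flagged),
        threshold=threshold,
    )


class TestPearsonChi2:
    def test_year_table_from_audit_counts(self):
        """154/40 vs 164/30 correct/incorrect: chi2 = 1.743, p = 0.19."""
        chi2, p = pearson_chi2_2x2(154, 40, 164, 30)
        assert chi2 == pytest.approx(1.743, abs=1e-3)
        assert round(p, 2) == 0.19

    def test_identical_rows_give_zero(self):
        chi2, p = pearson_chi2_2x2(50, 50, 50, 50)
        assert chi2 == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "table, p2",
        [((120, 74, 116, 78), 0.68), ((132, 62, 126, 68), 0.52)],
    )
    def test_category_year_tables(self, table, p2):
        _, p = pearson_chi2_2x2(*table)
        assert round(p, 2) == p2

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2_2x2(0, 0, 5, 5)

    def test_row_column_exchange_invariant(self):
        a = pearson_chi2_2x2(20, 30, 40, 10)
        assert pearson_chi2_2x2(40, 10, 20, 30)[0] == pytest.approx(a[0])
        assert pearson_chi2_2x2(30, 20, 10, 40)[0] == pytest.approx(a[0])

    def test_matches_scipy_uncorrected(self):
        """Independent cross-check against scipy's Pearson statistic."""
        table = np.array([[154, 40], [164, 30]])
        ours = pearson_chi2_table(table)
        ref = chi2_contingency(table, correction=False)
        assert ours[0] == pytest.approx(ref.statistic)
        assert ours[1] == pytest.approx(ref.pvalue)


class TestCaseCorrect:
    def test_matched_needs_flag_on_deducted_item(self):
        s = _score("C", 2015, {"a": 3.62, "b": 0.1})
        assert case_correct(s, {"a": True, "b": False}, mode="matched") is True

    def test_mode_semantics_differ(self):
        s = _score("C", 2015, {"a": 1.5, "b": 2.5})
        labels = {"a": True, "b": False}
        assert case_correct(s, labels, mode="matched") is False
        assert case_correct(s, labels, mode="any") is True

    def test_no_deductions_not_evaluable_in_matched_mode(self):
        s = _score("C", 2015, {"a": 2.5})
        assert case_correct(s, {"a": False}, mode="matched") is None


class TestAccuracyTable:
    def test_pooled_rate_from_fixed_counts(self):
        """154+164 correct of 388 pools to 0.82."""
        pooled = ConfusionCounts(154 + 164, 40 + 30)
        assert round(pooled.rate, 2) == 0.82

    def test_counts_equal_brute_force_recount(self, study):
        """Table counts must equal an independent per-case recount."""
        scores = study["result"].scored()
        labels = study["labels"]
        table = accuracy_table(scores, labels, mode="matched")
        for year in ("2015", "2016"):
            recount = [
                bool(
                    {i for i, v in labels[s.case_id].items() if v}
                    & s.flagged_items
                )
                for s in scores
                if str(s.year) == year and s.case_id in labels
            ]
            assert table.strata[year].correct == sum(recount)
            assert table.strata[year].total == len(recount)

    def test_all_correct_gives_rate_one_chi2_zero(self):
        scores = [
            _score("A", 2015, {"a": 3.0}),
            _score("B", 2016, {"a": 2.6}),
        ]
        labels = {"A": {"a": True}, "B": {"a": True}}
        table = accuracy_table(scores, labels)
        assert table.pooled.rate == 1.0
        assert table.chi2 == 0.0 and table.p == 1.0

    def test_single_stratum_omits_test(self):
        scores = [_score("A", 2015, {"a": 3.0})]
        table = accuracy_table(scores, {"A": {"a": True}})
        assert table.chi2 is None and table.p is None


class TestCategoryTable:
    CMAP = {"d1": "drug", "d2": "drug", "m1": "material", "x1": "examination"}

    def test_agreement_counting(self):
        scores = [
            _score("A", 2015, {"d1": 3.0, "m1": 0.2, "x1": 0.1}),
            _score("B", 2015, {"d2": 0.5, "m1": 2.5, "x1": 0.0}),
        ]
        labels = {
            "A": {"d1": True, "m1": False, "x1": False},
            "B": {"d2": False, "m1": False, "x1": False},
        }
        tables = category_table(scores, labels, self.CMAP)
        # A: drug flagged & deducted -> correct; B: drug neither -> correct
        assert tables["drug"].pooled.rate == 1.0
        # B: material flagged but not deducted -> incorrect
        assert tables["material"].pooled.correct == 1
        # examination: no flags, no deductions anywhere -> rate 1.0
        assert tables["examination"].pooled.rate == 1.0

    def test_denominator_is_case_count(self, study):
        scores = study["result"].scored()
        labels = study["labels"]
        cmap = study["exp_set"].schema.category_map()
        tables = category_table(scores, labels, cmap)
        for t in tables.values():
            assert t.pooled.total == len(scores)

    def test_unmapped_item_rejected(self):
        scores = [_score("A", 2015, {"zz": 1.0})]
        with pytest.raises(ValueError, match="zz"):
            category_table(scores, {"A": {"zz": False}}, self.CMAP)


class TestAuc:
    def test_perfect_separation(self):
        r = auc_mann_whitney([2.0, 3.0, 0.0, 1.0], [True, True, False, False])
        assert r.auc == 1.0

    def test_all_ties_is_half(self):
        r = auc_mann_whitney([1.0] * 6, [True, False] * 3)
        assert r.auc == 0.5

    def test_matches_pair_counting_oracle(self):
        """Rank-based AUC equals exhaustive O(n^2) pair counting."""
        rng = np.random.default_rng(123)
        for _ in range(5):
            x = np.round(rng.normal(size=50), 1)  # rounding forces ties
            y = rng.random(50) < 0.4
            if y.all() or not y.any():
                continue
            r = auc_mann_whitney(x, y)
            pos, neg = x[y], x[~y]
            conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert r.auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_label_swap_duality(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=40)
        y = rng.random(40) < 0.5
        a = auc_mann_whitney(x, y).auc
        b = auc_mann_whitney(x, ~y).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1.0, 2.0], [True, True])

    def test_significance_grows_with_separation(self):
        rng = np.random.default_rng(21)
        y = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        weak = np.r_[rng.normal(0.2, 1, 100), rng.normal(0, 1, 100)]
        strong = np.r_[rng.normal(1.5, 1, 100), rng.normal(0, 1, 100)]
        assert (
            auc_mann_whitney(strong, y).p_vs_half
            < auc_mann_whitney(weak, y).p_vs_half
        )

    def test_roc_points_monotone_with_endpoints(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.random(30) < 0.5
        pts = roc_points(x, y)
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)


class TestPipelineRoc:
    def test_item_auc_beats_chance_on_injected_data(self, study):
        roc = item_level_roc(study["result"].scored(), study["labels"])
        assert roc.auc > 0.5
        assert roc.p_vs_half < 0.05

    def test_category_roc_keys_and_range(self, study):
        cmap = study["exp_set"].schema.category_map()
        rocs = category_roc(study["result"].scored(), study["labels"], cmap)
        assert set(rocs) <= {"drug", "material", "examination"}
        for r in rocs.values():
            assert 0.0 <= r.auc <= 1.0
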