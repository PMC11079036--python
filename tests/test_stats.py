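"""Power analysis, correlation, paired tests, cohort filter, Likert."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import arbbt as a
from arbbt.stats import (
    LIKERT_LEVELS,
    QUESTIONNAIRE_ITEMS,
    exclusion_reason,
    questionnaire_frame,
    study_table_frame,
)


class TestSampleSize:
    @pytest.mark.parametrize(
        "rho, power, expected",
        [
            (0.5, 0.80, 29),
            (0.5, 0.90, 38),
            (0.3, 0.80, 85),
        ],
    )
    def test_design_points(self, rho, power, expected):
        spec = a.PowerSpec(rho_H1=rho, alpha=0.05, power=power, tails=2)
        assert a.sample_size_for_correlation(spec) == expected

    def test_rho_zero_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            a.PowerSpec(rho_H1=0.0)

    def test_monotone_in_rho_power_alpha(self):
        """Required n: non-increasing in |rho| and alpha, non-decreasing
        in target power."""
        ns_rho = [
            a.sample_size_for_correlation(a.PowerSpec(rho_H1=r))
            for r in (0.2, 0.3, 0.5, 0.7)
        ]
        assert ns_rho == sorted(ns_rho, reverse=True)
        ns_power = [
            a.sample_size_for_correlation(a.PowerSpec(rho_H1=0.5, power=p))
            for p in (0.70, 0.80, 0.90, 0.95)
        ]
        assert ns_power == sorted(ns_power)
        ns_alpha = [
            a.sample_size_for_correlation(a.PowerSpec(rho_H1=0.5, alpha=al))
            for al in (0.01, 0.05, 0.10)
        ]
        assert ns_alpha == sorted(ns_alpha, reverse=True)

    def test_analytic_power_close_to_monte_carlo(self):
        analytic = a.correlation_power(38, 0.5)
        mc = a.monte_carlo_power(38, 0.5, n_sims=4000, seed=123)
        assert analytic == pytest.approx(mc, abs=0.03)

    def test_one_tailed_needs_fewer_subjects(self):
        two = a.sample_size_for_correlation(a.PowerSpec(rho_H1=0.5, tails=2))
        one = a.sample_size_for_correlation(a.PowerSpec(rho_H1=0.5, tails=1))
        assert one < two


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = a.pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.cohen_class == "large"

    def test_small_example_by_hand(self):
        # r = cov/(sx*sy) computed directly for x=[1,2,3], y=[1,2,4]
        res = a.pearson_correlation([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.9819805, abs=1e-6)
        assert res.df == 1

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert a.pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_zero_variance_names_vector(self):
        with pytest.raises(ValueError, match="zero variance in y"):
            a.pearson_correlation([1, 2, 3], [5, 5, 5])

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = 0.6 * x + rng.normal(size=40)
        base = a.pearson_correlation(x, y).r
        assert a.pearson_correlation(3.0 * x + 7.0, y).r == pytest.approx(base)
        assert a.pearson_correlation(x, 0.5 * y - 2.0).r == pytest.approx(base)
        assert a.pearson_correlation(-x, y).r == pytest.approx(-base)

    def test_t_and_p_consistent(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=31)
        y = 0.9 * x + 0.4 * rng.normal(size=31)
        res = a.pearson_correlation(x, y)
        t_manual = res.r * math.sqrt(res.df) / math.sqrt(1 - res.r**2)
        assert res.t_statistic == pytest.approx(t_manual)
        p_manual = 2 * sps.t.sf(abs(t_manual), res.df)
        assert res.p_two_tailed == pytest.approx(p_manual, rel=1e-6)


class TestCohenClass:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (0.5, "large"),
            (0.3, "medium"),
            (0.1, "small"),
            (0.05, "negligible"),
            (-0.6, "large"),
            (0.918, "large"),
            (0.29999, "small"),
        ],
    )
    def test_thresholds(self, r, expected):
        assert a.cohen_class(r) == expected


class TestPairedDecrease:
    def test_identical_vectors_degenerate(self):
        res = a.paired_decrease_test([3, 4, 5], [3, 4, 5])
        assert res.p_value == 1.0
        assert res.degenerate
        assert res.direction == "none"

    def test_large_decrease_detected_vs_closed_form(self):
        """Pairs with mean difference ~-24.7 (SD 5, n=31): decrease at
        p < 0.001, matching the closed-form paired-t computation."""
        rng = np.random.default_rng(8)
        bbt = rng.normal(36.64, 6.14, size=31)
        diffs = rng.normal(-24.7, 5.0, size=31)
        arbbt = bbt + diffs
        res = a.paired_decrease_test(arbbt, bbt)
        assert res.direction == "decrease"
        assert res.p_value < 0.001
        d = arbbt - bbt
        t_manual = d.mean() / (d.std(ddof=1) / math.sqrt(31))
        p_manual = 2 * sps.t.sf(abs(t_manual), 30)
        assert res.statistic == pytest.approx(t_manual)
        assert res.p_value == pytest.approx(p_manual, rel=1e-9)

    def test_swapping_arguments_flips_direction(self):
        rng = np.random.default_rng(9)
        x = rng.normal(10, 2, 20)
        y = x + rng.normal(5, 1, 20)
        r1 = a.paired_decrease_test(x, y)
        r2 = a.paired_decrease_test(y, x)
        assert r1.direction == "decrease" and r2.direction == "increase"
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_wilcoxon_alternative(self):
        rng = np.random.default_rng(10)
        x = rng.normal(10, 2, 25)
        y = x + np.abs(rng.normal(3, 1, 25))
        res = a.paired_decrease_test(x, y, method="wilcoxon")
        assert res.method == "wilcoxon"
        assert res.direction == "decrease"
        assert res.p_value < 0.01


class TestCohortFilter:
    def test_synthetic_screened_cohort_counts(self):
        records = a.synthetic_screened_cohort(seed=1)
        assert len(records) == 48
        included, tally = a.cohort_filter(records)
        assert len(included) == 31
        assert tally == {
            "neurological_comorbidity": 5,
            "rheumatoid_arthritis": 9,
            "joint_stiffness": 3,
        }

    def test_empty_input(self):
        included, tally = a.cohort_filter([])
        assert included == [] and tally == {}

    def test_conservation_and_idempotence(self):
        records = a.synthetic_screened_cohort(seed=2)
        included, tally = a.cohort_filter(records)
        assert len(included) + sum(tally.values()) == len(records)
        again, tally2 = a.cohort_filter(included)
        assert again == included and tally2 == {}

    def test_ashworth_and_time_rules(self):
        base = dict(patient_id="p", months_since_diagnosis=3.0, ashworth=2)
        ok = a.StudyRecord(**base)
        criteria = a.EligibilityCriteria()
        assert exclusion_reason(ok, criteria) is None
        spastic = a.StudyRecord(**{**base, "ashworth": 4})
        assert exclusion_reason(spastic, criteria) == "ashworth_above_max"
        chronic = a.StudyRecord(**{**base, "months_since_diagnosis": 9.0})
        assert exclusion_reason(chronic, criteria) == "time_since_incident"
        ischemic = a.StudyRecord(**{**base, "etiology": "ischemic stroke"})
        assert exclusion_reason(ischemic, criteria) == "etiology"

    def test_reason_precedence_comorbidity_first(self):
        rec = a.StudyRecord(
            patient_id="p",
            months_since_diagnosis=9.0,
            ashworth=4,
            comorbidities=("parkinson's disease", "rheumatoid arthritis"),
        )
        assert exclusion_reason(rec, a.EligibilityCriteria()) == (
            "neurological_comorbidity"
        )

    def test_missing_field_errors(self):
        rec = a.StudyRecord(patient_id="p42", months_since_diagnosis=1.0)
        with pytest.raises(ValueError, match="p42.*ashworth"):
            a.cohort_filter([rec])


class TestLikert:
    def test_fraction_rounding(self):
        counts = {"item": {"disagree": 14, "strongly disagree": 15, "agree": 2}}
        out = a.likert_summarize(counts, n=31)
        assert out.loc["item", "disagree_combined"] == 93.5  # 29/31
        assert out.loc["item", "agree_combined"] == 6.5

    def test_unanimity_and_zero(self):
        counts = {
            "all": {"agree": 31},
            "none": {"strongly agree": 0},
        }
        out = a.likert_summarize(counts, n=31)
        assert out.loc["all", "agree_combined"] == 100.0
        assert out.loc["none", "agree_combined"] == 0.0

    def test_counts_exceeding_n_error(self):
        with pytest.raises(ValueError, match="exceed"):
            a.likert_summarize({"q": {"agree": 40}}, n=31)

    def test_half_away_from_zero_rounding(self):
        # 7/28 = 25%, 5/8 = 62.5%; 0.125 -> 12.5, and half cases go up
        out = a.likert_summarize({"q": {"agree": 1}}, n=8)
        assert out.loc["q", "agree"] == 12.5
        out2 = a.likert_summarize({"q": {"agree": 29}}, n=31)
        assert out2.loc["q", "agree"] == 93.5

    def test_dataframe_input(self):
        records = [r for r in a.synthetic_screened_cohort(seed=3) if r.questionnaire]
        frame = questionnaire_frame(records)
        out = a.likert_summarize(frame)
        assert list(out.index) == list(QUESTIONNAIRE_ITEMS)
        row_sums = out[list(LIKERT_LEVELS)].sum(axis=1)
        assert np.all(np.abs(row_sums - 100.0) < 0.3)  # rounding slack


class TestGenerator:
    def test_large_sample_recovers_rho(self):
        x, y = a.generate_paired_scores(
            100_000, rho=0.918, seed=11, integerize=False
        )
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(0.918, abs=0.005)

    def test_null_rho_within_sampling_band(self):
        x, y = a.generate_paired_scores(100_000, rho=0.0, seed=12, integerize=False)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.02

    def test_seed_determinism_and_integerization(self):
        x1, y1 = a.generate_paired_scores(50, seed=13)
        x2, y2 = a.generate_paired_scores(50, seed=13)
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)
        assert np.all(x1 >= 0) and np.all(x1 == np.rint(x1))

    def test_moments_near_targets(self):
        x, y = a.generate_paired_scores(200_000, seed=14, integerize=False)
        assert x.mean() == pytest.approx(11.90, abs=0.05)
        assert y.mean() == pytest.approx(36.64, abs=0.1)
        assert x.std(ddof=1) == pytest.approx(2.11, abs=0.05)
        assert y.std(ddof=1) == pytest.approx(6.14, abs=0.1)


class TestConfidenceInterval:
    def test_interval_contains_point_and_shrinks(self):
        lo1, hi1 = a.r_confidence_interval(0.7, 20)
        lo2, hi2 = a.r_confidence_interval(0.7, 200)
        assert lo1 < 0.7 < hi1
        assert (hi2 - lo2) < (hi1 - lo1)


class TestStudyCsv:
    def test_round_trip(self, tmp_path):
        records = a.synthetic_screened_cohort(seed=4)
        path = tmp_path / "study.csv"
        a.write_study_csv(records, path)
        loaded = a.read_study_csv(path)
        assert loaded == records

    def test_frame_has_documented_header(self):
        frame = study_table_frame(a.synthetic_screened_cohort(seed=5))
        assert list(frame.columns[:3]) == ["patient_id", "bbt_score", "arbbt_score"]
        assert "q11" in frame.columns
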