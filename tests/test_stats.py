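"""Statistical layer: exact binomial intervals, predictive values, paired
relative NPV, random-effects pooling, SROC, rank-sum and the outcome model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from hfoarea.containers import ConfusionMatrix, HfoArea, PatientRecord
from hfoarea.stats import (
    LM_EFFECTS,
    clopper_pearson,
    diagnostic_summary,
    outcome_lm,
    pooled_or,
    pooled_proportion,
    rate_comparison,
    relative_npv_test,
    sroc,
)
from hfoarea.synthetic import CohortSpec, simulate_cohort


class TestClopperPearson:
    def test_reproduces_published_seizure_free_interval(self):
        lo, hi = clopper_pearson(74, 146)
        assert (round(lo * 100), round(hi * 100)) == (42, 59)

    def test_boundary_zero_successes(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and hi < 1.0

    def test_boundary_all_successes(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0

    def test_exact_beta_quantiles(self):
        lo, hi = clopper_pearson(31, 45)
        assert lo == pytest.approx(spstats.beta.ppf(0.025, 31, 15), abs=1e-12)
        assert hi == pytest.approx(spstats.beta.ppf(0.975, 32, 14), abs=1e-12)
        assert (round(lo, 3), round(hi, 3)) == (0.534, 0.818)

    def test_agrees_with_statsmodels_beta_method(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(3, 17), (40, 45), (74, 146)]:
            lo, hi = clopper_pearson(x, n)
            slo, shi = proportion_confint(x, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(slo, abs=1e-9)
            assert hi == pytest.approx(shi, abs=1e-9)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)


class TestDiagnosticSummary:
    def test_published_cells(self):
        ds = diagnostic_summary(ConfusionMatrix(TP=58, TN=31, FP=43, FN=14))
        assert ds.npv.point == pytest.approx(31 / 45)
        assert ds.ppv.point == pytest.approx(58 / 101)
        assert ds.sensitivity.point == pytest.approx(58 / 72)
        assert ds.specificity.point == pytest.approx(31 / 74)
        assert ds.accuracy.point == pytest.approx(89 / 146)

    def test_degenerate_comparator_marks_statistics_undefined(self):
        ds = diagnostic_summary(ConfusionMatrix(TP=0, TN=74, FP=0, FN=72))
        assert ds.npv.point == pytest.approx(74 / 146)
        assert ds.ppv is None and ds.sensitivity is None and ds.specificity is None

    def test_perfect_test(self):
        ds = diagnostic_summary(ConfusionMatrix(TP=10, TN=10, FP=0, FN=0))
        for name in ("ppv", "npv", "sensitivity", "specificity", "accuracy"):
            assert getattr(ds, name).point == 1.0


class TestRelativeNpv:
    def test_identical_tests_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        neg = rng.random(200) < 0.5
        good = rng.random(200) < 0.6
        r = relative_npv_test(neg, neg, good)
        assert r.rnpv == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)

    def test_study_ratio_from_published_cells(self):
        t1 = np.r_[np.ones(45), np.zeros(101)].astype(bool)  # crHFO-area calls
        t2 = np.ones(146, dtype=bool)  # RV comparator: all negative
        good = np.r_[np.ones(31), np.zeros(14), np.ones(43), np.zeros(58)].astype(bool)
        r = relative_npv_test(t1, t2, good)
        assert r.rnpv == pytest.approx((31 / 45) / (74 / 146), abs=1e-12)
        assert r.rnpv == pytest.approx(1.36, abs=0.005)
        assert r.ci_low < r.rnpv < r.ci_high
        assert r.p_value < 0.01

    def test_no_negative_calls_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            relative_npv_test(np.zeros(10, bool), np.ones(10, bool), np.ones(10, bool))


def _brute_dl(effects, variances):
    """Independent oracle: DerSimonian-Laird arithmetic written out directly."""
    w = 1 / variances
    fe = (w * effects).sum() / w.sum()
    q = (w * (effects - fe) ** 2).sum()
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (len(effects) - 1)) / c)
    wr = 1 / (variances + tau2)
    return (wr * effects).sum() / wr.sum(), tau2, q


class TestPooledProportion:
    def test_single_centre_returns_itself(self):
        m = pooled_proportion([(31, 45)])
        assert m.pooled_estimate == pytest.approx(31 / 45)
        assert m.i2 == 0.0
        lo, hi = clopper_pearson(31, 45)
        assert (m.ci_low, m.ci_high) == (lo, hi)

    def test_identical_centres_are_homogeneous(self):
        m = pooled_proportion([(7, 10)] * 5)
        assert m.pooled_estimate == pytest.approx(0.7, abs=1e-9)
        assert m.tau2 == 0.0 and m.i2 == 0.0

    def test_heterogeneous_centres_match_brute_force_oracle(self):
        m = pooled_proportion([(8, 10), (2, 10)])
        eff = np.array([np.log(8 / 2), np.log(2 / 8)])
        var = np.array([1 / 8 + 1 / 2, 1 / 2 + 1 / 8])
        pooled_t, tau2, q = _brute_dl(eff, var)
        assert m.pooled_estimate == pytest.approx(1 / (1 + np.exp(-pooled_t)), abs=1e-12)
        assert m.tau2 == pytest.approx(tau2, abs=1e-12)
        assert m.q == pytest.approx(q, abs=1e-12)
        assert 0.2 < m.pooled_estimate < 0.8 and m.q > 0

    def test_matches_statsmodels_when_heterogeneous(self):
        from statsmodels.stats.meta_analysis import combine_effects

        eff = np.array([0.5, -0.2, 0.9, 0.1])
        var = np.array([0.04, 0.05, 0.06, 0.03])
        res = combine_effects(eff, var, method_re="dl")
        pooled_t, tau2, _ = _brute_dl(eff, var)
        assert res.tau2 > 0  # non-truncated case: estimators coincide
        assert pooled_t == pytest.approx(float(res.mean_effect_re), abs=1e-10)
        assert tau2 == pytest.approx(float(res.tau2), abs=1e-10)

    def test_freeman_tukey_transform_available(self):
        m = pooled_proportion([(8, 10), (6, 10), (7, 12)], transform="freeman_tukey")
        assert 0.4 < m.pooled_estimate < 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pooled_proportion([(0, 0)])


class TestPooledOr:
    def test_single_table(self):
        m = pooled_or([(2, 1, 1, 2)])
        assert m.pooled_estimate == pytest.approx(4.0)

    def test_identical_tables_homogeneous(self):
        m = pooled_or([(20, 10, 10, 20)] * 4)
        assert m.pooled_estimate == pytest.approx(4.0, abs=1e-9)
        assert m.i2 == 0.0

    def test_whole_cohort_crude_odds_ratio(self):
        m = pooled_or([(31, 43, 14, 58)])
        assert m.pooled_estimate == pytest.approx((31 * 58) / (43 * 14), rel=1e-9)

    def test_empty_row_centre_excluded(self):
        m = pooled_or([(2, 1, 1, 2), (0, 0, 3, 4)], labels=["A", "B"])
        assert m.excluded == ["B"]
        assert m.pooled_estimate == pytest.approx(4.0)

    def test_swapping_rows_and_columns_preserves_or(self):
        tables = [(5, 3, 2, 7), (8, 2, 4, 6)]
        swapped = [(d, c, b, a) for a, b, c, d in tables]
        assert pooled_or(tables).pooled_estimate == pytest.approx(
            pooled_or(swapped).pooled_estimate, rel=1e-9
        )

    def test_transposing_rows_inverts_or(self):
        tables = [(5, 3, 2, 7), (8, 2, 4, 6)]
        flipped = [(c, d, a, b) for a, b, c, d in tables]
        assert pooled_or(flipped).pooled_estimate == pytest.approx(
            1 / pooled_or(tables).pooled_estimate, rel=1e-9
        )


class TestSroc:
    def test_chance_level_centres(self):
        s = sroc([(50, 50, 50, 50)] * 4, n_mc=50)
        assert s.auc == pytest.approx(0.5, abs=0.02)

    def test_near_perfect_centres(self):
        s = sroc([(99, 1, 99, 1)] * 4, n_mc=50)
        assert s.auc > 0.95

    def test_centre_order_invariance(self):
        tabs = [(20, 10, 8, 4), (15, 5, 12, 6), (30, 12, 10, 9)]
        s1 = sroc(tabs, n_mc=10)
        s2 = sroc(tabs[::-1], n_mc=10)
        assert s1.pooled_sensitivity == pytest.approx(s2.pooled_sensitivity, abs=1e-5)
        assert s1.auc == pytest.approx(s2.auc, abs=1e-5)

    def test_single_centre_rejected(self):
        with pytest.raises(ValueError, match="2 centres"):
            sroc([(10, 5, 8, 3)])

    def test_curve_monotone_nondecreasing(self):
        s = sroc([(20, 10, 8, 4), (15, 5, 12, 6), (30, 12, 10, 9)], n_mc=10)
        tpr = s.curve[:, 1]
        assert (np.diff(tpr) >= -1e-12).all()


class TestRateComparison:
    def test_identical_groups(self):
        stat, p = rate_comparison([1.0, 2.0, 3.5], [1.5, 2.5, 3.0])
        assert p > 0.5

    def test_exact_small_sample_extreme_ranking(self):
        _, p = rate_comparison([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)  # 2/20 orderings this extreme

    def test_large_separated_samples(self):
        rng = np.random.default_rng(0)
        a = rng.normal(4.0, 1.0, 366)
        b = rng.normal(2.1, 1.0, 21)
        _, p = rate_comparison(a, b)
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rate_comparison([], [1.0])


class TestOutcomeLm:
    def test_output_has_intercept_plus_nine_effects(self):
        pats = simulate_cohort(CohortSpec(n_centres=2, patients_per_centre=60, seed=0))
        lm = outcome_lm(pats)
        assert list(lm.table.index) == ["intercept"] + LM_EFFECTS
        assert lm.n == 120

    def test_fdr_never_below_raw_p(self):
        pats = simulate_cohort(CohortSpec(n_centres=2, patients_per_centre=60, seed=1))
        t = outcome_lm(pats).table.dropna(subset=["p_fdr"])
        assert (t["p_fdr"] >= t["p"] - 1e-12).all()

    def test_constant_outcome_gives_zero_slopes(self):
        pats = simulate_cohort(CohortSpec(n_centres=1, patients_per_centre=40,
                                          p_ilae1_given_cr=1.0, p_ilae1_given_noncr=0.0, seed=2))
        # every prediction correct -> y constant 1
        lm = outcome_lm(pats)
        assert (lm.table.loc[LM_EFFECTS, "estimate"].fillna(0.0) == 0.0).all()

    def test_quantization_levels(self):
        from hfoarea.stats import quantize_patient

        p = PatientRecord(
            patient_id="P1", centre_id="C1",
            hfo_area=HfoArea(frozenset({"B1", "B2"}), {"B1": 100.0, "B2": 100.0}, True, 12, []),
            resected_channels=frozenset({"B1", "B2"}),
            ilae=1, electrode_type="sEEG", age=29, sex="f", pathology=2,
            n_channels=78, n_resected_channels=11, follow_up_months=36,
        )
        q = quantize_patient(p, cr_hfo=True)
        assert q == {"age": 3, "sex": 1, "pathology": 2, "elecType": 1,
                     "i": 1, "j": 1, "k": 1, "crHFOarea": 0, "fu": 1}
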