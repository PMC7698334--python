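"""Performance statistics: confusion metrics, exact CIs, AUC, annotation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import mrsidh as m
from mrsidh.errors import InvalidParameterError
from mrsidh.evaluate import default_assignment_table, annotate_bin

from conftest import make_cv_result

MUT, WT = m.IDHMUT, m.IDHWT


class TestConfusionMetrics:
    def test_study_cohort_counts(self):
        # 22 mutants / 12 wild type with one missed mutant and three false
        # positives: the canonical 88.2 / 95.5 / 75.0 configuration
        true = [MUT] * 22 + [WT] * 12
        pred = [MUT] * 21 + [WT] + [MUT] * 3 + [WT] * 9
        cv = make_cv_result(true, pred, np.zeros(34))
        c = m.confusion_metrics(cv)
        assert (c.tp, c.fn, c.fp, c.tn) == (21, 1, 3, 9)
        assert m.round_percent(c.accuracy) == 88.2
        assert m.round_percent(c.sensitivity) == 95.5
        assert m.round_percent(c.specificity) == 75.0

    def test_all_correct(self):
        cv = make_cv_result([MUT, MUT, WT], [MUT, MUT, WT], [1, 1, -1])
        c = m.confusion_metrics(cv)
        assert (c.accuracy, c.sensitivity, c.specificity) == (1.0, 1.0, 1.0)

    def test_all_predicted_positive(self):
        cv = make_cv_result([MUT, WT, WT], [MUT, MUT, MUT], [1, 1, 1])
        c = m.confusion_metrics(cv)
        assert c.sensitivity == 1.0 and c.specificity == 0.0


class TestRounding:
    @pytest.mark.parametrize(
        "proportion,expected",
        [(0.88235, 88.2), (0.9545, 95.5), (0.75, 75.0), (0.004999, 0.5), (1.0, 100.0)],
    )
    def test_half_away_from_zero_one_decimal(self, proportion, expected):
        assert m.round_percent(proportion) == expected


def _cp_oracle(x, n, alpha):
    """Independent oracle: bisection on exact binomial tail sums."""

    def upper_tail(p):  # P(X >= x)
        return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k) for k in range(x, n + 1))

    def lower_tail(p):  # P(X <= x)
        return sum(math.comb(n, k) * p ** k * (1 - p) ** (n - k) for k in range(0, x + 1))

    def bisect(f, target, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else bisect(upper_tail, alpha / 2, 0.0, 1.0)
    upper = 1.0 if x == n else bisect(lambda p: -lower_tail(p), -alpha / 2, 0.0, 1.0)
    return lower, upper


class TestClopperPearson:
    def test_printed_sensitivity_interval(self):
        ci = m.clopper_pearson(21, 22, 0.05)
        assert round(ci.lower, 3) == 0.772
        assert round(ci.upper, 3) == 0.999

    def test_printed_specificity_interval(self):
        ci = m.clopper_pearson(9, 12, 0.05)
        assert round(ci.upper, 3) == 0.945
        # exact value to one percent decimal is 42.8 (the study prints 42.9)
        assert m.round_percent(ci.lower) == 42.8

    def test_boundary_cases_closed_form(self):
        for n in (1, 5, 22):
            lo = m.clopper_pearson(0, n, 0.05)
            assert lo.lower == 0.0
            hi = m.clopper_pearson(n, n, 0.05)
            assert hi.upper == 1.0
            assert hi.lower == pytest.approx((0.025) ** (1.0 / n), abs=1e-12)

    def test_matches_tail_sum_oracle_small_n(self):
        for n in (1, 7, 22, 40):
            for x in range(n + 1):
                lo, hi = _cp_oracle(x, n, 0.05)
                ci = m.clopper_pearson(x, n, 0.05)
                assert ci.lower == pytest.approx(lo, abs=1e-9)
                assert ci.upper == pytest.approx(hi, abs=1e-9)

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for x, n in [(21, 22), (9, 12), (3, 10), (0, 6)]:
            lo, hi = proportion_confint(x, n, alpha=0.05, method="beta")
            ci = m.clopper_pearson(x, n, 0.05)
            assert ci.lower == pytest.approx(float(lo), abs=1e-12)
            assert ci.upper == pytest.approx(float(hi), abs=1e-12)

    @given(st.integers(1, 40).flatmap(lambda n: st.tuples(st.just(n), st.integers(0, n))))
    def test_interval_nesting_in_alpha(self, nx):
        n, x = nx
        wide = m.clopper_pearson(x, n, 0.01)
        narrow = m.clopper_pearson(x, n, 0.05)
        assert wide.lower <= narrow.lower and narrow.upper <= wide.upper
        assert wide.lower <= x / n <= wide.upper

    def test_invalid_counts(self):
        with pytest.raises(InvalidParameterError):
            m.clopper_pearson(5, 4, 0.05)


def _auc_oracle(pos_scores, neg_scores):
    wins = sum(
        1.0 if p > q else 0.5 if p == q else 0.0
        for p in pos_scores for q in neg_scores
    )
    return wins / (len(pos_scores) * len(neg_scores))


class TestRocAuc:
    def test_perfect_ordering(self):
        cv = make_cv_result([MUT, MUT, WT, WT], [MUT] * 4, [3.0, 2.0, -1.0, -2.0])
        assert m.roc_auc(cv) == 1.0

    def test_all_ties_give_half(self):
        cv = make_cv_result([MUT, MUT, WT], [MUT] * 3, [1.0, 1.0, 1.0])
        assert m.roc_auc(cv) == 0.5

    def test_pair_counting_example(self):
        cv = make_cv_result(
            [MUT, MUT, MUT, WT, WT], [MUT] * 5, [0.9, 0.8, 0.3, 0.7, 0.2]
        )
        assert m.roc_auc(cv) == pytest.approx(5 / 6)

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_pos = int(rng.integers(1, 15))
            n_neg = int(rng.integers(1, 15))
            # discretized scores force ties
            scores = np.round(rng.normal(size=n_pos + n_neg), 1)
            true = [MUT] * n_pos + [WT] * n_neg
            cv = make_cv_result(true, [MUT] * (n_pos + n_neg), scores)
            assert m.roc_auc(cv) == pytest.approx(
                _auc_oracle(scores[:n_pos], scores[n_pos:]), abs=1e-12
            )

    def test_single_class_rejected(self):
        cv = make_cv_result([MUT, MUT], [MUT, MUT], [1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            m.roc_auc(cv)


class TestAverageClassSpectra:
    def test_identical_members_give_member_mean(self, axis):
        edges = [(2.0, 1.9), (1.9, 1.8)]
        vals = np.array([[0.6, 0.4], [0.6, 0.4], [0.3, 0.7]])
        mat = m.FeatureMatrix(vals, edges, ["a", "b", "c"],
                              [MUT, MUT, WT], stage="normalized")
        mean_mut, mean_wt, diff, _ = m.average_class_spectra(mat)
        assert np.allclose(mean_mut, [0.6, 0.4])
        assert np.allclose(diff, [0.3, -0.3])

    def test_requires_normalized_stage(self, default_matrix):
        with pytest.raises(InvalidParameterError):
            m.average_class_spectra(default_matrix)  # log2 stage

    def test_largest_difference_in_green_region(self, basis):
        # 50 noiseless draws per class: the biggest class difference sits in
        # the 3.5-4.1 ppm window the in vivo comparison highlights
        cfg = m.SimulationConfig(n_mut=50, n_wt=50, seed=3, noise_sd=0.0)
        cohort = m.simulate_cohort(basis, cfg)
        mat = m.preprocess_cohort(cohort, final_stage="normalized")
        _, _, diff, edges = m.average_class_spectra(mat)
        mids = np.array([(hi + lo) / 2 for hi, lo in edges])
        peak_mid = mids[int(np.argmax(np.abs(diff)))]
        assert 3.5 <= peak_mid <= 4.1


class TestAnnotateFeatures:
    def test_gly_mins_bin(self):
        table = default_assignment_table()
        assert set(annotate_bin((3.57, 3.53), table)) == {"Gly", "M-ins"}

    def test_choline_bin(self):
        table = default_assignment_table()
        assert annotate_bin((3.22, 3.18), table) == ["Cho"]

    def test_empty_region_unassigned(self):
        table = default_assignment_table()
        assert annotate_bin((6.0, 5.9), table) == ["unassigned"]

    def test_full_annotation_report(self):
        freqs = np.array([0.9, 0.0])
        edges = [(3.57, 3.53), (6.0, 5.9)]
        ann = m.annotate_features(freqs, edges)
        assert ann[0]["metabolites"] == ["Gly", "M-ins"]
        assert ann[1]["metabolites"] == ["unassigned"]


class TestReport:
    def test_report_consistency(self, default_matrix):
        cv = m.nested_loocv(default_matrix)
        rep = m.build_report(cv)
        c = rep.confusion
        assert c.total == 34 and c.n_positive == 22 and c.n_negative == 12
        assert rep.accuracy == pytest.approx((c.tp + c.tn) / 34)
        assert 0.0 <= rep.auc <= 1.0
        assert rep.sensitivity_ci.lower <= rep.sensitivity <= rep.sensitivity_ci.upper
        text = rep.summary_text()
        assert "accuracy" in text and "AUC" in text
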