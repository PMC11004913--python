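import numpy as np
import pytest

from ovascreen import (Cohort, VisitSeries, auc, contingency, lead_time,
                       make_folds, permutation_test_paired, screen_horizon,
                       sensitivity_at_specificity)
from ovascreen.evaluation import lead_time_summary, summarize_metric
from ovascreen.simulate import GeneratorConfig, generate_cohort

from helpers import auc_pair_counting, exact_sign_flip_p, sens_at_spec_scan


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_textbook_example(self):
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.5, 0.1]) == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=4000)
        scores = rng.uniform(size=4000)
        assert auc(labels, scores) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_counting_oracle(self, seed):
        """Rank-based AUC equals explicit pair enumeration, ties included."""
        rng = np.random.default_rng(seed)
        n = 60
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        scores = np.round(rng.uniform(size=n), 1)   # force ties
        assert auc(labels, scores) == pytest.approx(
            auc_pair_counting(labels, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.1, 0.2])


class TestSensitivityAtSpecificity:
    def test_separated_toy(self):
        labels = [0] * 10 + [1] * 4
        scores = list(np.arange(0.0, 1.0, 0.1)) + [1.0] * 4
        sens, thr = sensitivity_at_specificity(labels, scores)
        assert sens == 1.0
        assert thr > 0.8

    def test_exchangeable_scores_spend_false_positive_budget(self):
        rng = np.random.default_rng(1)
        labels = np.r_[np.zeros(4000, int), np.ones(4000, int)]
        scores = rng.uniform(size=8000)
        sens, _ = sensitivity_at_specificity(labels, scores)
        assert sens == pytest.approx(0.10, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_cutoff_scan(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.r_[np.zeros(6, int), np.ones(4, int)]
        scores = np.round(rng.uniform(size=10), 1)
        ours = sensitivity_at_specificity(labels, scores)
        assert ours == pytest.approx(sens_at_spec_scan(labels, scores))

    def test_monotone_in_specificity(self):
        rng = np.random.default_rng(2)
        labels = np.r_[np.zeros(50, int), np.ones(50, int)]
        scores = np.r_[rng.normal(0, 1, 50), rng.normal(1, 1, 50)]
        s90, _ = sensitivity_at_specificity(labels, scores, 0.90)
        s100, _ = sensitivity_at_specificity(labels, scores, 1.0)
        assert s100 <= s90


class TestPermutationTest:
    def test_identical_vectors_give_p_one(self):
        a = np.array([0.9, 0.8, 0.85, 0.7])
        assert permutation_test_paired(a, a, n_perm=2**10) == 1.0

    def test_all_positive_differences_exact(self):
        a = np.arange(10) + 1.0
        b = np.arange(10) * 1.0
        p = permutation_test_paired(a, b, n_perm=2**10)
        assert p == pytest.approx(1.0 / 1024.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.05, 0.1, size=8)
        p = permutation_test_paired(d, np.zeros(8), n_perm=2**8)
        assert p == pytest.approx(exact_sign_flip_p(d), abs=1e-12)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.1, 0.2, size=8)
        b = rng.normal(0.0, 0.2, size=8)
        p_ab = permutation_test_paired(a, b, n_perm=2**8)
        p_ba = permutation_test_paired(b, a, n_perm=2**8)
        d = a - b
        ties = exact_sign_flip_p(d) + exact_sign_flip_p(-d) - 1.0
        assert p_ab + p_ba == pytest.approx(1.0 + ties, abs=1e-12)

    def test_sampled_converges_to_exact(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.03, 0.1, size=10)
        exact = permutation_test_paired(d, np.zeros(10), n_perm=2**10)
        sampled = permutation_test_paired(d, np.zeros(10), n_perm=400,
                                          seed=1)
        assert sampled == pytest.approx(exact, abs=0.08)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_paired([], [], n_perm=10)


class TestFolds:
    def test_study_sized_fold_counts(self):
        """180 controls / 44 cases, k=5: every test fold holds 36 controls
        and 8 or 9 cases."""
        cohort, _ = generate_cohort(GeneratorConfig(n_controls=180,
                                                    n_cases=44, seed=1))
        plan = make_folds(cohort, k=5, reps=2, seed=0)
        assert len(plan) == 10
        status = {p.patient_id: p.status for p in cohort.patients}
        for train_ids, test_ids in plan:
            n_ctrl = sum(1 for i in test_ids if status[i] == 0)
            n_case = sum(1 for i in test_ids if status[i] == 1)
            assert n_ctrl == 36
            assert n_case in (8, 9)

    def test_each_repetition_partitions_cohort(self, small_cohort):
        cohort, _ = small_cohort
        plan = make_folds(cohort, k=5, reps=2, seed=3)
        for rep in range(2):
            test_union = set()
            for _, test_ids in plan.folds[rep * 5:(rep + 1) * 5]:
                assert test_union.isdisjoint(test_ids)
                test_union.update(test_ids)
            assert test_union == set(cohort.ids)

    def test_deterministic_and_too_small_rejected(self, small_cohort):
        cohort, _ = small_cohort
        p1 = make_folds(cohort, seed=5)
        p2 = make_folds(cohort, seed=5)
        assert p1.folds == p2.folds
        with pytest.raises(ValueError):
            make_folds(cohort, k=30)


class TestScreenHorizon:
    def _cohort(self):
        ctrl = VisitSeries("c0", 0, ages=[60.0, 61.0, 62.0, 63.0],
                           levels={"m": [10.0] * 4})
        case = VisitSeries("p0", 1, ages=[61.8, 62.6],
                           levels={"m": [10.0, 30.0]}, diagnosis_age=63.0)
        return Cohort([ctrl, case], biomarker_names=["m"])

    def test_all_horizon_is_last_visit(self):
        cohort = self._cohort()
        ev = screen_horizon(cohort, "all")
        assert ev["c0"] == 3 and ev["p0"] == 1

    def test_one_year_horizon_picks_last_qualifying_visit(self):
        """Case visits 1.2 and 0.4 years before diagnosis: h=1 uses the
        visit 1.2 years out."""
        cohort = self._cohort()
        ev = screen_horizon(cohort, 1.0)
        assert ev["p0"] == 0           # age 61.8, 1.2 years before 63.0
        assert ev["c0"] == 2           # 63.0 - 62.0 >= 1

    def test_unreachable_horizon_excludes_patient(self):
        cohort = self._cohort()
        ev = screen_horizon(cohort, 2.0)
        assert "p0" not in ev
        assert ev["c0"] == 1


class TestLeadTime:
    def test_first_visit_abnormal(self):
        assert lead_time([59.5, 60.5, 61.5], [0.9, 0.95, 0.99], 0.5,
                         63.0) == pytest.approx(3.5)

    def test_never_abnormal_returns_none(self):
        assert lead_time([60.0, 61.0], [0.1, 0.2], 0.5, 63.0) is None

    def test_threshold_tie_counts_as_abnormal(self):
        assert lead_time([60.0, 61.0], [0.2, 0.5], 0.5, 62.0) == \
            pytest.approx(1.0)

    def test_summary_orders_min_median_max(self):
        stats = lead_time_summary([[1.0, 2.5, 0.5], [2.0, 3.0]])
        assert stats.min[0] <= stats.median[0] <= stats.max[0]


class TestContingency:
    def test_identical_models_have_zero_off_diagonal(self):
        det = {"a": True, "b": False, "c": True}
        cells = contingency(det, dict(det))
        assert cells["a_diagnosed_b_missed"] == 0
        assert cells["a_missed_b_diagnosed"] == 0
        assert cells["a_diagnosed_b_diagnosed"] == 2
        assert cells["a_missed_b_missed"] == 1

    def test_disjoint_detection_concentrates_off_diagonal(self):
        case_ids = [f"p{i}" for i in range(5)]
        a = {c: True for c in case_ids}
        b = {c: False for c in case_ids}
        cells = contingency(a, b)
        assert cells["a_diagnosed_b_missed"] == 5
        assert sum(cells.values()) == 5

    def test_hand_tally(self):
        a = {"p0": True, "p1": True, "p2": False, "p3": True, "p4": False}
        b = {"p0": True, "p1": False, "p2": True, "p3": True, "p4": False}
        cells = contingency(a, b)
        assert cells == {"a_diagnosed_b_diagnosed": 2,
                         "a_diagnosed_b_missed": 1,
                         "a_missed_b_diagnosed": 1,
                         "a_missed_b_missed": 1}

    def test_mismatched_case_sets_rejected(self):
        with pytest.raises(ValueError):
            contingency({"a": True}, {"b": True})


def test_summarize_metric_normal_ci():
    vals = [0.9, 0.95, 0.85, 0.92]
    est, lo, hi = summarize_metric(vals)
    assert est == pytest.approx(np.mean(vals))
    assert lo < est < hi
    boot = summarize_metric(vals, method="bootstrap", seed=0)
    assert boot[1] <= boot[0] <= boot[2]
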