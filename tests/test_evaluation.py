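"""Cross-validation folds, ROC/cutoff machinery and model-series statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from tripgait.evaluation import (CVScheme, ModelEvaluation, anova_one_way,
                                 classify_at_cutoff, evaluate_subset,
                                 optimal_cutoff, overall_accuracy,
                                 paired_ttest, per_class_tpr, roc_multiclass,
                                 roc_one_vs_rest, select_best_and_optimal,
                                 stratified_folds)

from conftest import make_blob_table


class TestStratifiedFolds:
    def test_fold_sizes_for_298_rows(self, cohort_table):
        folds = stratified_folds(cohort_table, CVScheme(n_repeats=1, seed=0))
        sizes = sorted(len(te) for _, _, _, te in folds)
        assert sum(sizes) == 298
        assert set(sizes) <= {59, 60}

    def test_minority_class_stratification(self, cohort_table):
        folds = stratified_folds(cohort_table, CVScheme(n_repeats=1, seed=0))
        y = cohort_table["outcome"].to_numpy()
        for _, _, _, te in folds:
            n_e = (y[te] == "E_fall").sum()
            assert n_e in (4, 5)

    def test_partition_per_repeat(self, cohort_table):
        folds = stratified_folds(cohort_table, CVScheme(n_repeats=2, seed=1))
        for rep in (0, 1):
            test_idx = np.concatenate([te for r, _, _, te in folds if r == rep])
            assert sorted(test_idx) == list(range(298))

    def test_deterministic(self, cohort_table):
        a = stratified_folds(cohort_table, CVScheme(seed=3))
        b = stratified_folds(cohort_table, CVScheme(seed=3))
        for (_, _, tra, tea), (_, _, trb, teb) in zip(a, b):
            np.testing.assert_array_equal(tra, trb)
            np.testing.assert_array_equal(tea, teb)

    def test_class_smaller_than_folds_rejected(self):
        table = pd.DataFrame({"f": np.arange(20.0),
                              "outcome": ["no_fall"] * 17 + ["E_fall"] * 3})
        with pytest.raises(ValueError, match="E_fall"):
            stratified_folds(table, CVScheme(n_folds=5, seed=0))


class TestROC:
    def test_perfect_separation_gives_auc_1(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["neg", "neg", "pos", "pos"])
        assert roc_one_vs_rest(scores, labels, "pos").auc == 1.0

    def test_auc_equals_pairwise_concordance(self):
        """Mann-Whitney identity: AUC = concordant pairs / (n+ * n-)."""
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array(["n", "n", "p", "p"])
        auc = roc_one_vs_rest(scores, labels, "p").auc
        pos = scores[labels == "p"]
        neg = scores[labels == "n"]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)))
        assert auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_concordance_identity_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(30)
        labels = rng.choice(["p", "n"], size=30)
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        auc = roc_one_vs_rest(scores, labels, "p").auc
        pos, neg = scores[labels == "p"], scores[labels == "n"]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)), abs=1e-12)

    def test_permutation_null_auc_half(self):
        rng = np.random.default_rng(7)
        scores = rng.random(4000)
        labels = rng.choice(["p", "n"], size=4000)
        auc = roc_one_vs_rest(scores, labels, "p").auc
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        scores = rng.random(200)
        labels = rng.choice(["p", "n"], size=200)
        a = roc_one_vs_rest(scores, labels, "p").auc
        b = roc_one_vs_rest(np.exp(3 * scores) - 1, labels, "p").auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_absent_class_flagged_and_excluded(self):
        post = np.array([[0.7, 0.2, 0.1], [0.3, 0.6, 0.1], [0.2, 0.7, 0.1]])
        labels = np.array(["a", "b", "b"])
        res = roc_multiclass(post, labels, ["a", "b", "c"])
        assert res.missing_classes == ["c"]
        assert set(res.curves) == {"a", "b"}


class TestOptimalCutoff:
    def test_perfect_classifier_reaches_ideal_point(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array(["n", "n", "p", "p"])
        curve = roc_one_vs_rest(scores, labels, "p")
        cut = optimal_cutoff(curve)
        pred = scores >= cut
        truth = labels == "p"
        assert (pred == truth).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_threshold_search(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(40), 2)
        labels = rng.choice(["p", "n"], size=40, p=[0.4, 0.6])
        curve = roc_one_vs_rest(scores, labels, "p")
        cut = optimal_cutoff(curve)

        def j_at(thr):
            pred = scores >= thr
            pos, neg = labels == "p", labels == "n"
            return pred[pos].mean() - pred[neg].mean()

        best_j = max(j_at(t) for t in np.unique(scores))
        assert j_at(cut) == pytest.approx(best_j, abs=1e-12)
        # ties resolved toward the lower (more sensitive) threshold
        tied = [t for t in np.unique(scores)
                if j_at(t) == pytest.approx(best_j, abs=1e-12)]
        assert cut == pytest.approx(min(tied))

    def test_random_scores_give_near_zero_j(self):
        rng = np.random.default_rng(11)
        scores = rng.random(5000)
        labels = rng.choice(["p", "n"], size=5000)
        curve = roc_one_vs_rest(scores, labels, "p")
        assert np.max(curve.tpr - curve.fpr) < 0.06


class TestClassifyAtCutoff:
    ORDER = ["a", "b", "c"]

    def test_unanimous_exceedance(self):
        pred = classify_at_cutoff([[0.8, 0.1, 0.1]], np.full(3, 0.5), self.ORDER)
        assert pred[0] == "a"

    def test_none_exceed_margin_rule(self):
        pred = classify_at_cutoff([[0.4, 0.35, 0.25]], np.full(3, 0.5), self.ORDER)
        assert pred[0] == "a"

    def test_symmetric_tie_goes_to_first_class(self):
        third = 1.0 / 3.0
        pred = classify_at_cutoff([[third, third, third]], np.full(3, 0.5), self.ORDER)
        assert pred[0] == "a"

    def test_multiple_exceed_largest_margin_wins(self):
        pred = classify_at_cutoff([[0.45, 0.50, 0.05]],
                                  np.array([0.4, 0.3, 0.5]), self.ORDER)
        # margins: a: 0.05, b: 0.20, c: -0.45
        assert pred[0] == "b"


class TestOverallAccuracy:
    def test_printed_row_identity(self):
        """Per-class rates (90.9, 38.9, 88.4) at prevalences (192, 22, 84)
        recombine to the printed 86.4% overall."""
        acc = overall_accuracy((90.9, 38.9, 88.4), (192, 22, 84))
        assert round(acc, 1) == 86.4

    def test_ceiling(self):
        assert overall_accuracy((100, 100, 100), (192, 22, 84)) == 100.0

    def test_majority_only(self):
        acc = overall_accuracy((100, 0, 0), (192, 22, 84))
        assert round(acc, 1) == 64.4


class TestAnova:
    def test_identical_constant_groups(self):
        f, p = anova_one_way([[0.5] * 5, [0.5] * 5, [0.5] * 5])
        assert f == 0.0 and p == 1.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        f, p_f = anova_one_way([a, b])
        t, p_t = scipy.stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_hand_computed_example(self):
        # groups (1,2,3), (2,3,4), (3,4,5): SSB = 6, SSW = 6, F = 3
        f, p = anova_one_way([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0)
        assert p == pytest.approx(float(scipy.stats.f.sf(3.0, 2, 6)))

    def test_matches_scipy_on_random_groups(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(m, 1, 12) for m in (0.0, 0.2, 0.4, 0.1)]
        f, p = anova_one_way(groups)
        ref = scipy.stats.f_oneway(*groups)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            anova_one_way([[1.0], [1, 2]])


class TestPairedTTest:
    def test_identical_samples(self):
        t, p = paired_ttest([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference(self):
        t, p = paired_ttest([1, 2, 3], [0, 1, 2])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1, 2], [1, 2, 3])

    def test_rejection_rate_matches_power_oracle(self):
        """Empirical rejection rate at alpha = 0.05 vs noncentral-t power."""
        n, shift, sd = 20, 0.6, 1.0
        alpha = 0.05
        nc = shift / (sd / np.sqrt(n))
        t_crit = scipy.stats.t.ppf(1 - alpha / 2, n - 1)
        power = (1 - scipy.stats.nct.cdf(t_crit, n - 1, nc)
                 + scipy.stats.nct.cdf(-t_crit, n - 1, nc))
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 4000
        for _ in range(reps):
            base = rng.normal(0, 1, n)
            a = base + rng.normal(shift, sd, n)
            _, p = paired_ttest(a, base)
            rejections += p < alpha
        assert rejections / reps == pytest.approx(power, abs=0.02)


class TestModelSelection:
    @staticmethod
    def _fake_eval(k, mean):
        samples = np.full(50, mean)
        return ModelEvaluation(
            n_features=k, features=[f"f{i}" for i in range(k)],
            auc_samples=samples, default_tpr={}, default_overall=0.0,
            optimal_tpr={}, optimal_overall=0.0, optimal_cutoffs={})

    def test_reference_auc_pattern(self):
        """Max AUC 0.96 at 17 features; 0.93 at 8 clears 0.95 x max."""
        aucs = {k: 0.70 + 0.012 * k for k in range(1, 8)}   # up to 0.784
        aucs.update({k: 0.93 for k in range(8, 17)})
        aucs[17] = 0.96
        aucs.update({k: 0.95 for k in (18, 19, 20)})
        evals = [self._fake_eval(k, v) for k, v in aucs.items()]
        best, optimal = select_best_and_optimal(evals)
        assert (best, optimal) == (17, 8)
        assert 0.93 > 0.95 * 0.96

    def test_singleton_is_both(self):
        evals = [self._fake_eval(4, 0.8)]
        assert select_best_and_optimal(evals) == (4, 4)

    def test_monotone_sequence_optimal_not_larger_than_best(self):
        evals = [self._fake_eval(k, 0.5 + 0.02 * k) for k in range(1, 21)]
        best, optimal = select_best_and_optimal(evals)
        assert optimal <= best


class TestEvaluateSubset:
    def test_blob_subset_high_auc_and_counts(self):
        table = make_blob_table(60, seed=5)
        ev = evaluate_subset(table, ["f1", "f2"],
                             CVScheme(n_folds=5, n_repeats=2, seed=1),
                             seed=1, tune_mode="none")
        assert len(ev.auc_samples) == 10
        assert ev.mean_auc > 0.99
        assert ev.default_overall > 95.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(6)
        table = make_blob_table(60, seed=6)
        table["outcome"] = rng.permutation(table["outcome"].to_numpy())
        ev = evaluate_subset(table, ["f1", "f2"],
                             CVScheme(n_folds=5, n_repeats=2, seed=2),
                             seed=2, tune_mode="none")
        assert ev.mean_auc == pytest.approx(0.5, abs=0.1)
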