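"""Fold stratification, CV/nested-CV integrity, metrics and comparisons."""

import copy

import numpy as np
import pytest
from scipy import stats

from connbench import evaluation as E
from connbench import synthdata as S
from connbench.cohort import CohortData
from conftest import SMALL_FEATURES, tiny_generation_config


def _expand_site_table(scale=1.0):
    labels, sites = [], []
    for site, a, t in S.abide_like_site_table(scale):
        labels += ["autism"] * a + ["td"] * t
        sites += [site] * (a + t)
    return np.array(labels), np.array(sites)


class TestStratifiedFolds:
    def test_balanced_two_class_single_site(self):
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        plan = E.make_stratified_folds(labels, np.full(10, "A"), k=5, seed=0)
        for f in range(5):
            fold_labels = labels[plan.fold == f]
            assert sorted(fold_labels) == [0, 1]

    def test_full_scale_cohort_cell_deviation_at_most_one(self):
        labels, sites = _expand_site_table(1.0)
        plan = E.make_stratified_folds(labels, sites, k=5, seed=1)
        for site in np.unique(sites):
            for lab in np.unique(labels):
                cell = (sites == site) & (labels == lab)
                per_fold = np.bincount(plan.fold[cell], minlength=5)
                assert per_fold.max() - (cell.sum() / 5) <= 1
                assert (cell.sum() / 5) - per_fold.min() <= 1

    def test_870_samples_give_fold_sizes_174_plus_minus_one(self):
        labels, sites = _expand_site_table(1.0)
        assert labels.size == 870
        plan = E.make_stratified_folds(labels, sites, k=5, seed=2)
        sizes = np.bincount(plan.fold, minlength=5)
        assert np.abs(sizes - 174).max() <= 1

    def test_deterministic_given_seed_and_covering(self):
        labels, sites = _expand_site_table(0.25)
        p1 = E.make_stratified_folds(labels, sites, k=5, seed=7)
        p2 = E.make_stratified_folds(labels, sites, k=5, seed=7)
        assert np.array_equal(p1.fold, p2.fold)
        assert np.isin(p1.fold, np.arange(5)).all()
        p3 = E.make_stratified_folds(labels, sites, k=5, seed=8)
        assert not np.array_equal(p1.fold, p3.fold)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            E.make_stratified_folds([0, 1, 0], ["A", "A", "A"], k=5)


class TestMetrics:
    def test_auc_matches_pair_enumeration(self, rng):
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(30), 1)  # coarse scores to force ties
        wins = half = total = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                total += 1
                if s[i] > s[j]:
                    wins += 1
                elif s[i] == s[j]:
                    half += 1
        assert E.roc_auc(s, y) == pytest.approx((wins + 0.5 * half) / total)

    def test_auc_trivial_cases(self):
        assert E.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert E.roc_auc([0.2, 0.2], [1, 0]) == 0.5
        with pytest.raises(ValueError):
            E.roc_auc([0.1, 0.2], [1, 1])

    def test_accuracy(self):
        assert E.accuracy([1, 0, 1], [1, 1, 1]) == pytest.approx(2 / 3)

    def test_paired_t_closed_form(self):
        t, p = E.paired_t_test([1, 2, 3, 4, 5], [0, 0, 0, 0, 0])
        assert t == pytest.approx(3 / (np.std([1, 2, 3, 4, 5], ddof=1) / np.sqrt(5)))
        assert t == pytest.approx(4.2426, abs=1e-4)
        assert p == pytest.approx(0.0132, abs=5e-4)

    def test_paired_t_identical_vectors_convention(self):
        assert E.paired_t_test([0.7, 0.8], [0.7, 0.8]) == (0.0, 1.0)
        with pytest.raises(ValueError):
            E.paired_t_test([1.0], [2.0])

    def test_chi_squared_matches_hand_formula(self):
        # correctness contingency ((50,10),(10,50))
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 120)
        ca = np.repeat([True, False], [60, 60])
        cb = np.repeat([True, False, True, False], [50, 10, 10, 50])
        pred_a = np.where(ca, labels, 1 - labels)
        pred_b = np.where(cb, labels, 1 - labels)
        chi2, p = E.chi_squared_best(pred_a, pred_b, labels)
        n, aa, bb, cc, dd = 120, 50, 10, 10, 50
        hand = n * (aa * dd - bb * cc) ** 2 / ((aa + bb) * (cc + dd) * (aa + cc) * (bb + dd))
        assert chi2 == pytest.approx(hand)
        assert 0 <= p <= 1


@pytest.fixture(scope="module")
def cv_results(tiny_cohort, tiny_plan):
    data, _ = tiny_cohort
    return {
        arch: E.run_cv(
            arch,
            "s+f",
            tiny_plan,
            data,
            feature_params=SMALL_FEATURES,
            model_overrides={} if arch == "svm" else {"max_epochs": 40},
            model_seed=0,
        )
        for arch in ("svm", "fcn")
    }


class TestRunCV:
    def test_every_sample_predicted_exactly_once(self, cv_results, tiny_cohort):
        data, _ = tiny_cohort
        for res in cv_results.values():
            assert res.preds.size == data.n and (res.preds >= 0).all()
            assert np.isfinite(res.scores).all()

    def test_separable_cohort_reaches_high_accuracy(self, cv_results):
        for arch, res in cv_results.items():
            assert res.pooled_accuracy >= 0.9, arch
            assert res.pooled_auc >= 0.9, arch

    def test_label_permuted_cohort_is_at_chance(self, tiny_cohort):
        data, _ = tiny_cohort
        null = copy.copy(data)
        null.y = np.random.default_rng(1).permutation(data.y)
        plan = E.make_stratified_folds(null.y, null.sites, k=5, seed=0)
        res = E.run_cv("svm", "s+f", plan, null, feature_params=SMALL_FEATURES)
        assert abs(res.pooled_accuracy - 0.5) <= 0.08

    def test_validation_accuracy_exceeds_test_on_average(self):
        """Hyper-parameters are picked on the validation fold, so validation
        accuracy is optimistically biased relative to test accuracy."""
        vals, tests = [], []
        for seed in range(4):
            records, _ = S.generate_cohort(tiny_generation_config(seed=seed, d=0.5))
            data = CohortData.from_records(records)
            plan = E.make_stratified_folds(data.y, data.sites, k=5, seed=seed)
            res = E.run_cv("svm", "s+f", plan, data, feature_params=SMALL_FEATURES)
            vals += res.per_fold_val_acc
            tests += res.per_fold_test_acc
        assert np.mean(vals) >= np.mean(tests)

    def test_fold_seed_change_still_covers_every_sample(self, tiny_cohort):
        data, _ = tiny_cohort
        plan = E.make_stratified_folds(data.y, data.sites, k=5, seed=99)
        res = E.run_cv("svm", "s+f", plan, data, feature_params=SMALL_FEATURES)
        assert (res.preds >= 0).all()

    def test_rerun_is_deterministic(self, tiny_cohort, tiny_plan, cv_results):
        data, _ = tiny_cohort
        again = E.run_cv("svm", "s+f", tiny_plan, data, feature_params=SMALL_FEATURES, model_seed=0)
        assert np.array_equal(again.preds, cv_results["svm"].preds)
        assert np.array_equal(again.scores, cv_results["svm"].scores)

    def test_accuracy_monotone_in_effect_size(self):
        """Pooled accuracy is non-decreasing in the planted effect size."""
        mean_acc = []
        for d in (0.0, 0.5, 1.0, 2.0):
            accs = []
            for seed in range(5):
                records, _ = S.generate_cohort(
                    tiny_generation_config(seed=10 + seed, d=d, n_rois=16)
                )
                data = CohortData.from_records(records)
                plan = E.make_stratified_folds(data.y, data.sites, k=5, seed=seed)
                res = E.run_cv(
                    "svm",
                    "f",
                    plan,
                    data,
                    feature_params=E.FeatureParams(k_fmri=40, rfe_step=0.3),
                )
                accs.append(res.pooled_accuracy)
            mean_acc.append(np.mean(accs))
        assert all(b >= a - 1e-9 for a, b in zip(mean_acc, mean_acc[1:]))


@pytest.fixture(scope="module")
def nested(tiny_cohort, tiny_plan):
    data, _ = tiny_cohort
    return E.run_nested_cv(
        "svm", "s+f", tiny_plan, data, feature_params=SMALL_FEATURES, model_seed=0
    )


class TestNestedCV:
    def test_exactly_25_models_trained(self, nested):
        assert nested.inner_model_count == 25

    def test_outer_test_never_leaks_into_inner_splits(self, tiny_cohort, tiny_plan):
        data, _ = tiny_cohort
        for f in range(tiny_plan.k):
            test = set(tiny_plan.test_indices(f).tolist())
            rest = np.flatnonzero(tiny_plan.fold != f)
            inner = E.make_stratified_folds(
                data.y[rest], data.sites[rest], k=5, seed=tiny_plan.seed * 31 + f + 1
            )
            for i in range(5):
                inner_ids = set(rest[inner.fold == i].tolist()) | set(rest[inner.fold != i].tolist())
                assert not (inner_ids & test)

    def test_votes_cover_every_sample(self, nested, tiny_cohort):
        data, _ = tiny_cohort
        assert nested.votes.shape == (5, data.n)
        assert (nested.votes >= 0).all()

    def test_max_vote_close_to_single_model_cv(self, nested, cv_results):
        assert nested.pooled_accuracy >= cv_results["svm"].pooled_accuracy - 0.02


class TestTrainTestDisjointness:
    def test_fold_split_partitions_cohort(self, tiny_plan, tiny_cohort):
        data, _ = tiny_cohort
        seen = np.zeros(data.n, dtype=int)
        for f in range(tiny_plan.k):
            seen[tiny_plan.test_indices(f)] += 1
        assert (seen == 1).all()
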