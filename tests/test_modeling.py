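"""Pipeline pieces: split, preprocessing, fit, ranking metrics, calibration."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import gdmsim as g
from gdmsim.errors import ValidationError
from gdmsim.modeling import LogisticConfig, evaluate_scores, load_model, save_model


def brute_auc(scores, labels):
    """Pairwise Mann-Whitney enumeration (independent oracle)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_ap(scores, labels):
    """Threshold-enumeration AP with ties grouped (independent oracle)."""
    n_pos = sum(labels)
    if n_pos == 0:
        return None
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = [s >= t for s in scores]
        tp = sum(1 for p, y in zip(pred, labels) if p and y == 1)
        pp = sum(pred)
        recall = tp / n_pos
        ap += (recall - prev_recall) * (tp / pp)
        prev_recall = recall
    return ap


class TestSplit:
    def _tiny(self, n=10, seed=0):
        cohort = g.generate_cohort(g.CohortSpec(n_patients=n, seed=seed))
        frame = g.make_label_frame(cohort.ids, cohort.truth, cohort.truth)
        return cohort, frame

    def test_sizes_and_disjointness(self):
        cohort, frame = self._tiny(10)
        plan = g.SplitPlan(
            test_fraction=0.3, stratify_on_reference=False, exclude_years=()
        )
        train, test = g.split_cohort(cohort, frame, plan)
        assert len(test) == 3 and len(train) == 7
        assert not set(train) & set(test)

    def test_excluded_year_absent_from_both_sets(self, cohort_small, frame_small):
        train, test = g.split_cohort(cohort_small, frame_small, g.SplitPlan(seed=1))
        years = cohort_small.years
        assert not (years[train] == 2020).any()
        assert not (years[test] == 2020).any()
        included = np.flatnonzero(years != 2020)
        assert len(train) + len(test) == included.size

    def test_stratification_preserves_prevalence(self, cohort_small, frame_small):
        train, test = g.split_cohort(cohort_small, frame_small, g.SplitPlan(seed=1))
        truth = frame_small.truth
        assert abs(truth[test].mean() - truth[train].mean()) < 0.01

    def test_determinism(self, cohort_small, frame_small):
        plan = g.SplitPlan(seed=9)
        a = g.split_cohort(cohort_small, frame_small, plan)
        b = g.split_cohort(cohort_small, frame_small, plan)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_tiny_class_suggests_unstratified(self):
        cohort, _ = self._tiny(12)
        truth = np.zeros(12, int)
        truth[0] = 1  # a single positive cannot be stratified
        frame = g.make_label_frame(cohort.ids, truth, truth)
        with pytest.raises(ValidationError, match="stratif"):
            g.split_cohort(cohort, frame, g.SplitPlan(exclude_years=()))


class TestPreprocessor:
    def _table(self):
        return pd.DataFrame(
            {
                "num1": [1.0, 2.0, 3.0, 4.0],
                "num2": [0.0, 1.0, 0.0, 1.0],
                "cat": ["a", "b", "c", "a"],
            }
        )

    def test_design_width(self):
        plan = g.fit_preprocessor(self._table(), ["num1", "num2"], ["cat"])
        X = plan.transform(self._table())
        assert X.shape == (4, 2 + (3 - 1))

    def test_train_columns_standardized(self):
        plan = g.fit_preprocessor(self._table(), ["num1", "num2"], ["cat"])
        X = plan.transform(self._table())
        np.testing.assert_allclose(X[:, :2].mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(X[:, :2].std(axis=0), 1, atol=1e-9)

    def test_unseen_category_encodes_all_zero(self):
        plan = g.fit_preprocessor(self._table(), [], ["cat"])
        X = plan.transform(pd.DataFrame({"cat": ["zz"]}))
        assert (X == 0).all()

    def test_first_category_dropped_is_lexicographic(self):
        plan = g.fit_preprocessor(self._table(), [], ["cat"])
        assert plan.feature_names == ["cat_b", "cat_c"]

    def test_zero_sd_numeric_transforms_to_zero(self):
        table = pd.DataFrame({"const": [5.0, 5.0, 5.0]})
        plan = g.fit_preprocessor(table, ["const"], [])
        assert (plan.transform(table) == 0).all()

    def test_missing_values_rejected(self):
        table = self._table()
        table.loc[0, "num1"] = np.nan
        with pytest.raises(ValidationError, match="num1"):
            g.fit_preprocessor(table, ["num1"], ["cat"])


class TestLogistic:
    def test_separable_data_has_finite_coefficients_and_train_auc_one(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = g.train_logistic(X, y)
        assert np.isfinite(model.coefficients).all()
        assert g.roc_auc(g.predict_proba(model, X), y) == 1.0

    def test_refit_is_deterministic(self, rng):
        X = rng.standard_normal((200, 3))
        y = rng.integers(0, 2, 200)
        a = g.train_logistic(X, y)
        b = g.train_logistic(X, y)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_uninformative_features_shrink_to_zero(self, rng):
        X = rng.standard_normal((20000, 2))
        y = rng.binomial(1, 0.2, 20000)
        model = g.train_logistic(X, y)
        assert np.abs(model.coefficients).max() < 0.05
        assert abs(model.intercept - logit(y.mean())) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            g.train_logistic(np.zeros((5, 1)), np.ones(5))

    def test_predict_width_mismatch(self):
        model = g.train_logistic(np.array([[0.0], [1.0]]), np.array([0, 1]))
        with pytest.raises(ValidationError):
            g.predict_proba(model, np.zeros((2, 3)))

    def test_intercept_shift_raises_all_probabilities(self):
        model = g.train_logistic(np.array([[0.0], [1.0]]), np.array([0, 1]))
        X = np.linspace(-2, 2, 9).reshape(-1, 1)
        base = g.predict_proba(model, X)
        model.intercept += 1.0
        assert (g.predict_proba(model, X) > base).all()

    def test_serialization_round_trip(self, tmp_path, rng):
        table = pd.DataFrame(
            {
                "x": rng.standard_normal(50),
                "c": rng.choice(["u", "v", "w"], 50),
            }
        )
        y = rng.integers(0, 2, 50)
        pre = g.fit_preprocessor(table, ["x"], ["c"])
        model = g.train_logistic(pre.transform(table), y)
        probs = g.predict_proba(model, pre.transform(table))
        path = tmp_path / "model.json"
        save_model(path, model, pre)
        model2, pre2 = load_model(path)
        probs2 = g.predict_proba(model2, pre2.transform(table))
        np.testing.assert_allclose(probs2, probs, rtol=0, atol=1e-12)


class TestRocAuc:
    def test_hand_example(self):
        assert g.roc_auc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    def test_perfect_separation(self):
        assert g.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores(self):
        assert g.roc_auc([0.4] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_single_class_undefined(self):
        assert g.roc_auc([0.1, 0.2], [1, 1]) is None

    def test_complement_identity(self, rng):
        scores = np.round(rng.random(40), 1)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        auc = g.roc_auc(scores, labels)
        assert abs(auc + g.roc_auc(-scores, labels) - 1.0) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        a = g.roc_auc(scores, labels)
        b = g.roc_auc(np.exp(5 * scores), labels)
        assert abs(a - b) < 1e-12

    def test_matches_bruteforce_on_small_fuzz(self, rng):
        for _ in range(300):
            n = rng.integers(2, 13)
            scores = np.round(rng.random(n), 1)  # rounded to force ties
            labels = rng.integers(0, 2, n)
            ours = g.roc_auc(scores, labels)
            oracle = brute_auc(scores.tolist(), labels.tolist())
            if oracle is None:
                assert ours is None
            else:
                assert abs(ours - oracle) < 1e-12


class TestAveragePrecision:
    def test_hand_example(self):
        assert abs(g.average_precision([0.9, 0.8, 0.3], [1, 0, 1]) - 5 / 6) < 1e-12

    def test_perfect_ranking(self):
        assert g.average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_constant_scores_equal_prevalence(self):
        assert abs(g.average_precision([0.5] * 8, [1, 0, 0, 0, 1, 0, 0, 0]) - 0.25) < 1e-12

    def test_no_positives_undefined(self):
        assert g.average_precision([0.5, 0.6], [0, 0]) is None

    def test_matches_bruteforce_on_small_fuzz(self, rng):
        for _ in range(300):
            n = rng.integers(1, 13)
            scores = np.round(rng.random(n), 1)
            labels = rng.integers(0, 2, n)
            ours = g.average_precision(scores, labels)
            oracle = brute_ap(scores.tolist(), labels.tolist())
            if oracle is None:
                assert ours is None
            else:
                assert abs(ours - oracle) < 1e-12


class TestAucCI:
    def _sample(self, rng, n=400):
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = labels + rng.standard_normal(n)
        return scores, labels

    def test_seed_fixes_interval(self, rng):
        scores, labels = self._sample(rng)
        assert g.auc_ci(scores, labels, 200, seed=4) == g.auc_ci(
            scores, labels, 200, seed=4
        )

    def test_interval_contains_point_estimate(self, rng):
        scores, labels = self._sample(rng)
        low, high = g.auc_ci(scores, labels, 500, seed=4)
        auc = g.roc_auc(scores, labels)
        assert low <= auc <= high

    def test_width_shrinks_with_sample_size(self, rng):
        s1, l1 = self._sample(rng, 200)
        s2, l2 = self._sample(rng, 3200)
        w1 = np.diff(g.auc_ci(s1, l1, 300, seed=1))[0]
        w2 = np.diff(g.auc_ci(s2, l2, 300, seed=1))[0]
        assert w2 < w1

    def test_too_few_resamples_rejected(self, rng):
        scores, labels = self._sample(rng)
        with pytest.raises(ValidationError):
            g.auc_ci(scores, labels, 10, seed=0)


class TestCalibration:
    def test_bin_counts_partition_sample(self, rng):
        probs = rng.random(500)
        labels = rng.binomial(1, probs)
        bins = g.calibration_curve(probs, labels, 10)
        assert bins["count"].sum() == 500

    def test_well_calibrated_sample_tracks_diagonal(self, rng):
        probs = rng.random(20000)
        labels = rng.binomial(1, probs)
        bins = g.calibration_curve(probs, labels, 10)
        for _, row in bins.iterrows():
            band = 3 * np.sqrt(row.mean_predicted * (1 - row.mean_predicted) / row["count"])
            assert abs(row.observed_rate - row.mean_predicted) < band + 0.01

    def test_constant_probs_single_bin(self):
        bins = g.calibration_curve([0.3] * 20, [0] * 15 + [1] * 5, 5)
        assert len(bins) == 1

    def test_more_bins_than_points_rejected(self):
        with pytest.raises(ValidationError):
            g.calibration_curve([0.5, 0.6], [0, 1], 5)

    def test_slope_and_intercept_recovered_under_correct_model(self, rng):
        probs = np.clip(rng.beta(1.2, 8, 20000), 1e-4, 1 - 1e-4)
        labels = rng.binomial(1, probs)
        intercept, slope = g.calibration_intercept_slope(probs, labels)
        assert 0.9 < slope < 1.1
        assert abs(intercept) < 0.1

    def test_overconfident_doubling_halves_slope(self, rng):
        true = np.clip(rng.beta(1.2, 8, 30000), 1e-4, 1 - 1e-4)
        labels = rng.binomial(1, true)
        overconfident = expit(2 * logit(true))
        _, slope = g.calibration_intercept_slope(overconfident, labels)
        assert 0.4 < slope < 0.6

    def test_degenerate_probs_flag_slope_undefined(self):
        intercept, slope = g.calibration_intercept_slope(
            [0.3] * 30, [0] * 20 + [1] * 10
        )
        assert slope is None
        assert abs(intercept - (logit(1 / 3) - logit(0.3))) < 1e-6


class TestExperiment:
    def test_zero_noise_frame_makes_all_arms_identical(self, cohort_small):
        frame = g.make_label_frame(
            cohort_small.ids, cohort_small.truth, cohort_small.truth,
            years=cohort_small.years,
        )
        res = g.run_label_source_experiment(
            cohort_small, frame, g.SplitPlan(seed=2), n_boot=0
        )
        arms = res["arms"]
        aucs = {name: ev.roc_auc for name, ev in arms.items()}
        assert len(set(aucs.values())) == 1
        aps = {name: ev.average_precision for name, ev in arms.items()}
        assert len(set(aps.values())) == 1

    def test_val_view_restricted_to_agreement_rows(self, cohort_small, frame_small):
        res = g.run_label_source_experiment(
            cohort_small, frame_small, g.SplitPlan(seed=2), n_boot=0
        )
        test_idx = res["split"]["test"]
        n_agree = int(frame_small.agreement_mask[test_idx].sum())
        assert res["arms"]["train_val_test_val"].n == n_agree
        assert res["arms"]["train_val_test_ehr"].n == len(test_idx)

    def test_fixed_seeds_reproduce_evaluation_exactly(self, cohort_small, frame_small):
        kwargs = dict(plan=g.SplitPlan(seed=2), n_boot=150, eval_seed=5)
        a = g.run_label_source_experiment(cohort_small, frame_small, **kwargs)
        b = g.run_label_source_experiment(cohort_small, frame_small, **kwargs)
        for arm in a["arms"]:
            assert a["arms"][arm].to_dict() == b["arms"][arm].to_dict()


def test_evaluate_scores_flags_single_class(rng):
    ev = evaluate_scores(rng.random(10), np.ones(10, int), n_boot=0)
    assert ev.roc_auc is None and ev.average_precision == 1.0


def test_cross_validated_auc_runs(cohort_small):
    aucs = g.modeling.cross_validated_auc(
        cohort_small, cohort_small.truth, k=3, seed=0
    )
    assert len(aucs) == 3
    assert all(0.5 < a < 1.0 for a in aucs)
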