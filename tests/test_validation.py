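"""Fold construction, performance metrics, cross-validation, incomplete path."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qolmap.synthetic import CohortSpec, generate_cohort, generate_from_linear_model, \
    inject_item_missingness
from qolmap.validation import (
    compute_metrics,
    cross_validate,
    evaluate_incomplete,
    make_folds,
)
from conftest import REFERENCE_LINEAR


class TestMakeFolds:
    def test_study_sized_cohort_gives_equal_folds(self):
        fa = make_folds(1905, k=5, seed=1)
        sizes = np.bincount(fa.folds)[1:]
        assert sizes.tolist() == [381] * 5

    def test_remainder_goes_to_lowest_folds(self):
        fa = make_folds(10, k=3, seed=2)
        assert sorted(np.bincount(fa.folds)[1:], reverse=True) == [4, 3, 3]
        assert np.bincount(fa.folds)[1] == 4

    def test_same_seed_same_assignment(self):
        a = make_folds(100, k=5, seed=3)
        b = make_folds(100, k=5, seed=3)
        assert np.array_equal(a.folds, b.folds)

    def test_partition_covers_every_row_exactly_once(self):
        fa = make_folds(57, k=4, seed=4)
        assert len(fa.folds) == 57
        assert set(fa.folds) == {1, 2, 3, 4}
        for f in range(1, 5):
            assert len(np.intersect1d(fa.test_index(f), fa.train_index(f))) == 0

    def test_patient_grouping_keeps_patients_together(self):
        groups = np.repeat(np.arange(40), np.random.default_rng(5).integers(1, 8, 40))
        fa = make_folds(len(groups), k=5, seed=5, grouping="patient", groups=groups)
        df = pd.DataFrame({"g": groups, "f": fa.folds})
        assert (df.groupby("g")["f"].nunique() == 1).all()

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_folds(3, k=5)
        with pytest.raises(ValueError):
            make_folds(10, k=1)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        obs = np.array([0.2, 0.5, 0.9, 1.0])
        with pytest.warns(UserWarning, match="t-test undefined"):
            m = compute_metrics(obs, obs)
        assert m.rmse == 0.0 and m.mae == 0.0
        assert m.spearman == pytest.approx(1.0)
        assert np.isnan(m.t_pvalue)

    def test_two_point_arithmetic(self):
        m = compute_metrics([1.0, 0.0], [0.5, 0.5])
        assert m.rmse == pytest.approx(0.5)
        assert m.mae == pytest.approx(0.5)

    def test_monotone_transform_has_unit_rank_correlation(self):
        rng = np.random.default_rng(6)
        obs = rng.uniform(0, 1, 50)
        m = compute_metrics(obs, np.sqrt(obs) * 3 - 1)
        assert m.spearman == pytest.approx(1.0)

    @given(st.lists(st.floats(-1, 1), min_size=2, max_size=50),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_rmse_dominates_mae(self, obs, seed):
        pred = np.random.default_rng(seed).uniform(-1, 1, len(obs))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_metrics(np.array(obs), pred)
        assert m.rmse >= m.mae - 1e-12

    def test_row_order_invariance(self):
        rng = np.random.default_rng(7)
        obs, pred = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        a, b = compute_metrics(obs, pred), compute_metrics(obs[perm], pred[perm])
        for f in ("rmse", "mae", "spearman", "t_pvalue", "mean", "sd"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), nan_ok=True)

    def test_constant_vector_spearman_missing_with_warning(self):
        with pytest.warns(UserWarning, match="Spearman"):
            m = compute_metrics([0.1, 0.2, 0.3], [0.5, 0.5, 0.5])
        assert np.isnan(m.spearman)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 2], [1, 2, 3])


class ConstantModel:
    def __init__(self, value):
        self.value = value


class TestCrossValidate:
    def test_pooled_predictions_cover_the_whole_cohort(self, small_scored_cohort):
        cv = cross_validate("linear_scales", small_scored_cohort, k=5, seed=1)
        assert len(cv.predictions) == len(small_scored_cohort)
        assert sorted(cv.predictions["row"]) == list(range(len(small_scored_cohort)))
        assert cv.pooled.n == len(small_scored_cohort)

    def test_constant_only_model_reproduces_training_means(self):
        # 20-row toy cohort, hand-checkable: prediction on a held-out fold is
        # the mean utility of the other folds
        rng = np.random.default_rng(8)
        cohort = pd.DataFrame({
            "patient_id": np.arange(20), "utility": rng.uniform(0, 1, 20)})
        cv = cross_validate(
            "linear_scales", cohort, k=4, seed=9,
            fitter=lambda train: ConstantModel(train["utility"].mean()),
            predictor=lambda m, test: pd.Series(m.value, index=test.index),
        )
        fa = make_folds(20, k=4, seed=9)
        for fold in range(1, 5):
            expect = cohort.iloc[fa.train_index(fold)]["utility"].mean()
            got = cv.predictions.loc[cv.predictions["fold"] == fold, "predicted"]
            assert np.allclose(got, expect)

    def test_pooled_rmse_approaches_generating_noise_sd(self):
        d = generate_from_linear_model(REFERENCE_LINEAR, noise_sd=0.098,
                                       random_intercept_sd=0.0, seed=10,
                                       truncate_at=None)
        cv = cross_validate("linear_scales", d, k=5, seed=11)
        assert abs(cv.pooled.rmse - 0.098) / 0.098 < 0.10

    def test_rerun_is_deterministic(self, small_scored_cohort):
        a = cross_validate("beta", small_scored_cohort, k=3, seed=12)
        b = cross_validate("beta", small_scored_cohort, k=3, seed=12)
        assert a.to_dict() == b.to_dict()

    def test_failing_fold_is_flagged_not_silently_pooled(self, small_scored_cohort):
        calls = {"n": 0}

        def flaky(train):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("synthetic fit failure")
            return ConstantModel(train["utility"].mean())

        cv = cross_validate("linear_scales", small_scored_cohort, k=5, seed=13,
                            fitter=flaky,
                            predictor=lambda m, test: pd.Series(m.value, index=test.index))
        assert cv.failed_folds == [2]
        assert len(cv.predictions) == len(small_scored_cohort) * 4 // 5


class TestEvaluateIncomplete:
    @pytest.fixture(scope="class")
    def fitted(self, scored_cohort):
        from qolmap.validation import fit_family

        return {f: fit_family(f, scored_cohort)
                for f in ("linear_scales", "response_mapping", "beta",
                          "separate_equations")}

    def test_zero_missingness_equals_complete_evaluation(self, scored_cohort, fitted):
        res = evaluate_incomplete(scored_cohort.head(300), {"linear_scales":
                                                            fitted["linear_scales"]})
        assert res["linear_scales"]["n_eligible"] == 300

    def test_half_rule_excludes_rows_from_eligibility(self, scored_cohort, fitted):
        cohort = scored_cohort.head(200).copy()
        # wipe out pain entirely on the first 50 rows (both items)
        cohort.iloc[:50, cohort.columns.get_loc("q9")] = np.nan
        cohort.iloc[:50, cohort.columns.get_loc("q19")] = np.nan
        model = fitted["linear_scales"]
        if "pain" in model.model.inputs:
            res = evaluate_incomplete(cohort, {"linear_scales": model})
            assert res["linear_scales"]["n_eligible"] == 150

    def test_common_subset_runs_all_scale_score_families(self, fitted):
        # emulate the incomplete-questionnaire validation: a subset of ~120
        # rows on which all four scale-score families remain applicable
        cohort = generate_cohort(CohortSpec(seed=19, n_rows=600, n_patients=150))
        cohort = inject_item_missingness(cohort, 0.12, seed=20)
        incomplete = cohort[~cohort["complete"]]
        from qolmap.instruments import score_qlqc30, SCALE_NAMES

        scores = score_qlqc30(incomplete)
        common = incomplete[scores[SCALE_NAMES].notna().all(axis=1)]
        subset = common.head(120)
        assert len(subset) == 120
        res = evaluate_incomplete(subset, fitted)
        for family, entry in res.items():
            assert entry["n_eligible"] == 120
            assert entry["metrics"].rmse > 0
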