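"""Synthetic cohort generator: determinism, calibration, recovery harnesses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qolmap.instruments import EQ5D_DOMAINS, score_qlqc30
from qolmap.synthetic import (
    CohortSpec,
    generate_beta_disutility_data,
    generate_cohort,
    generate_from_linear_model,
    inject_item_missingness,
)
from conftest import REFERENCE_LINEAR


class TestGenerateCohort:
    def test_same_seed_gives_identical_cohorts(self):
        a = generate_cohort(CohortSpec(seed=7, n_rows=200, n_patients=50))
        b = generate_cohort(CohortSpec(seed=7, n_rows=200, n_patients=50))
        pd.testing.assert_frame_equal(a, b)

    def test_default_cohort_matches_published_marginals(self, default_cohort, scored_cohort):
        c, s = default_cohort, scored_cohort
        assert len(c) == 1905 and c["patient_id"].nunique() == 473
        # physical functioning mean within 2 SE of the published 82.681
        se = 17.195 / np.sqrt(len(c))
        assert abs(s["physical"].mean() - 82.681) < 2 * se
        # utility dispersion within 20% of the published SD 0.171
        assert 0.171 * 0.8 < c["utility"].std(ddof=1) < 0.171 * 1.2

    def test_complete_rows_yield_all_scale_scores(self, scored_cohort):
        scales = [k for k in score_qlqc30(scored_cohort[:1]).columns]
        assert scored_cohort.loc[scored_cohort["complete"], scales].notna().all().all()

    def test_utilities_consistent_with_generating_tariff(self, default_cohort, nl_value_set):
        recomputed = nl_value_set.utility_frame(default_cohort[EQ5D_DOMAINS])
        assert np.allclose(default_cohort["utility"], recomputed)

    def test_utility_ceiling_and_instrument_correlation(self, default_cohort, scored_cohort):
        assert (default_cohort["utility"] <= 1.0).all()
        rho = stats.spearmanr(default_cohort["utility"], scored_cohort["physical"]).statistic
        assert rho > 0.5

    def test_negative_utility_fraction_near_defaults_and_controllable(self, default_cohort):
        frac = (default_cohort["utility"] < 0).mean()
        assert 0.0005 < frac < 0.006  # ~0.2% tail at default settings
        forced = generate_cohort(CohortSpec(seed=3, n_rows=1000, n_patients=250,
                                            negative_utility_prob=0.05))
        assert (forced["utility"] < 0).mean() > 0.04

    def test_full_ceiling_mass_degenerates_to_full_health(self):
        c = generate_cohort(CohortSpec(seed=5, n_patients=40, n_rows=40, mean_visits=1.0,
                                       latent_between_sd=0.0, latent_within_sd=0.0,
                                       ceiling_mass=1.0))
        assert (c["utility"] == 1.0).all()
        assert (c[EQ5D_DOMAINS] == 1).all().all()

    def test_infeasible_targets_raise_configuration_errors(self):
        with pytest.raises(ValueError, match="outside"):
            CohortSpec(scale_targets={"physical": (140.0, 10.0)}).validate()
        with pytest.raises(ValueError):
            CohortSpec(item_missingness=1.5).validate()
        with pytest.raises(ValueError):
            CohortSpec(n_patients=0).validate()


class TestLinearRecoveryHarness:
    def test_intercept_only_model_is_constant(self):
        d = generate_from_linear_model({"intercept": 0.5}, n_rows=50, n_patients=10,
                                       noise_sd=0.0, random_intercept_sd=0.0, seed=1)
        assert np.allclose(d["utility"], 0.5)

    def test_reference_coefficients_at_full_health(self):
        # functional scores 100, symptoms 0: linear predictor 0.2993 + 0.68
        d = generate_from_linear_model(REFERENCE_LINEAR, n_rows=10, n_patients=2,
                                       noise_sd=0.0, random_intercept_sd=0.0, seed=1)
        full = {k: 100.0 for k in REFERENCE_LINEAR if k != "intercept"}
        full.update(pain=0.0, insomnia=0.0)
        lp = REFERENCE_LINEAR["intercept"] + sum(
            REFERENCE_LINEAR[k] * v for k, v in full.items())
        assert lp == pytest.approx(0.9793)

    def test_same_seed_gives_identical_tables(self):
        a = generate_from_linear_model(REFERENCE_LINEAR, seed=3)
        b = generate_from_linear_model(REFERENCE_LINEAR, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 1905

    def test_covariates_truncated_to_score_range(self):
        d = generate_from_linear_model(REFERENCE_LINEAR, n_rows=2000, seed=2)
        for k in REFERENCE_LINEAR:
            if k != "intercept":
                assert d[k].between(0, 100).all()

    def test_unknown_coefficient_name_rejected(self):
        with pytest.raises(ValueError, match="not a scale score"):
            generate_from_linear_model({"intercept": 0.5, "bogus": 1.0}, n_rows=10)

    def test_utilities_truncated_at_ceiling(self):
        d = generate_from_linear_model({"intercept": 1.2}, n_rows=100, n_patients=10,
                                       noise_sd=0.01, seed=4)
        assert (d["utility"] <= 1.0).all()


class TestBetaRecoveryHarness:
    def test_seeded_determinism_and_bounds(self):
        coeffs = {"intercept": -1.5, "physical": -0.01}
        a = generate_beta_disutility_data(coeffs, n_rows=300, seed=5)
        b = generate_beta_disutility_data(coeffs, n_rows=300, seed=5)
        pd.testing.assert_frame_equal(a, b)
        assert (a["utility"] <= 1.0).all()


class TestItemMissingness:
    def test_zero_rate_is_identity(self, default_cohort):
        out = inject_item_missingness(default_cohort, 0.0)
        pd.testing.assert_frame_equal(out, default_cohort)

    def test_functional_scales_remain_scorable(self):
        c = generate_cohort(CohortSpec(seed=9, n_rows=400, n_patients=100,
                                       item_missingness=0.2))
        scores = score_qlqc30(c)
        from qolmap.instruments import FUNCTIONAL_SCALES

        assert scores[FUNCTIONAL_SCALES].notna().all().all()

    def test_unprotected_item_deletion_rate_matches_binomial(self):
        c = generate_cohort(CohortSpec(seed=13, n_rows=2000, n_patients=500))
        out = inject_item_missingness(c, 0.2, seed=1)
        # q8 (dyspnea) is a single-item symptom scale, never restored
        frac = out["q8"].isna().mean()
        tol = 4 * np.sqrt(0.2 * 0.8 / len(out))
        assert abs(frac - 0.2) < tol
        assert not out.loc[out[[f"q{i}" for i in range(1, 31)]].isna().any(axis=1),
                           "complete"].any()

    def test_infeasible_rate_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            inject_item_missingness(default_cohort, 0.6)
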