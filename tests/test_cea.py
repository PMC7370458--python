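"""ICER arithmetic, method-of-moments distributions, probabilistic analysis."""

import numpy as np
import pytest
from scipy import stats

from qolmap.cea import (
    ArmUtilitySummary,
    CEAConfig,
    beta_from_moments,
    compare_icers,
    compare_utility_sources,
    icer,
    probabilistic_analysis,
)


class TestICER:
    def test_unit_qaly(self):
        assert icer(30_163, 1.0) == pytest.approx(30_163)

    def test_division_from_printed_rounded_inputs(self):
        # rounded incremental QALYs give ~168,508 (unrounded inputs differ)
        assert icer(30_163, 0.179) == pytest.approx(168_508, abs=1.0)

    def test_reported_point_estimate_difference(self):
        # reference vs mapped-utility point estimates: a 10,140 drop
        diffs = compare_icers([168_048.0, 157_908.0])
        assert diffs[1] == pytest.approx(-10_140.0)

    def test_homogeneity_under_joint_scaling(self):
        assert icer(2 * 30_163, 2 * 0.179) == pytest.approx(icer(30_163, 0.179))

    def test_zero_incremental_qaly_flags_dominance_boundary(self):
        with pytest.warns(UserWarning, match="dominance"):
            assert np.isnan(icer(1000.0, 0.0))


class TestBetaFromMoments:
    def test_symmetric_closed_form(self):
        a, b = beta_from_moments(0.5, 0.1)
        assert (a, b) == pytest.approx((12.0, 12.0))

    def test_round_trip_of_analytic_moments(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            mean = rng.uniform(0.05, 0.95)
            se = rng.uniform(0.005, 0.9) * np.sqrt(mean * (1 - mean))
            a, b = beta_from_moments(mean, se)
            assert a / (a + b) == pytest.approx(mean, abs=1e-12)
            var = a * b / ((a + b) ** 2 * (a + b + 1))
            assert np.sqrt(var) == pytest.approx(se, abs=1e-12)

    def test_sampled_mean_matches_input(self):
        a, b = beta_from_moments(0.83, 0.01)
        draws = np.random.default_rng(2).beta(a, b, 10**6)
        assert abs(draws.mean() - 0.83) < 3 * 0.01 / 1000

    def test_small_se_concentrates_mass(self):
        a, b = beta_from_moments(0.7, 1e-4)
        assert stats.beta.ppf(0.999, a, b) - stats.beta.ppf(0.001, a, b) < 0.01

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError):
            beta_from_moments(1.2, 0.1)
        with pytest.raises(ValueError):
            beta_from_moments(0.5, 0.6)  # se^2 >= mean(1-mean)


def _config(se1=0.008, se2=0.0055, n=2000, seed=0):
    return CEAConfig(
        arm1_utility=ArmUtilitySummary(0.829, se1, "observed"),
        arm2_utility=ArmUtilitySummary(0.839, se2, "observed"),
        time_in_state=(1.6, 1.6),
        fixed_qaly=(0.9, 1.063),
        incremental_cost=30_163.0,
        n_samples=n,
        seed=seed,
    )


class TestProbabilisticAnalysis:
    def test_cloud_size_and_seeded_determinism(self):
        a = probabilistic_analysis(_config(seed=5))
        b = probabilistic_analysis(_config(seed=5))
        assert len(a.cloud) == 2000
        assert a.cloud.equals(b.cloud)
        assert a.icer == b.icer

    def test_vanishing_se_recovers_deterministic_icer(self):
        res = probabilistic_analysis(_config(se1=1e-7, se2=1e-7))
        det_dq = (0.839 - 0.829) * 1.6 + (1.063 - 0.9)
        assert res.incremental_qaly == pytest.approx(det_dq, abs=1e-5)
        assert res.icer == pytest.approx(30_163.0 / det_dq, rel=1e-4)
        assert res.cloud["delta_qaly"].std() < 1e-5

    def test_cloud_mean_matches_deterministic_within_mc_error(self):
        res = probabilistic_analysis(_config(n=10_000))
        det_dq = (0.839 - 0.829) * 1.6 + (1.063 - 0.9)
        mc_se = res.cloud["delta_qaly"].std(ddof=1) / np.sqrt(len(res.cloud))
        assert abs(res.incremental_qaly - det_dq) < 3 * mc_se

    def test_interval_covers_point_estimate(self):
        res = probabilistic_analysis(_config(n=10_000))
        lo, hi = res.icer_ci
        assert lo < res.icer < hi


class TestCompareUtilitySources:
    def _sources(self):
        obs = (ArmUtilitySummary(0.829, 0.008, "observed"),
               ArmUtilitySummary(0.839, 0.0055, "observed"))
        mapped = (ArmUtilitySummary(0.836, 0.0053, "mapped"),
                  ArmUtilitySummary(0.837, 0.0041, "mapped"))
        return obs, mapped

    def test_identical_sources_have_zero_difference(self):
        obs, _ = self._sources()
        same = (ArmUtilitySummary(0.829, 0.008, "copy"),
                ArmUtilitySummary(0.839, 0.0055, "copy"))
        tbl = compare_utility_sources([obs, same], (1.6, 1.6), (0.9, 1.063),
                                      30_163.0, n_samples=1000, seed=3)
        assert tbl["icer_difference"].iloc[1] == 0.0

    def test_larger_qaly_gain_lowers_the_icer(self):
        obs, _ = self._sources()
        better = (ArmUtilitySummary(0.82, 0.008, "better"),
                  ArmUtilitySummary(0.87, 0.0055, "better"))
        tbl = compare_utility_sources([obs, better], (1.6, 1.6), (0.9, 1.063),
                                      30_163.0, n_samples=1000, seed=4)
        assert tbl["icer"].iloc[1] < tbl["icer"].iloc[0]
        assert tbl["icer_difference"].iloc[1] < 0

    def test_cloud_exported_once_per_sample(self):
        obs, mapped = self._sources()
        tbl = compare_utility_sources([obs, mapped], (1.6, 1.6), (0.9, 1.063),
                                      30_163.0, n_samples=500, seed=5)
        for res in tbl.attrs["results"]:
            assert len(res.cloud) == 500

    def test_mismatched_source_tags_rejected(self):
        obs, _ = self._sources()
        bad = (ArmUtilitySummary(0.8, 0.01, "a"), ArmUtilitySummary(0.8, 0.01, "b"))
        with pytest.raises(ValueError, match="disagree"):
            compare_utility_sources([obs, bad], (1.6, 1.6), (0.9, 1.063), 30_163.0,
                                    n_samples=100)


class TestValidation:
    def test_arm_summary_invariants(self):
        with pytest.raises(ValueError):
            ArmUtilitySummary(1.2, 0.01)
        with pytest.raises(ValueError):
            ArmUtilitySummary(0.8, 0.0)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            CEAConfig(ArmUtilitySummary(0.8, 0.01), ArmUtilitySummary(0.8, 0.01),
                      time_in_state=(-1.0, 1.0), fixed_qaly=(0, 0),
                      incremental_cost=0.0)
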