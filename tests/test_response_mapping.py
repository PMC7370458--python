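"""Ordered-logit response mapping: probabilities, fitting, both scoring modes."""

import numpy as np
import pandas as pd
import pytest

from qolmap.instruments import EQ5D_DOMAINS, FUNCTIONAL_SCALES
from qolmap.response_mapping import (
    OrderedLogitDomainModel,
    ResponseMappingModel,
    domain_level_probs,
    fit_response_mapping,
    predict_response_mapping,
)
from qolmap.serialize import load_model, save_model


def _const_model(kappa1=0.0, kappa2=np.log(3)):
    """Domain model with empty coefficient map: latent L = -kappa1."""
    return OrderedLogitDomainModel("mobility", {}, kappa1, kappa2)


def _scores(n=1):
    return pd.DataFrame({s: np.zeros(n) for s in FUNCTIONAL_SCALES})


class TestDomainLevelProbs:
    def test_logistic_arithmetic_at_zero_latent(self):
        # L = 0, kappa = ln 3: (1/2, 3/4 - 1/2, 1/4 - 0) = (0.5, 0.25, 0.25)
        p = domain_level_probs(_const_model(), _scores())
        assert p.iloc[0].tolist() == pytest.approx([0.5, 0.25, 0.25], abs=1e-12)

    def test_probabilities_always_sum_to_one(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            coefs = dict(zip(FUNCTIONAL_SCALES, rng.normal(0, 0.1, 5)))
            k1 = rng.normal(0, 3)
            m = OrderedLogitDomainModel("mobility", coefs, k1, k1 + rng.uniform(0.1, 5))
            scores = pd.DataFrame(rng.uniform(0, 100, (20, 5)), columns=FUNCTIONAL_SCALES)
            p = domain_level_probs(m, scores)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert (p >= 0).all().all()

    def test_extreme_latent_limits(self):
        m = _const_model(kappa1=1000.0, kappa2=1001.0)  # L -> -inf
        p = domain_level_probs(m, _scores())
        assert p.iloc[0].tolist() == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)

    def test_thresholds_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            OrderedLogitDomainModel("mobility", {}, 1.0, 0.5)


class TestFitResponseMapping:
    @pytest.fixture(scope="class")
    def physical_driven(self):
        """Domain levels depend only on physical functioning."""
        rng = np.random.default_rng(3)
        n = 1200
        scores = pd.DataFrame(rng.uniform(0, 100, (n, 5)), columns=FUNCTIONAL_SCALES)
        latent = -0.06 * scores["physical"] + rng.logistic(size=n)
        data = scores.copy()
        for d in EQ5D_DOMAINS:
            data[d] = np.where(latent < -4.5, 1, np.where(latent < -1.5, 2, 3))
        return data

    def test_dominant_coefficient_identified(self, physical_driven):
        model = fit_response_mapping(physical_driven)
        for d in EQ5D_DOMAINS:
            coefs = model[d].coefficients
            assert abs(coefs["physical"]) > 5 * max(
                abs(v) for k, v in coefs.items() if k != "physical")
            assert coefs["physical"] < 0  # better function, lower level

    def test_fitted_thresholds_strictly_increase(self, physical_driven):
        model = fit_response_mapping(physical_driven)
        for d in EQ5D_DOMAINS:
            assert model[d].kappa2 > model[d].kappa1

    def test_refit_is_deterministic(self, physical_driven):
        a = fit_response_mapping(physical_driven)
        b = fit_response_mapping(physical_driven)
        for d in EQ5D_DOMAINS:
            for k in a[d].coefficients:
                assert a[d].coefficients[k] == pytest.approx(b[d].coefficients[k], abs=1e-8)

    def test_single_level_domain_raises_by_name(self, physical_driven):
        bad = physical_driven.copy()
        bad["self_care"] = 1
        with pytest.raises(ValueError, match="self_care"):
            fit_response_mapping(bad)


class TestPrediction:
    def _model_all_domains(self, kappa1, kappa2):
        return ResponseMappingModel(
            domains={d: OrderedLogitDomainModel(d, {}, kappa1, kappa2)
                     for d in EQ5D_DOMAINS})

    def test_degenerate_full_health_in_both_modes(self, toy_value_set):
        model = self._model_all_domains(1000.0, 1001.0)  # P(level 1) = 1 everywhere
        for mode in ("most_likely", "expected"):
            pred = predict_response_mapping(model, _scores(3), toy_value_set, mode=mode)
            assert np.allclose(pred, 1.0)
            assert pred.attrs["mode"] == mode

    def test_modes_agree_at_one_hot_vertices(self, toy_value_set):
        model = self._model_all_domains(-1000.0, 2000.0)  # P(level 2) = 1 everywhere
        ml = predict_response_mapping(model, _scores(2), toy_value_set, "most_likely")
        ex = predict_response_mapping(model, _scores(2), toy_value_set, "expected")
        assert np.allclose(ml, ex, atol=1e-9)
        assert np.allclose(ml, 1.0 - 5 * 0.1)

    def test_expected_mode_decrement_arithmetic(self, toy_value_set):
        # all domains at (0.5, 0.25, 0.25): 1 - 5*(0.25*0.1 + 0.25*0.3) = 0.5
        model = self._model_all_domains(0.0, np.log(3))
        pred = predict_response_mapping(model, _scores(), toy_value_set, "expected")
        assert pred.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_expected_mode_permutation_invariance(self, toy_value_set):
        # permuting which domain carries which probabilities leaves the
        # expectation unchanged under a symmetric additive tariff
        k = np.log(3)
        base = [OrderedLogitDomainModel(d, {}, off, off + k)
                for d, off in zip(EQ5D_DOMAINS, [-1.0, 0.0, 1.0, 2.0, -2.0])]
        perm = list(np.roll(np.arange(5), 2))
        m1 = ResponseMappingModel(domains={m.domain: m for m in base})
        m2 = ResponseMappingModel(domains={
            EQ5D_DOMAINS[i]: OrderedLogitDomainModel(EQ5D_DOMAINS[i], {},
                                                     base[j].kappa1, base[j].kappa2)
            for i, j in enumerate(perm)})
        p1 = predict_response_mapping(m1, _scores(), toy_value_set, "expected")
        p2 = predict_response_mapping(m2, _scores(), toy_value_set, "expected")
        assert p1.iloc[0] == pytest.approx(p2.iloc[0], abs=1e-12)

    def test_serialization_round_trip(self, tmp_path, toy_value_set):
        model = self._model_all_domains(0.3, 1.7)
        path = tmp_path / "rm.json"
        save_model(model, path)
        back = load_model(path)
        a = predict_response_mapping(model, _scores(4), toy_value_set, "expected")
        b = predict_response_mapping(back, _scores(4), toy_value_set, "expected")
        assert np.array_equal(a.to_numpy(), b.to_numpy())
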