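"""Response mapping: ordered-logit models per EQ-5D-3L domain.

Instead of regressing the utility itself, the response-mapping family
predicts each EQ-5D-3L domain's response level (1 = no problems, 2 = some,
3 = extreme) from the five QLQ-C30 functional scale scores with a
proportional-odds (ordered logit) model, and only then scores the
predicted response with a tariff.  The approach is therefore
tariff-independent until the final scoring step.

With L the latent linear predictor relative to the first threshold and
kappa the offset of the second threshold, the level probabilities are

    Prob1 = 1 / (1 + e^L)
    Prob2 = 1 / (1 + e^(L - kappa)) - 1 / (1 + e^L)
    Prob3 = 1 - Prob1 - Prob2

Two prediction modes are available: ``most_likely`` picks the modal level
per domain and scores the resulting state; ``expected`` averages the
tariff over the full joint level distribution (domains independent given
the scores).  No backward selection is applied in this family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel

from qolmap.instruments import EQ5D_DOMAINS, FUNCTIONAL_SCALES, ValueSet

logger = logging.getLogger(__name__)

__all__ = [
    "OrderedLogitDomainModel",
    "ResponseMappingModel",
    "fit_response_mapping",
    "domain_level_probs",
    "predict_response_mapping",
]


@dataclass
class OrderedLogitDomainModel:
    """Proportional-odds model for one EQ-5D domain.

    ``kappa1`` anchors level 1 vs higher; ``kappa2`` (None when level 3 was
    never observed in training) anchors levels <=2 vs 3.  Coefficients are
    on the latent scale where higher values mean a *worse* level.
    """

    domain: str
    coefficients: Mapping[str, float]
    kappa1: float
    kappa2: float | None

    def __post_init__(self):
        if self.kappa2 is not None and not self.kappa2 > self.kappa1:
            raise ValueError(
                f"domain {self.domain}: thresholds must be strictly increasing "
                f"(kappa1={self.kappa1}, kappa2={self.kappa2})"
            )

    def latent(self, scores: pd.DataFrame) -> np.ndarray:
        """Linear predictor L relative to the first threshold."""
        for name in self.coefficients:
            if name not in scores.columns:
                raise ValueError(f"missing required predictor {name!r}")
            if scores[name].isna().any():
                raise ValueError(f"missing values in required predictor {name!r}")
        X = scores[list(self.coefficients)].to_numpy(dtype=float)
        beta = np.array(list(self.coefficients.values()))
        return X @ beta - self.kappa1


@dataclass
class ResponseMappingModel:
    """Five per-domain ordered-logit models plus metadata."""

    domains: Mapping[str, OrderedLogitDomainModel]
    scales: Sequence[str] = tuple(FUNCTIONAL_SCALES)
    mode: str = "most_likely"
    meta: dict = field(default_factory=dict)

    def __getitem__(self, domain: str) -> OrderedLogitDomainModel:
        return self.domains[domain]


def fit_response_mapping(
    data: pd.DataFrame,
    scales: Sequence[str] = tuple(FUNCTIONAL_SCALES),
    domains: Sequence[str] = tuple(EQ5D_DOMAINS),
) -> ResponseMappingModel:
    """Fit one ordered-logit model per EQ-5D domain on functional scores.

    Requires every domain to show at least two distinct observed levels;
    a single-level domain raises a degenerate-domain error by name.
    """
    models: dict[str, OrderedLogitDomainModel] = {}
    X = data[list(scales)]
    if X.isna().any().any():
        raise ValueError("missing functional scale scores in training data")
    for domain in domains:
        levels = pd.to_numeric(data[domain], errors="raise").astype(int)
        observed = np.unique(levels)
        if len(observed) < 2:
            raise ValueError(
                f"degenerate domain {domain!r}: single observed level {observed[0]}"
            )
        endog = pd.Categorical(levels, categories=sorted(observed), ordered=True)
        res = OrderedModel(endog, X, distr="logit").fit(method="bfgs", disp=0, maxiter=500)
        k = len(scales)
        thresholds = res.model.transform_threshold_params(res.params)  # [-inf, k1(, k2), inf]
        coefs = dict(zip(scales, map(float, res.params[:k])))
        kappa1 = float(thresholds[1])
        if len(observed) == 3:
            kappa2 = float(thresholds[2])
        else:
            kappa2 = None
            logger.warning("domain %s: level 3 unobserved in training; Prob3 fixed at 0", domain)
        models[domain] = OrderedLogitDomainModel(domain, coefs, kappa1, kappa2)
    return ResponseMappingModel(domains=models, scales=tuple(scales),
                                meta={"n_obs": int(len(data))})


def domain_level_probs(model: OrderedLogitDomainModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Level probabilities (columns p1, p2, p3) for each row of scores."""
    L = model.latent(scores)
    p1 = expit(-L)  # 1 / (1 + e^L)
    if model.kappa2 is None:
        p2 = 1.0 - p1
        p3 = np.zeros_like(p1)
    else:
        kappa = model.kappa2 - model.kappa1
        p2 = expit(kappa - L) - p1
        p3 = 1.0 - p1 - p2
    out = pd.DataFrame({"p1": p1, "p2": np.clip(p2, 0.0, 1.0), "p3": np.clip(p3, 0.0, 1.0)},
                       index=scores.index)
    return out


def predict_response_mapping(
    model: ResponseMappingModel,
    scores: pd.DataFrame,
    value_set: ValueSet,
    mode: str | None = None,
) -> pd.Series:
    """Predict utilities from functional scale scores.

    ``most_likely``: per domain take the argmax-probability level (ties go
    to the better level and are logged) and score that state.
    ``expected``: average the tariff over the joint distribution of the
    five domain levels, i.e. sum over all 243 states of P(state) * u(state)
    — for a purely additive tariff this equals constant minus the
    probability-weighted decrements.  The mode used is recorded in the
    returned Series' ``attrs``.
    """
    mode = mode or model.mode
    if mode not in ("most_likely", "expected"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    probs = {d: domain_level_probs(m, scores).to_numpy() for d, m in model.domains.items()}

    if mode == "most_likely":
        state = pd.DataFrame(index=scores.index)
        for d in EQ5D_DOMAINS:
            P = probs[d]
            lv = np.argmax(P, axis=1) + 1  # first max wins -> better level on ties
            n_ties = int(np.sum(np.sum(P == P.max(axis=1, keepdims=True), axis=1) > 1))
            if n_ties:
                logger.info("domain %s: %d probability ties resolved to the better level",
                            d, n_ties)
            state[d] = lv
        pred = value_set.utility_frame(state)
    else:
        utilities = np.array(
            [value_set.utility(dict(zip(EQ5D_DOMAINS, lv)))
             for lv in product((1, 2, 3), repeat=5)]
        )
        joint = np.ones((len(scores), 1))
        for d in EQ5D_DOMAINS:  # running tensor product over domains
            joint = (joint[:, :, None] * probs[d][:, None, :]).reshape(len(scores), -1)
        pred = pd.Series(joint @ utilities, index=scores.index)
    pred = pred.rename("predicted_utility")
    pred.attrs["mode"] = mode
    pred.attrs["tariff"] = value_set.name
    return pred
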