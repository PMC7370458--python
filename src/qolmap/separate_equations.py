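"""Separate-equations mixture: subgroup regressions weighted by class probabilities.

The utility distribution has three qualitatively different regions: a
ceiling spike at exactly 1, a bulk between 0.6 and 1, and a low tail below
0.6 (related to scoring "extreme problems" on some EQ-5D-3L dimension).
This family first fits a 3-class multinomial logit on the scale scores for
class membership {u < 0.6, 0.6 <= u < 1, u = 1}, then fits the model-1
recipe (random intercept, selection, pruning) separately on the low and
mid subgroups, and predicts

    u_hat = P(low) * u_low + P(mid) * u_mid + P(u = 1) * 1.

The multinomial step is exempt from backward selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.discrete.discrete_model import MNLogit

from qolmap.linear_models import SCALE_CANDIDATES, LinearMappingModel, fit_linear, predict_linear
from qolmap.selection import DEFAULT_ALPHA, FitResult

logger = logging.getLogger(__name__)

__all__ = ["SeparateEquationsModel", "fit_separate_equations", "predict_separate_equations"]

CLASS_LABELS = ("low", "mid", "one")
LOW_THRESHOLD = 0.6
CEILING_TOL = 1e-12


@dataclass
class SeparateEquationsModel:
    """Multinomial class model plus low/mid linear submodels."""

    class_coefficients: Mapping[str, Mapping[str, float]]  # per non-baseline class
    class_inputs: Sequence[str]
    low_model: LinearMappingModel
    mid_model: LinearMappingModel
    threshold: float = LOW_THRESHOLD
    family: str = "separate_equations"
    meta: dict = field(default_factory=dict)

    def class_probs(self, data: pd.DataFrame) -> pd.DataFrame:
        """P(low), P(mid), P(one) per row (softmax, baseline class ``low``)."""
        for t in self.class_inputs:
            if t not in data.columns:
                raise ValueError(f"missing required predictor {t!r}")
        X = np.column_stack(
            [np.ones(len(data))] + [pd.to_numeric(data[t], errors="coerce").to_numpy()
                                    for t in self.class_inputs]
        )
        if np.isnan(X).any():
            raise ValueError("missing values among class-model predictors")
        eta = np.zeros((len(data), 3))
        for j, label in enumerate(CLASS_LABELS[1:], start=1):
            coefs = self.class_coefficients[label]
            beta = np.array([coefs["const"]] + [coefs[t] for t in self.class_inputs])
            eta[:, j] = X @ beta
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=data.index, columns=list(CLASS_LABELS))


def _classify(utility: pd.Series, threshold: float) -> pd.Series:
    u = pd.to_numeric(utility, errors="coerce")
    cls = pd.Series("mid", index=u.index)
    cls[u < threshold] = "low"
    cls[u >= 1.0 - CEILING_TOL] = "one"
    return cls


def fit_separate_equations(
    data: pd.DataFrame,
    outcome: str = "utility",
    cluster_key: str = "patient_id",
    alpha: float = DEFAULT_ALPHA,
    threshold: float = LOW_THRESHOLD,
    method: str = "reml",
) -> FitResult:
    """Fit the separate-equations family; every class must be populated."""
    cls = _classify(data[outcome], threshold)
    counts = cls.value_counts()
    for label in CLASS_LABELS:
        if counts.get(label, 0) == 0:
            raise ValueError(
                f"empty utility class {label!r} (counts: {counts.to_dict()}); "
                "the separate-equations family needs all three classes in training"
            )
    codes = cls.map({label: i for i, label in enumerate(CLASS_LABELS)}).to_numpy()
    X = pd.DataFrame({"const": np.ones(len(data))})
    for t in SCALE_CANDIDATES:
        X[t] = pd.to_numeric(data[t], errors="coerce").to_numpy()
    if X.isna().any().any():
        raise ValueError("missing scale scores among class-model predictors")
    mn = MNLogit(codes, X).fit(method="newton", maxiter=200, disp=0)
    class_coefs = {
        label: dict(zip(X.columns, map(float, mn.params.iloc[:, j - 1])))
        for j, label in enumerate(CLASS_LABELS[1:], start=1)
    }

    low_fit = fit_linear(data[cls == "low"], "linear_scales", outcome=outcome,
                         cluster_key=cluster_key, alpha=alpha, method=method)
    mid_fit = fit_linear(data[cls == "mid"], "linear_scales", outcome=outcome,
                         cluster_key=cluster_key, alpha=alpha, method=method)

    model = SeparateEquationsModel(
        class_coefficients=class_coefs,
        class_inputs=list(SCALE_CANDIDATES),
        low_model=low_fit.model,
        mid_model=mid_fit.model,
        threshold=threshold,
        meta={"class_counts": {k: int(v) for k, v in counts.items()},
              "n_obs": int(len(data))},
    )
    history = (
        [dict(h, submodel="low") for h in low_fit.history]
        + [dict(h, submodel="mid") for h in mid_fit.history]
    )
    # the headline summary reports the mid (bulk) submodel; submodel fits kept in meta
    return FitResult(model=model, family="separate_equations", summary=mid_fit.summary,
                     history=history, alpha=alpha,
                     meta={"low_summary": low_fit.summary, "mid_summary": mid_fit.summary,
                           "class_counts": model.meta["class_counts"]})


def predict_separate_equations(model: SeparateEquationsModel, data: pd.DataFrame) -> pd.Series:
    """Probability-weighted combination of the submodel predictions and 1."""
    probs = model.class_probs(data)
    u_low = predict_linear(model.low_model, data)
    u_mid = predict_linear(model.mid_model, data)
    pred = probs["low"] * u_low + probs["mid"] * u_mid + probs["one"] * 1.0
    return pred.rename("predicted_utility")
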