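"""Linear mapping families: utilities regressed on QLQ-C30 inputs.

Three predictor families share one estimation recipe (random-intercept
panel model, cluster-robust inference, backward selection, sign pruning):

- ``linear_scales``   : the five functional and nine symptom scale scores;
- ``linear_items``    : the 30 raw items treated as continuous covariates;
- ``linear_dummies``  : one indicator per item level above the reference
                        level 1 (levels 2-4, or 2-7 for q29/q30).

Predictions are the raw linear predictor: no clipping is applied, so a
mapped utility can exceed the observed range — a documented property of
linear mapping algorithms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from qolmap.instruments import FUNCTIONAL_SCALES, ITEM_COLUMNS, ITEM_MAX, SYMPTOM_SCALES
from qolmap.random_intercept import fit_random_intercept
from qolmap.selection import (
    DEFAULT_ALPHA,
    INTERCEPT,
    FitResult,
    SignConvention,
    _summary_frame,
    select_and_prune,
)

logger = logging.getLogger(__name__)

__all__ = ["LinearMappingModel", "candidate_terms", "design_matrix", "fit_linear", "predict_linear"]

LINEAR_FAMILIES = ("linear_scales", "linear_items", "linear_dummies")

#: model-1 candidate set: functional and symptom scale scores (global health
#: enters only the beta family)
SCALE_CANDIDATES = FUNCTIONAL_SCALES + SYMPTOM_SCALES


@dataclass
class LinearMappingModel:
    """A fitted (or published) linear utility-mapping coefficient set."""

    family: str
    intercept: float
    coefficients: Mapping[str, float]
    residual_sd: float | None = None
    random_intercept_var: float | None = None
    cov_type: str = "cluster"
    tariff: str | None = None
    name: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in LINEAR_FAMILIES:
            raise ValueError(f"unknown linear family {self.family!r}")
        for term in self.coefficients:
            _validate_term(self.family, term)

    @property
    def inputs(self) -> list[str]:
        return list(self.coefficients)


def _validate_term(family: str, term: str) -> None:
    if family == "linear_scales":
        if term not in SCALE_CANDIDATES + ["global_health"]:
            raise ValueError(f"{term!r} is not a QLQ-C30 scale score")
    elif family == "linear_items":
        if term not in ITEM_COLUMNS:
            raise ValueError(f"{term!r} is not a QLQ-C30 item")
    else:
        item, _, lv = term.partition("_lv")
        if item not in ITEM_COLUMNS or not lv.isdigit() or not 2 <= int(lv) <= ITEM_MAX[item]:
            raise ValueError(f"{term!r} is not a valid item-level dummy (reference is level 1)")


def candidate_terms(family: str) -> list[str]:
    """The full candidate predictor set of a linear family."""
    if family == "linear_scales":
        return list(SCALE_CANDIDATES)
    if family == "linear_items":
        return list(ITEM_COLUMNS)
    if family == "linear_dummies":
        return [f"{c}_lv{lv}" for c in ITEM_COLUMNS for lv in range(2, ITEM_MAX[c] + 1)]
    raise ValueError(f"unknown linear family {family!r}")


def design_matrix(data: pd.DataFrame, family: str, terms: Sequence[str],
                  intercept: bool = True) -> pd.DataFrame:
    """Design matrix for a term list; raises naming any missing predictor."""
    cols = {}
    if intercept:
        cols[INTERCEPT] = np.ones(len(data))
    for term in terms:
        _validate_term(family, term)
        if family == "linear_dummies":
            item, _, lv = term.partition("_lv")
            src, needed = item, item
        else:
            src, needed = term, term
        if needed not in data.columns:
            raise ValueError(f"missing required predictor {needed!r}")
        vals = pd.to_numeric(data[src], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"missing values in required predictor {needed!r}")
        cols[term] = (vals == int(term.partition("_lv")[2])).astype(float) \
            if family == "linear_dummies" else vals.astype(float)
    return pd.DataFrame(cols, index=data.index)


def fit_linear(
    data: pd.DataFrame,
    family: str = "linear_scales",
    outcome: str = "utility",
    cluster_key: str = "patient_id",
    alpha: float = DEFAULT_ALPHA,
    select: bool = True,
    candidates: Sequence[str] | None = None,
    method: str = "reml",
) -> FitResult:
    """Fit a linear mapping family with selection and sign pruning.

    ``method="reml"`` (default) estimates the random-intercept model;
    ``method="ols"`` falls back to pooled OLS with cluster-robust errors.
    ``select=False`` fits the candidate set as-is (used e.g. for
    parameter-recovery runs where the predictor set is fixed).
    Zero-variance candidates are dropped with a warning before fitting.
    """
    if cluster_key not in data.columns:
        raise ValueError(f"cluster column {cluster_key!r} not in data")
    terms = list(candidates) if candidates is not None else candidate_terms(family)
    X_full = design_matrix(data, family, terms)
    y = pd.to_numeric(data[outcome], errors="coerce")
    if y.isna().any():
        raise ValueError(f"missing values in outcome {outcome!r}")
    groups = data[cluster_key].to_numpy()

    degenerate = [t for t in terms if X_full[t].std() == 0.0]
    for t in degenerate:
        warnings.warn(f"dropping zero-variance predictor {t!r} before fitting", stacklevel=2)
        terms.remove(t)

    def refit(current: Sequence[str]):
        return fit_random_intercept(y, X_full[[INTERCEPT, *current]], groups, method=method)

    convention = SignConvention.for_items() if family == "linear_items" else (
        SignConvention.for_dummies() if family == "linear_dummies"
        else SignConvention.for_scale_scores())
    if select:
        fit, terms, history = select_and_prune(refit, terms, convention, alpha)
    else:
        fit, history = refit(terms), []

    model = LinearMappingModel(
        family=family,
        intercept=float(fit.params[INTERCEPT]),
        coefficients={t: float(fit.params[t]) for t in terms},
        residual_sd=fit.resid_sd,
        random_intercept_var=fit.tau2,
        cov_type=fit.cov_type,
        meta={"method": method, "n_obs": fit.n_obs, "n_clusters": fit.n_clusters},
    )
    return FitResult(model=model, family=family, summary=_summary_frame(fit),
                     history=history, alpha=alpha, convention=convention,
                     meta=dict(model.meta, outcome=outcome))


def predict_linear(model: LinearMappingModel, data: pd.DataFrame) -> pd.Series:
    """Utility predictions: intercept + sum(coefficient * predictor).

    ``data`` must carry every predictor the model names (scale-score
    columns, item columns, or item columns for the dummy family), with no
    missing values among them; a missing predictor raises by name.
    """
    X = design_matrix(data, model.family, model.inputs, intercept=False)
    beta = np.array([model.coefficients[t] for t in model.inputs])
    pred = model.intercept + X.to_numpy() @ beta
    return pd.Series(pred, index=data.index, name="predicted_utility")
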