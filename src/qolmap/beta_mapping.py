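"""Beta-regression mapping on the disutility scale.

Utilities are bounded above by 1 and heavily right-skewed, so this family
models the *disutility* d = 1 - u as a beta-distributed outcome with a
logit mean link and constant precision.  A beta outcome must lie strictly
inside (0, 1), while observed disutilities include exact 0 (full health)
and, rarely, values above 1 (utilities below 0, i.e. states worse than
dead).  Disutilities above 1 are first truncated to 1 (logged count), then
the standard open-interval compression with calibration sample size N

    y' = (d * (N - 1) + 0.5) / N          (inverse: d = (y' * N - 0.5) / (N - 1))

maps [0, 1] into (0, 1).  N is fixed at fit time and stored with the model
so predictions invert the same transform.  Candidate predictors are global
health plus the functional and symptom scale scores; backward selection
and sign pruning run on the link scale, where the expected signs are the
reverse of the utility-scale convention (pain worsens disutility: +).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

from qolmap.instruments import FUNCTIONAL_SCALES, SYMPTOM_SCALES
from qolmap.selection import (
    DEFAULT_ALPHA,
    INTERCEPT,
    FitResult,
    SignConvention,
    select_and_prune,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BetaTransformSpec",
    "BetaMappingModel",
    "to_open_interval",
    "from_open_interval",
    "fit_beta",
    "predict_beta",
]

#: beta-family candidate set: global health plus all scale scores
BETA_CANDIDATES = ["global_health"] + FUNCTIONAL_SCALES + SYMPTOM_SCALES


@dataclass(frozen=True)
class BetaTransformSpec:
    """Open-interval compression calibrated on N observations."""

    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("transform sample size N must be >= 2")


def to_open_interval(disutility, spec: BetaTransformSpec):
    """Map disutilities in [0, 1] into (0, 1); values > 1 truncate to 1."""
    d = np.asarray(disutility, dtype=float)
    n_over = int(np.sum(d > 1.0))
    if n_over:
        warnings.warn(
            f"truncating {n_over} disutilities > 1 (negative utilities) to 1 "
            "before the open-interval transform", stacklevel=2)
        d = np.minimum(d, 1.0)
    if np.any(d < 0.0):
        raise ValueError("disutility below 0 (utility above 1) is not representable")
    return (d * (spec.n - 1) + 0.5) / spec.n


def from_open_interval(y, spec: BetaTransformSpec):
    """Inverse compression; exact round trip for inputs in [0, 1]."""
    y = np.asarray(y, dtype=float)
    return (y * spec.n - 0.5) / (spec.n - 1)


@dataclass
class BetaMappingModel:
    """Fitted beta-regression mapping (link-scale coefficients)."""

    intercept: float
    coefficients: Mapping[str, float]
    precision: float
    transform: BetaTransformSpec
    link: str = "logit"
    family: str = "beta"
    meta: dict = field(default_factory=dict)

    @property
    def inputs(self) -> list[str]:
        return list(self.coefficients)


class _BetaFitAdapter:
    """Expose the mean-submodel inference of a BetaModel fit by term name."""

    def __init__(self, res, names):
        k = len(names)
        idx = pd.Index(names)
        self.params = pd.Series(np.asarray(res.params[:k]), index=idx)
        self.bse = pd.Series(np.asarray(res.bse[:k]), index=idx)
        self.tvalues = pd.Series(np.asarray(res.tvalues[:k]), index=idx)
        self.pvalues = pd.Series(np.asarray(res.pvalues[:k]), index=idx)
        ci = np.asarray(res.conf_int())[:k]
        self.conf_int = pd.DataFrame(ci, index=idx, columns=["lower", "upper"])
        with np.errstate(over="ignore"):
            self.precision = float(np.exp(res.params[k]))  # log-link precision
        self.res = res


def fit_beta(
    data: pd.DataFrame,
    outcome: str = "utility",
    alpha: float = DEFAULT_ALPHA,
    select: bool = True,
    candidates: Sequence[str] | None = None,
) -> FitResult:
    """Fit the beta-regression mapping family with selection and pruning."""
    if len(data) < 2:
        raise ValueError("need at least 2 rows to fit the beta family")
    u = pd.to_numeric(data[outcome], errors="coerce")
    if u.isna().any():
        raise ValueError(f"missing values in outcome {outcome!r}")
    if (u > 1.0 + 1e-12).any():
        raise ValueError("utilities above 1 are not valid")
    spec = BetaTransformSpec(n=len(data))
    y = to_open_interval(1.0 - u.to_numpy(), spec)

    terms = list(candidates) if candidates is not None else list(BETA_CANDIDATES)
    for t in terms:
        if t not in data.columns:
            raise ValueError(f"missing required predictor {t!r}")
        if data[t].isna().any():
            raise ValueError(f"missing values in required predictor {t!r}")
    degenerate = [t for t in terms if data[t].std() == 0.0]
    for t in degenerate:
        warnings.warn(f"dropping zero-variance predictor {t!r} before fitting", stacklevel=2)
        terms.remove(t)

    def refit(current: Sequence[str]):
        names = [INTERCEPT, *current]
        X = pd.DataFrame({INTERCEPT: np.ones(len(data))})
        for t in current:
            X[t] = pd.to_numeric(data[t], errors="coerce").to_numpy()
        # deterministic warm start: OLS on the logit scale, moment-based precision
        eta = logit(y)
        Xm = X.to_numpy()
        start_mean, *_ = np.linalg.lstsq(Xm, eta, rcond=None)
        mu0 = expit(Xm @ start_mean)
        resid_var = max(np.var(y - mu0), 1e-6)
        phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
        start = np.append(start_mean, np.log(phi0))
        model = BetaModel(y, X, exog_precision=np.ones((len(data), 1)))
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(start_params=res.params, method="nm", maxiter=5000, disp=0)
        return _BetaFitAdapter(res, names)

    convention = SignConvention.for_scale_scores(scale="disutility")
    if select:
        fit, terms, history = select_and_prune(refit, terms, convention, alpha)
    else:
        fit, history = refit(terms), []

    model = BetaMappingModel(
        intercept=float(fit.params[INTERCEPT]),
        coefficients={t: float(fit.params[t]) for t in terms},
        precision=fit.precision,
        transform=spec,
        meta={"n_obs": int(len(data))},
    )
    summary = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues,
         "ci_low": fit.conf_int["lower"], "ci_high": fit.conf_int["upper"]}
    )
    return FitResult(model=model, family="beta", summary=summary, history=history,
                     alpha=alpha, convention=convention,
                     meta={"n_obs": int(len(data)), "outcome": outcome})


def predict_beta(model: BetaMappingModel, data: pd.DataFrame) -> pd.Series:
    """Predicted utilities: 1 - inverse-transformed mean disutility.

    Predictions lie strictly inside the image of the inverse transform, so
    they can never reach 1 exactly nor fall to the tariff floor.
    """
    for t in model.inputs:
        if t not in data.columns:
            raise ValueError(f"missing required predictor {t!r}")
        if data[t].isna().any():
            raise ValueError(f"missing values in required predictor {t!r}")
    X = data[model.inputs].to_numpy(dtype=float)
    beta = np.array([model.coefficients[t] for t in model.inputs])
    mu = expit(model.intercept + X @ beta)
    pred = 1.0 - from_open_interval(mu, model.transform)
    return pd.Series(pred, index=data.index, name="predicted_utility")
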