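"""Cross-validation harness and prediction-performance metrics.

Performance of a mapping algorithm is summarized by the mean/SD/min/max of
its predictions, the root mean squared error and mean absolute error
against the observed utilities, the Spearman rank correlation, and a
(paired, by default) t-test of predicted vs observed.  Model development
is evaluated with k-fold cross-validation: the full fitting procedure —
including backward selection and sign pruning — is re-run on the training
folds and scored on the held-out fold, and the held-out predictions are
pooled (and also reported per fold).

Incomplete questionnaires are handled without imputation: a row enters
the incomplete-evaluation path only if every scale score a model needs is
computable under the half-completion rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from qolmap.beta_mapping import BETA_CANDIDATES, fit_beta, predict_beta
from qolmap.instruments import FUNCTIONAL_SCALES, ValueSet, load_value_set, score_qlqc30
from qolmap.linear_models import SCALE_CANDIDATES, fit_linear, predict_linear
from qolmap.response_mapping import fit_response_mapping, predict_response_mapping
from qolmap.separate_equations import fit_separate_equations, predict_separate_equations

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "PerformanceMetrics",
    "CVReport",
    "MODEL_FAMILIES",
    "make_folds",
    "compute_metrics",
    "cross_validate",
    "evaluate_incomplete",
    "fit_family",
    "predict_family",
]


@dataclass(frozen=True)
class FoldAssignment:
    """Per-row fold indices (1..k)."""

    folds: np.ndarray
    k: int
    grouping: str
    seed: int

    def test_index(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    def train_index(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds != fold)


@dataclass
class PerformanceMetrics:
    """Summary of predicted utilities against observed ones."""

    n: int
    mean: float
    sd: float
    min: float
    max: float
    rmse: float
    mae: float
    spearman: float
    t_pvalue: float

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items()}

    def round(self, ndigits: int = 3) -> dict:
        """Presentation rounding (3 decimals, matching reporting convention)."""
        return {k: (round(v, ndigits) if isinstance(v, float) and not np.isnan(v) else v)
                for k, v in self.__dict__.items()}


@dataclass
class CVReport:
    """Per-fold and pooled cross-validated performance for one family."""

    family: str
    k: int
    seed: int
    fold_metrics: list[PerformanceMetrics]
    pooled: PerformanceMetrics
    per_fold_mean: dict
    predictions: pd.DataFrame = field(repr=False, default=None)
    failed_folds: list[int] = field(default_factory=list)

    def to_dict(self, include_predictions: bool = False) -> dict:
        d = {
            "family": self.family,
            "k": self.k,
            "seed": self.seed,
            "fold_metrics": [m.to_dict() for m in self.fold_metrics],
            "pooled": self.pooled.to_dict(),
            "per_fold_mean": self.per_fold_mean,
            "failed_folds": self.failed_folds,
        }
        if include_predictions and self.predictions is not None:
            d["predictions"] = self.predictions.to_dict(orient="list")
        return d


def make_folds(n_rows: int, k: int = 5, seed: int = 0, grouping: str = "row",
               groups=None) -> FoldAssignment:
    """Random partition into k folds.

    Row-level (default): fold sizes differ by at most one, remainder rows
    going to the lowest-index folds.  Patient-level (``grouping="patient"``,
    needs ``groups``): whole patients are assigned, largest patients first,
    each to the currently smallest fold after a seeded shuffle.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if grouping == "row":
        sizes = np.full(k, n_rows // k)
        sizes[: n_rows % k] += 1
        labels = np.repeat(np.arange(1, k + 1), sizes)
        folds = np.empty(n_rows, dtype=int)
        folds[rng.permutation(n_rows)] = labels
    elif grouping == "patient":
        if groups is None:
            raise ValueError("patient-level folding needs the groups argument")
        groups = np.asarray(groups)
        if len(groups) != n_rows:
            raise ValueError("groups must have one entry per row")
        uniq, counts = np.unique(groups, return_counts=True)
        order = rng.permutation(len(uniq))
        uniq, counts = uniq[order], counts[order]
        order = np.argsort(-counts, kind="stable")
        assignment = {}
        load = np.zeros(k)
        for i in order:
            f = int(np.argmin(load))
            assignment[uniq[i]] = f + 1
            load[f] += counts[i]
        folds = np.array([assignment[g] for g in groups])
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return FoldAssignment(folds=folds, k=k, grouping=grouping, seed=seed)


def compute_metrics(observed, predicted, paired_ttest: bool = True) -> PerformanceMetrics:
    """Prediction-error metrics over paired observed/predicted utilities."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = ~(np.isnan(obs) | np.isnan(pred))
    obs, pred = obs[ok], pred[ok]
    n = len(obs)
    if n < 2:
        raise ValueError("need at least 2 non-missing pairs")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        rho = np.nan
    else:
        rho = float(stats.spearmanr(obs, pred).statistic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired_ttest:
            p = float(stats.ttest_rel(pred, obs).pvalue) if np.ptp(err) > 0 else np.nan
        else:
            p = float(stats.ttest_ind(pred, obs).pvalue)
    if np.isnan(p):
        warnings.warn("zero-variance differences: t-test undefined", stacklevel=2)
    return PerformanceMetrics(
        n=n, mean=float(pred.mean()), sd=float(pred.std(ddof=1)),
        min=float(pred.min()), max=float(pred.max()),
        rmse=rmse, mae=mae, spearman=rho, t_pvalue=p,
    )


# --- model-family registry -------------------------------------------------

#: scale columns each family needs at prediction time (None = raw items)
MODEL_FAMILIES: dict[str, dict] = {
    "linear_scales": {"needs_scales": SCALE_CANDIDATES},
    "linear_items": {"needs_scales": None},
    "linear_dummies": {"needs_scales": None},
    "response_mapping": {"needs_scales": FUNCTIONAL_SCALES},
    "beta": {"needs_scales": BETA_CANDIDATES},
    "separate_equations": {"needs_scales": SCALE_CANDIDATES},
}


def fit_family(family: str, train: pd.DataFrame, value_set: ValueSet | str = "NL",
               alpha: float = 0.05, method: str = "reml"):
    """Run a family's full fitting procedure on training data."""
    if family in ("linear_scales", "linear_items", "linear_dummies"):
        return fit_linear(train, family, alpha=alpha, method=method)
    if family == "response_mapping":
        return fit_response_mapping(train)
    if family == "beta":
        return fit_beta(train, alpha=alpha)
    if family == "separate_equations":
        return fit_separate_equations(train, alpha=alpha, method=method)
    raise ValueError(f"unknown model family {family!r}")


def predict_family(family: str, fitted, test: pd.DataFrame,
                   value_set: ValueSet | str = "NL") -> pd.Series:
    model = getattr(fitted, "model", fitted)
    if family in ("linear_scales", "linear_items", "linear_dummies"):
        return predict_linear(model, test)
    if family == "response_mapping":
        vs = load_value_set(value_set) if isinstance(value_set, str) else value_set
        return predict_response_mapping(model, test, vs)
    if family == "beta":
        return predict_beta(model, test)
    if family == "separate_equations":
        return predict_separate_equations(model, test)
    raise ValueError(f"unknown model family {family!r}")


def cross_validate(
    family: str,
    cohort: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    value_set: ValueSet | str = "NL",
    grouping: str = "row",
    alpha: float = 0.05,
    method: str = "reml",
    fitter: Callable | None = None,
    predictor: Callable | None = None,
) -> CVReport:
    """k-fold cross-validation of a family's full fitting procedure.

    The cohort must contain complete rows only (all predictors present).
    A fold whose fit fails is flagged in ``failed_folds`` and excluded
    from pooling rather than silently dropped.  ``fitter``/``predictor``
    may override the registry (e.g. for a constant-only reference model).
    """
    cohort = cohort.reset_index(drop=True)
    fa = make_folds(len(cohort), k=k, seed=seed, grouping=grouping,
                    groups=cohort["patient_id"] if grouping == "patient" else None)
    fitter = fitter or (lambda train: fit_family(family, train, value_set, alpha, method))
    predictor = predictor or (lambda fitted, test: predict_family(family, fitted, test, value_set))

    fold_metrics: list[PerformanceMetrics] = []
    failed: list[int] = []
    parts: list[pd.DataFrame] = []
    for fold in range(1, k + 1):
        train = cohort.iloc[fa.train_index(fold)]
        test = cohort.iloc[fa.test_index(fold)]
        try:
            fitted = fitter(train)
            pred = predictor(fitted, test)
        except Exception as exc:  # noqa: BLE001 - fold failure is reported, not fatal
            logger.warning("fold %d: fitting failed (%s)", fold, exc)
            failed.append(fold)
            continue
        fold_metrics.append(compute_metrics(test["utility"], pred))
        parts.append(pd.DataFrame({
            "row": test.index, "fold": fold,
            "observed": test["utility"].to_numpy(), "predicted": np.asarray(pred),
        }))
    if not parts:
        raise RuntimeError(f"every fold failed for family {family!r}")
    predictions = pd.concat(parts, ignore_index=True).sort_values("row").reset_index(drop=True)
    pooled = compute_metrics(predictions["observed"], predictions["predicted"])
    numeric = [f for f in PerformanceMetrics.__dataclass_fields__ if f != "n"]
    per_fold_mean = {f: float(np.mean([getattr(m, f) for m in fold_metrics])) for f in numeric}
    return CVReport(family=family, k=k, seed=seed, fold_metrics=fold_metrics,
                    pooled=pooled, per_fold_mean=per_fold_mean,
                    predictions=predictions, failed_folds=failed)


def eligible_incomplete_rows(cohort: pd.DataFrame, needed_scales: Sequence[str]) -> pd.DataFrame:
    """Score an incomplete cohort and keep rows whose needed scales exist."""
    scores = score_qlqc30(cohort)
    ok = scores[list(needed_scales)].notna().all(axis=1)
    out = cohort.loc[ok].copy()
    for c in scores.columns:
        out[c] = scores.loc[ok, c]
    return out


def evaluate_incomplete(
    cohort: pd.DataFrame,
    fitted_models: Mapping[str, object],
    value_set: ValueSet | str = "NL",
) -> dict[str, dict]:
    """Evaluate fitted scale-score models on incomplete questionnaires.

    ``fitted_models`` maps family name -> fitted model (families that need
    raw items are rejected).  Rows are restricted, per model, to those
    whose required scale scores are computable under the half rule; the
    eligible count is reported alongside the metrics.
    """
    results: dict[str, dict] = {}
    for family, fitted in fitted_models.items():
        needed = MODEL_FAMILIES[family]["needs_scales"]
        if needed is None:
            raise ValueError(f"family {family!r} needs raw items; "
                             "it cannot be evaluated on incomplete questionnaires")
        model = getattr(fitted, "model", fitted)
        needed = getattr(model, "inputs", None) or needed
        elig = eligible_incomplete_rows(cohort, needed)
        if len(elig) == 0:
            raise ValueError(f"no eligible incomplete rows for family {family!r}")
        pred = predict_family(family, fitted, elig, value_set)
        results[family] = {
            "n_eligible": int(len(elig)),
            "metrics": compute_metrics(elig["utility"], pred),
        }
    return results
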