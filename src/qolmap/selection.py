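"""Backward selection and non-logical-coefficient pruning.

All mapping families except the response-mapping family (and the
multinomial step of the separate-equations family) are reduced in two
steps:

1. *Backward selection*: starting from the family's full candidate set,
   the single coefficient with the largest p-value above the cut-off
   (alpha = 0.05) is removed and the model refit, until every remaining
   coefficient is significant.  Ties on p-value are broken towards the
   smaller absolute coefficient, then lexicographically.  The intercept is
   never a candidate for removal.
2. *Sign pruning*: coefficients whose sign contradicts the clinical
   expectation (a "non-logical" coefficient, e.g. more nausea predicting a
   *better* utility) are removed, the model refit and backward selection
   re-run, iterating to a fixed point.

Both steps work through a ``refit`` callback so the same logic drives the
linear panel families and the beta-regression family.  Every removal is
recorded in the selection history with its reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import pandas as pd

from qolmap.instruments import FUNCTIONAL_SCALES, ITEM_MAX, SCALE_NAMES, SYMPTOM_SCALES

logger = logging.getLogger(__name__)

__all__ = ["SignConvention", "FitResult", "backward_select", "prune_nonlogical", "select_and_prune"]

INTERCEPT = "const"
DEFAULT_ALPHA = 0.05
MAX_PRUNE_ITERATIONS = 20


@dataclass(frozen=True)
class SignConvention:
    """Expected coefficient sign per candidate predictor.

    On the utility scale, functional scales (and global health) carry an
    expected positive sign and symptom scales a negative one; raw items
    q1-q28 are "higher = worse" hence negative, while q29/q30 are
    "higher = better" hence positive, and item-level dummies inherit the
    sign of their item.  On the disutility / link scale (the beta family)
    every expectation is reversed.
    """

    expected: Mapping[str, int]
    scale: str = "utility"

    def expected_sign(self, name: str) -> int:
        if name not in self.expected:
            raise KeyError(f"no expected sign declared for predictor {name!r}")
        return self.expected[name]

    def violations(self, params: pd.Series) -> list[str]:
        """Names of surviving coefficients with an incongruous sign."""
        bad = []
        for name, coef in params.items():
            if name == INTERCEPT or name not in self.expected:
                continue
            if coef != 0 and (1 if coef > 0 else -1) != self.expected[name]:
                bad.append(name)
        return bad

    @staticmethod
    def _flip(table: dict[str, int], scale: str) -> dict[str, int]:
        if scale == "utility":
            return table
        if scale == "disutility":
            return {k: -v for k, v in table.items()}
        raise ValueError(f"unknown scale {scale!r}")

    @classmethod
    def for_scale_scores(cls, scale: str = "utility") -> "SignConvention":
        table = {name: 1 for name in FUNCTIONAL_SCALES}
        table["global_health"] = 1
        table.update({name: -1 for name in SYMPTOM_SCALES})
        return cls(cls._flip(table, scale), scale)

    @classmethod
    def for_items(cls, scale: str = "utility") -> "SignConvention":
        table = {f"q{i}": (-1 if i <= 28 else 1) for i in range(1, 31)}
        return cls(cls._flip(table, scale), scale)

    @classmethod
    def for_dummies(cls, scale: str = "utility") -> "SignConvention":
        table = {}
        for i in range(1, 31):
            sign = -1 if i <= 28 else 1
            for level in range(2, ITEM_MAX[f"q{i}"] + 1):
                table[f"q{i}_lv{level}"] = sign
        return cls(cls._flip(table, scale), scale)


@dataclass
class FitResult:
    """A fitted mapping model plus its inference and selection audit trail.

    ``summary`` has one row per surviving term (including the intercept)
    with columns coef, se, t, p, ci_low, ci_high.  ``history`` records each
    removed term as ``{"term", "reason" ("p_value" | "sign"), "p", "coef"}``
    in removal order.
    """

    model: Any
    family: str
    summary: pd.DataFrame
    history: list[dict] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA
    convention: SignConvention | None = None
    meta: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.summary["coef"]

    @property
    def pvalues(self) -> pd.Series:
        return self.summary["p"]

    @property
    def terms(self) -> list[str]:
        return [t for t in self.summary.index if t != INTERCEPT]

    def dropped(self, reason: str | None = None) -> list[str]:
        return [h["term"] for h in self.history if reason is None or h["reason"] == reason]

    def assert_sound(self) -> None:
        """Raise if any surviving term is non-significant or wrong-signed."""
        bad_p = self.pvalues.drop(INTERCEPT, errors="ignore")
        bad_p = bad_p[bad_p > self.alpha]
        if len(bad_p):
            raise AssertionError(f"non-significant surviving terms: {dict(bad_p)}")
        if self.convention is not None:
            bad = self.convention.violations(self.params)
            if bad:
                raise AssertionError(f"wrong-signed surviving terms: {bad}")


def _summary_frame(fit) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": fit.conf_int["lower"],
            "ci_high": fit.conf_int["upper"],
        }
    )


def _worst_term(fit, terms: Sequence[str], alpha: float) -> str | None:
    """Largest-p term above alpha; ties to smaller |coef| then name."""
    cand = [t for t in terms if fit.pvalues[t] > alpha]
    if not cand:
        return None
    return max(cand, key=lambda t: (fit.pvalues[t], -abs(fit.params[t]), _neg_name(t)))


class _neg_name(str):
    # reverse lexicographic comparison so max() prefers the *earlier* name
    def __lt__(self, other):
        return str(self) > str(other)


def backward_select(
    refit: Callable[[Sequence[str]], Any],
    terms: Sequence[str],
    alpha: float = DEFAULT_ALPHA,
    history: list[dict] | None = None,
):
    """Iteratively drop the least significant term until all p <= alpha.

    ``refit(terms)`` must return a fit exposing ``params``/``pvalues``/
    ``bse``/``tvalues``/``conf_int`` indexed by term names plus the
    intercept.  Returns ``(fit, surviving_terms, history)``.  If every term
    is eliminated an intercept-only model is returned with a warning.
    """
    terms = list(terms)
    history = history if history is not None else []
    fit = refit(terms)
    while terms:
        worst = _worst_term(fit, terms, alpha)
        if worst is None:
            break
        history.append(
            {"term": worst, "reason": "p_value",
             "p": float(fit.pvalues[worst]), "coef": float(fit.params[worst])}
        )
        logger.info("backward selection: dropping %s (p=%.4g)", worst, fit.pvalues[worst])
        terms.remove(worst)
        fit = refit(terms)
    if not terms:
        warnings.warn("backward selection eliminated every predictor; "
                      "returning an intercept-only model", stacklevel=2)
    return fit, terms, history


def prune_nonlogical(
    refit: Callable[[Sequence[str]], Any],
    fit,
    terms: Sequence[str],
    convention: SignConvention,
    alpha: float = DEFAULT_ALPHA,
    history: list[dict] | None = None,
):
    """Remove wrong-signed coefficients and iterate with backward selection.

    All sign violations are removed simultaneously, the model refit, and
    backward selection re-run; the loop repeats until no violation remains
    (at most ``MAX_PRUNE_ITERATIONS`` rounds).
    """
    terms = list(terms)
    history = history if history is not None else []
    for _ in range(MAX_PRUNE_ITERATIONS):
        bad = [t for t in convention.violations(fit.params) if t in terms]
        if not bad:
            return fit, terms, history
        for t in bad:
            history.append(
                {"term": t, "reason": "sign",
                 "p": float(fit.pvalues[t]), "coef": float(fit.params[t])}
            )
            logger.info("sign pruning: dropping %s (coef=%.4g, expected sign %+d)",
                        t, fit.params[t], convention.expected_sign(t))
            terms.remove(t)
        fit, terms, history = backward_select(refit, terms, alpha, history)
    warnings.warn("sign pruning did not reach a fixed point within "
                  f"{MAX_PRUNE_ITERATIONS} iterations", stacklevel=2)
    return fit, terms, history


def select_and_prune(
    refit: Callable[[Sequence[str]], Any],
    terms: Sequence[str],
    convention: SignConvention,
    alpha: float = DEFAULT_ALPHA,
):
    """Full two-step reduction; returns ``(fit, terms, history)``."""
    fit, terms, history = backward_select(refit, terms, alpha)
    return prune_nonlogical(refit, fit, terms, convention, alpha, history)
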