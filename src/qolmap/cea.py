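"""ICER sensitivity to the utility source, with probabilistic analysis.

The original cost-effectiveness evaluation behind the motivating study is
a discrete-event simulation that cannot be reconstructed from published
material; what this layer preserves is the question it was used to
answer: *how much does the choice of utility source (observed vs mapped)
move the ICER?*  The model here is a transparent two-arm algebraic QALY
model: each arm accrues

    QALY_arm = utility_arm * time_in_state + fixed_qaly_arm

where ``time_in_state`` covers the health state in which utilities were
measured and ``fixed_qaly`` the (literature-informed) contribution of
subsequent states.  Incremental costs are a fixed input.  Parameter
uncertainty in the utilities is propagated by drawing each arm's utility
from a beta distribution matched to its (mean, SE) by the method of
moments; the ICER point estimate is mean incremental cost over mean
incremental QALYs of the cloud, with a percentile 95% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmUtilitySummary",
    "CEAConfig",
    "ICERResult",
    "icer",
    "beta_from_moments",
    "probabilistic_analysis",
    "compare_utility_sources",
    "compare_icers",
]


@dataclass(frozen=True)
class ArmUtilitySummary:
    """Mean utility and its standard error for one treatment arm."""

    mean: float
    se: float
    source: str = "observed"

    def __post_init__(self):
        if self.mean > 1.0:
            raise ValueError("mean utility cannot exceed 1")
        if self.se <= 0.0:
            raise ValueError("utility SE must be positive")


@dataclass(frozen=True)
class CEAConfig:
    """Two-arm configuration; arm 1 is the reference (e.g. observation)."""

    arm1_utility: ArmUtilitySummary
    arm2_utility: ArmUtilitySummary
    time_in_state: tuple[float, float]
    fixed_qaly: tuple[float, float]
    incremental_cost: float
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if any(t < 0 for t in self.time_in_state):
            raise ValueError("time in state must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclass
class ICERResult:
    """Point estimates plus the probabilistic cloud."""

    incremental_cost: float
    incremental_qaly: float
    icer: float
    source: str
    cloud: pd.DataFrame = field(repr=False, default=None)  # delta_qaly, delta_cost
    icer_ci: tuple[float, float] | None = None
    dominance_boundary: bool = False

    def to_dict(self, include_cloud: bool = False) -> dict:
        d = {
            "source": self.source,
            "incremental_cost": self.incremental_cost,
            "incremental_qaly": self.incremental_qaly,
            "icer": None if np.isnan(self.icer) else self.icer,
            "icer_ci": None if self.icer_ci is None else list(self.icer_ci),
            "dominance_boundary": self.dominance_boundary,
        }
        if include_cloud and self.cloud is not None:
            d["cloud"] = self.cloud.to_dict(orient="list")
        return d


def icer(incremental_cost: float, incremental_qaly: float) -> float:
    """Incremental cost-effectiveness ratio in cost units per QALY."""
    if incremental_qaly == 0.0:
        warnings.warn("zero incremental QALYs: ICER undefined (dominance boundary)",
                      stacklevel=2)
        return np.nan
    return incremental_cost / incremental_qaly


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters (a, b) matching a mean and standard error.

    nu = mean (1 - mean) / se^2 - 1;  a = mean nu, b = (1 - mean) nu.
    The resulting distribution reproduces the input moments exactly.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"method of moments needs 0 < mean < 1, got {mean}")
    if se <= 0.0 or se**2 >= mean * (1.0 - mean):
        raise ValueError(f"infeasible moments for a beta distribution: mean={mean}, se={se}")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    return mean * nu, (1.0 - mean) * nu


def _qaly(utility, time_in_state: float, fixed: float):
    return utility * time_in_state + fixed


def probabilistic_analysis(config: CEAConfig) -> ICERResult:
    """Monte-Carlo propagation of utility uncertainty into the ICER."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    draws = []
    for arm in (config.arm1_utility, config.arm2_utility):
        a, b = beta_from_moments(arm.mean, arm.se)
        draws.append(rng.beta(a, b, size=config.n_samples))
    q1 = _qaly(draws[0], config.time_in_state[0], config.fixed_qaly[0])
    q2 = _qaly(draws[1], config.time_in_state[1], config.fixed_qaly[1])
    dq = q2 - q1
    dc = np.full(config.n_samples, float(config.incremental_cost))
    cloud = pd.DataFrame({"delta_qaly": dq, "delta_cost": dc})
    mean_dq = float(dq.mean())
    point = icer(float(dc.mean()), mean_dq) if mean_dq != 0.0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = dc / dq
    finite = ratios[np.isfinite(ratios)]
    ci = (float(np.percentile(finite, 2.5)), float(np.percentile(finite, 97.5))) \
        if len(finite) else None
    return ICERResult(
        incremental_cost=float(dc.mean()),
        incremental_qaly=mean_dq,
        icer=point,
        source=config.arm1_utility.source,
        cloud=cloud,
        icer_ci=ci,
        dominance_boundary=mean_dq == 0.0,
    )


def compare_utility_sources(
    sources: Sequence[tuple[ArmUtilitySummary, ArmUtilitySummary]],
    time_in_state: tuple[float, float],
    fixed_qaly: tuple[float, float],
    incremental_cost: float,
    n_samples: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One PSA per utility source; differences against the first source.

    All sources share costs, state times and the Monte-Carlo seed (common
    random numbers, so source differences are not blurred by sampling
    noise and identical sources give identical results); the first source
    (by convention the observed utilities) is the reference for the
    reported ICER differences.  Returns one row per source.
    """
    if len(sources) < 2:
        raise ValueError("need at least two utility sources to compare")
    results = []
    for i, (arm1, arm2) in enumerate(sources):
        if arm1.source != arm2.source:
            raise ValueError(f"source {i}: arm summaries disagree on the source tag")
        cfg = CEAConfig(arm1_utility=arm1, arm2_utility=arm2,
                        time_in_state=time_in_state, fixed_qaly=fixed_qaly,
                        incremental_cost=incremental_cost,
                        n_samples=n_samples, seed=seed)  # common random numbers
        results.append(probabilistic_analysis(cfg))
    ref = results[0]
    rows = []
    for res in results:
        rows.append({
            "source": res.source,
            "incremental_cost": res.incremental_cost,
            "incremental_qaly": res.incremental_qaly,
            "icer": res.icer,
            "icer_ci_low": None if res.icer_ci is None else res.icer_ci[0],
            "icer_ci_high": None if res.icer_ci is None else res.icer_ci[1],
            "icer_difference": res.icer - ref.icer,
        })
    out = pd.DataFrame(rows)
    out.attrs["results"] = results
    return out


def compare_icers(point_estimates: Sequence[float], reference_index: int = 0) -> list[float]:
    """Differences of ICER point estimates against a reference estimate."""
    ref = point_estimates[reference_index]
    return [float(v - ref) for v in point_estimates]
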