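"""Synthetic paired QLQ-C30 / EQ-5D-3L panel cohorts.

No patient-level data from the motivating metastatic colorectal cancer
cohort are available, so the analysis runs on synthetic cohorts that
reproduce its published statistical structure: ~473 patients contributing
~1905 paired questionnaires over repeated visits, scale-score marginals
with the published means, EQ-5D domain-level frequencies, a right-skewed
utility distribution with a ceiling at 1 and a ~0.2% tail of negative
utilities, and within-patient correlation across visits.

Mechanism.  Each patient carries a latent health trait; each visit adds
within-patient noise.  The standardized visit latent drives, through
ordinal cutpoints, (a) every QLQ-C30 item (via an item-specific loading,
so items of a scale are correlated but not collinear) and (b) every EQ-5D
domain level.  Cutpoints are moment-matched: item cutpoints are solved so
each scale's mean equals its target; domain cutpoints are placed at the
normal quantiles of the target level frequencies.  The observed utility
is always the generating tariff applied to the generated EQ-5D response,
so both instruments are internally consistent and correlated.

A second generator family produces parameter-recovery datasets: scale
scores drawn from truncated normals with the published moments, and
outcomes built from a *known* coefficient set (linear with random
intercept, or beta on the transformed disutility scale), so that fitting
procedures can be checked against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from qolmap.beta_mapping import BetaTransformSpec, from_open_interval
from qolmap.instruments import (
    EQ5D_DOMAINS,
    FUNCTIONAL_SCALES,
    ITEM_COLUMNS,
    ITEM_MAX,
    SCALES,
    ValueSet,
    load_value_set,
)

__all__ = [
    "CohortSpec",
    "DEFAULT_SCALE_TARGETS",
    "DEFAULT_EQ5D_LEVEL_FREQS",
    "generate_cohort",
    "generate_from_linear_model",
    "generate_beta_disutility_data",
    "inject_item_missingness",
    "default_covariate_spec",
]

#: published cohort scale-score moments (mean, SD) used as generator targets
DEFAULT_SCALE_TARGETS: dict[str, tuple[float, float]] = {
    "physical": (82.681, 17.195),
    "role": (76.947, 24.218),
    "emotional": (85.744, 15.829),
    "cognitive": (89.221, 15.294),
    "social": (86.177, 18.718),
    "global_health": (74.711, 17.464),
    "fatigue": (24.205, 20.059),
    "nausea_vomiting": (4.234, 11.286),
    "pain": (13.508, 20.705),
    "dyspnea": (10.866, 19.061),
    "insomnia": (15.083, 22.297),
    "appetite_loss": (9.729, 19.651),
    "constipation": (6.824, 15.917),
    "diarrhea": (10.569, 19.363),
    "financial": (6.229, 15.978),
}

#: published EQ-5D-3L level frequencies per domain (levels 1/2/3)
DEFAULT_EQ5D_LEVEL_FREQS: dict[str, tuple[float, float, float]] = {
    "mobility": (0.579, 0.418, 0.003),
    "self_care": (0.934, 0.061, 0.004),  # published row sums to 0.999
    "usual_activities": (0.575, 0.385, 0.039),
    "pain_discomfort": (0.602, 0.384, 0.014),
    "anxiety_depression": (0.772, 0.218, 0.010),
}


@dataclass(frozen=True)
class CohortSpec:
    """Generator configuration; defaults reproduce the published cohort shape.

    ``latent_between_sd`` / ``latent_within_sd`` set the patient-trait vs
    visit-noise split of the (internally standardized) latent, i.e. the
    within-patient correlation.  ``item_loading`` is each item's
    correlation with the visit latent; ``utility_noise_sd`` is extra
    visit-level noise entering only the EQ-5D side, loosening the coupling
    between the two instruments.  ``ceiling_mass`` adds a forced
    fully-healthy spike; ``negative_utility_prob`` a forced worst-state
    spike on top of the latent mechanism, which at the default settings
    already yields a ~0.2% tail of worse-than-dead observations.
    ``n_rows`` pins the
    total questionnaire count exactly; visit counts per patient are
    1 + Poisson(mean_visits - 1), adjusted to the pinned total.
    """

    n_patients: int = 473
    n_rows: int | None = 1905
    mean_visits: float = 4.03
    latent_between_sd: float = 0.75
    latent_within_sd: float = 0.66
    item_loading: float = 0.8
    utility_noise_sd: float = 1.0
    item_spacing: float = 1.1
    global_item_spacing: float = 0.8
    scale_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALE_TARGETS))
    eq5d_level_freqs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EQ5D_LEVEL_FREQS))
    ceiling_mass: float = 0.0
    negative_utility_prob: float = 0.0
    item_missingness: float = 0.0
    value_set: str = "NL"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("latent_between_sd", "latent_within_sd", "utility_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("ceiling_mass", "negative_utility_prob", "item_missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.item_loading <= 1.0:
            raise ValueError("item_loading must lie in (0, 1]")
        for scale, (m, _) in self.scale_targets.items():
            if scale not in SCALES:
                raise ValueError(f"unknown scale {scale!r} in scale_targets")
            if not 0.0 <= m <= 100.0:
                raise ValueError(f"target mean for {scale} outside [0, 100]: {m}")
        for dom, freqs in self.eq5d_level_freqs.items():
            if dom not in EQ5D_DOMAINS:
                raise ValueError(f"unknown EQ-5D domain {dom!r}")
            if any(f < 0 for f in freqs):
                raise ValueError(f"negative level frequency for {dom}")


def _item_cutpoints(mean_level: float, n_levels: int, spacing: float) -> np.ndarray:
    """Severity cutpoints giving an item the requested mean level.

    The item level is modeled as a discretized shifted normal: level >= k
    iff the standard-normal severity exceeds tau_k, with tau_k = d_k - mu
    on an equally spaced grid d_k and mu solved so that
    E[level] = 1 + sum_k Phi(mu - d_k) equals the target.
    """
    target = mean_level - 1.0
    kmax = n_levels - 1
    if target <= 1e-9:
        return np.full(kmax, np.inf)
    if target >= kmax - 1e-9:
        return np.full(kmax, -np.inf)
    d = (np.arange(2, n_levels + 1) - 1.5) * spacing

    def excess(mu):
        return stats.norm.cdf(mu - d).sum() - target

    lo, hi = d.min() - 12.0, d.max() + 12.0
    mu = optimize.brentq(excess, lo, hi, xtol=1e-12)
    return d - mu


def _ordinal_from_latent(severity: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    return 1 + (severity[:, None] > cutpoints[None, :]).sum(axis=1)


def generate_cohort(spec: CohortSpec | None = None, **overrides) -> pd.DataFrame:
    """Generate a paired panel cohort as one long DataFrame.

    Columns: patient_id, visit, q1..q30, the five EQ-5D domain levels,
    ``utility`` (generating tariff applied to the generated response) and a
    ``complete`` flag.  Same spec and seed give byte-identical output.
    """
    spec = replace(spec or CohortSpec(), **overrides)
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_struct, rng_items, rng_domains, rng_spikes, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5))

    # visit counts, pinned to the requested total
    counts = 1 + rng_struct.poisson(max(spec.mean_visits - 1.0, 0.0), size=spec.n_patients)
    if spec.n_rows is not None:
        if spec.n_rows < spec.n_patients:
            raise ValueError("n_rows must be >= n_patients (every patient has >= 1 visit)")
        diff = int(spec.n_rows - counts.sum())
        i = 0
        while diff != 0:
            j = i % spec.n_patients
            if diff > 0:
                counts[j] += 1
                diff -= 1
            elif counts[j] > 1:
                counts[j] -= 1
                diff += 1
            i += 1
    n = int(counts.sum())
    patient = np.repeat(np.arange(1, spec.n_patients + 1), counts)
    visit = np.concatenate([np.arange(1, c + 1) for c in counts])

    # standardized visit latent (higher = healthier)
    total_sd = float(np.hypot(spec.latent_between_sd, spec.latent_within_sd))
    if total_sd == 0.0:
        z = np.zeros(n)
    else:
        trait = rng_struct.normal(0.0, spec.latent_between_sd, size=spec.n_patients)
        z = (np.repeat(trait, counts)
             + rng_struct.normal(0.0, spec.latent_within_sd, size=n)) / total_sd

    df = pd.DataFrame({"patient_id": patient, "visit": visit})

    # QLQ-C30 items through moment-matched cutpoints
    lam = spec.item_loading
    resid = float(np.sqrt(1.0 - lam**2))
    for scale, info in SCALES.items():
        m, _sd = spec.scale_targets[scale]
        rng_range = info["range"]
        if info["kind"] == "functional":
            mean_raw = 1.0 + rng_range * (1.0 - m / 100.0)
        else:
            mean_raw = 1.0 + rng_range * (m / 100.0)
        for item in info["items"]:
            n_levels = ITEM_MAX[item]
            spacing = spec.global_item_spacing if n_levels == 7 else spec.item_spacing
            if item in ("q29", "q30"):
                # 7-point, higher = better: match the mean of the reversed level
                cut = _item_cutpoints(n_levels + 1 - mean_raw, n_levels, spacing)
            else:
                cut = _item_cutpoints(mean_raw, n_levels, spacing)
            sev = -lam * z + resid * rng_items.normal(size=n)
            level = _ordinal_from_latent(sev, cut)
            df[item] = (n_levels + 1 - level) if item in ("q29", "q30") else level

    # EQ-5D domains at the published level frequencies
    dom_loading = 1.0 / np.hypot(1.0, spec.utility_noise_sd)
    dom_resid = float(np.sqrt(1.0 - dom_loading**2))
    for dom in EQ5D_DOMAINS:
        p = np.asarray(spec.eq5d_level_freqs[dom], dtype=float)
        p = p / p.sum()
        cut = stats.norm.ppf([p[0], p[0] + p[1]])
        sev = -dom_loading * z + dom_resid * rng_domains.normal(size=n)
        df[dom] = _ordinal_from_latent(sev, cut)

    # spikes: forced worst states (negative utilities) and forced full health
    u = rng_spikes.uniform(size=n)
    neg = u < spec.negative_utility_prob
    ceil = (~neg) & (u > 1.0 - spec.ceiling_mass)
    for item in ITEM_COLUMNS:
        worst, best = (1, ITEM_MAX[item]) if item in ("q29", "q30") else (ITEM_MAX[item], 1)
        df.loc[neg, item] = worst
        df.loc[ceil, item] = best
    for dom in EQ5D_DOMAINS:
        df.loc[neg, dom] = 3
        df.loc[ceil, dom] = 1

    vs = load_value_set(spec.value_set) if isinstance(spec.value_set, str) else spec.value_set
    df["utility"] = vs.utility_frame(df)
    df["complete"] = True
    for item in ITEM_COLUMNS:
        df[item] = df[item].astype(float)

    if spec.item_missingness > 0:
        df = inject_item_missingness(df, spec.item_missingness,
                                     rng=rng_miss)
    return df


def default_covariate_spec(scales: Sequence[str] | None = None) -> dict[str, tuple[float, float]]:
    """Published (mean, SD) targets for the requested scale scores."""
    scales = scales if scales is not None else list(DEFAULT_SCALE_TARGETS)
    return {s: DEFAULT_SCALE_TARGETS[s] for s in scales}


def _draw_covariates(names, n_rows, covariate_spec, rng) -> pd.DataFrame:
    """Truncated-normal scale scores on [0, 100] with the given moments."""
    out = {}
    for name in names:
        m, sd = covariate_spec[name]
        a, b = (0.0 - m) / sd, (100.0 - m) / sd
        out[name] = stats.truncnorm.rvs(a, b, loc=m, scale=sd, size=n_rows, random_state=rng)
    return pd.DataFrame(out, index=pd.RangeIndex(n_rows))


def _coeff_parts(coeffs: Mapping[str, float]):
    names = [k for k in coeffs if k not in ("intercept", "const")]
    for name in names:
        if name not in SCALES:
            raise ValueError(f"unknown coefficient name {name!r} (not a scale score)")
    intercept = float(coeffs.get("intercept", coeffs.get("const", 0.0)))
    return intercept, names, np.array([float(coeffs[k]) for k in names])


def generate_from_linear_model(
    coeffs: Mapping[str, float],
    n_rows: int = 1905,
    n_patients: int = 473,
    noise_sd: float = 0.09,
    random_intercept_sd: float = 0.05,
    covariate_spec: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    truncate_at: float | None = 1.0,
) -> pd.DataFrame:
    """Parameter-recovery data: utility = linear predictor + b_patient + noise.

    Scale scores are truncated-normal on [0, 100] with the published
    moments (or ``covariate_spec``); the utility is truncated above at
    ``truncate_at`` (the tariff ceiling) unless that is None.  The
    untruncated linear predictor is returned as ``linear_pred``.
    """
    intercept, names, beta = _coeff_parts(coeffs)
    spec = dict(default_covariate_spec())
    if covariate_spec:
        spec.update(covariate_spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    X = _draw_covariates(list(spec), n_rows, spec, rng)
    patient = np.sort(np.arange(n_rows) % n_patients) + 1
    visit = np.concatenate([np.arange(1, c + 1) for c in np.bincount(patient)[1:]])
    b = rng.normal(0.0, random_intercept_sd, size=n_patients)
    lp = intercept + (X[names].to_numpy() @ beta if len(beta) else np.zeros(n_rows))
    u = lp + b[patient - 1] + rng.normal(0.0, noise_sd, size=n_rows)
    if truncate_at is not None:
        u = np.minimum(u, truncate_at)
    out = X.copy()
    out.insert(0, "visit", visit)
    out.insert(0, "patient_id", patient)
    out["linear_pred"] = lp
    out["utility"] = u
    return out


def generate_beta_disutility_data(
    coeffs: Mapping[str, float],
    n_rows: int = 1905,
    precision: float = 10.0,
    covariate_spec: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    transform_n: int | None = None,
) -> pd.DataFrame:
    """Recovery data for the beta family.

    The transformed disutility is drawn from a beta distribution whose
    logit mean is the given link-scale linear predictor and whose
    precision is fixed; it is then decompressed with the same
    open-interval transform the fitting procedure applies (calibration
    size ``transform_n``, default ``n_rows``) and returned as a utility.
    """
    intercept, names, beta = _coeff_parts(coeffs)
    spec = dict(default_covariate_spec())
    if covariate_spec:
        spec.update(covariate_spec)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    X = _draw_covariates(list(spec), n_rows, spec, rng)
    mu = expit(intercept + (X[names].to_numpy() @ beta if len(beta) else np.zeros(n_rows)))
    y = rng.beta(mu * precision, (1.0 - mu) * precision)
    tspec = BetaTransformSpec(n=transform_n or n_rows)
    d = np.clip(from_open_interval(y, tspec), 0.0, 1.0)
    out = X.copy()
    out.insert(0, "visit", 1)
    out.insert(0, "patient_id", np.arange(1, n_rows + 1))
    out["utility"] = 1.0 - d
    return out


def inject_item_missingness(
    cohort: pd.DataFrame,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Delete items at random (MCAR) while keeping functional scales scorable.

    Items are dropped independently with probability ``rate`` per row; the
    deletion is then repaired so every *functional* scale keeps at least
    half of its items (rounded up), which is the precondition for the
    incomplete-questionnaire evaluation path.  The ``complete`` flag is
    refreshed.  Returns a copy.
    """
    if not 0.0 <= rate < 0.5:
        raise ValueError(f"missingness rate must lie in [0, 0.5): {rate}")
    out = cohort.copy()
    if rate == 0.0:
        return out
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed or 0))
    n = len(out)
    items = [c for c in ITEM_COLUMNS if c in out.columns]
    drop = rng.random((n, len(items))) < rate
    col_of = {c: j for j, c in enumerate(items)}
    for scale in FUNCTIONAL_SCALES:
        cols = [col_of[c] for c in SCALES[scale]["items"]]
        keep_min = -(-len(cols) // 2)
        sub = drop[:, cols]
        excess = sub.sum(axis=1) - (len(cols) - keep_min)
        for i in np.flatnonzero(excess > 0):
            dropped = [cols[j] for j in range(len(cols)) if sub[i, j]]
            restore = rng.choice(dropped, size=int(excess[i]), replace=False)
            drop[i, restore] = False
    vals = out[items].to_numpy(dtype=float)
    vals[drop] = np.nan
    out[items] = vals
    out["complete"] = ~drop.any(axis=1)
    return out
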