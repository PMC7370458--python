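"""Scoring of the EORTC QLQ-C30 (version 3.0) and the EQ-5D-3L.

The QLQ-C30 has 30 items: q1-q28 on a 1-4 scale ("not at all" .. "very
much"), q29-q30 on a 1-7 scale ("very poor" .. "excellent").  They are
aggregated into 15 scale scores on 0-100 following the EORTC scoring manual:
the raw score RS is the mean of the answered items of a scale, then

    functional scales and global health on "better" items:
        S = (1 - (RS - 1) / range) * 100     (functional; higher = better)
    symptom scales / single items and global health:
        S = ((RS - 1) / range) * 100

where range is 3 for 4-point items and 6 for the two 7-point items.  Note
q29/q30 are oriented "higher = better", so global health uses the symptom
formula yet still reads "higher = better".  A scale score is computable as
long as at least half of its items were answered (the half-completion
rule); otherwise it is missing.  No imputation is ever performed.

The EQ-5D-3L describes a health state by five domains (mobility, self-care,
usual activities, pain/discomfort, anxiety/depression) at three levels
each.  A country-specific value set ("tariff") converts the 243 possible
states into a utility anchored at 1 (full health) and 0 (dead); severe
states may map below 0.  Value sets are additive: a full-health constant
minus per-domain per-level decrements minus extra terms triggered by
predicates on the whole state (e.g. "any domain at level 3").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

# --- QLQ-C30 structure -----------------------------------------------------

ITEM_COLUMNS = [f"q{i}" for i in range(1, 31)]

#: item -> scale assignment from the official scoring manual (v3.0)
SCALES: dict[str, dict] = {
    "physical": {"items": ["q1", "q2", "q3", "q4", "q5"], "range": 3, "kind": "functional"},
    "role": {"items": ["q6", "q7"], "range": 3, "kind": "functional"},
    "emotional": {"items": ["q21", "q22", "q23", "q24"], "range": 3, "kind": "functional"},
    "cognitive": {"items": ["q20", "q25"], "range": 3, "kind": "functional"},
    "social": {"items": ["q26", "q27"], "range": 3, "kind": "functional"},
    "global_health": {"items": ["q29", "q30"], "range": 6, "kind": "global"},
    "fatigue": {"items": ["q10", "q12", "q18"], "range": 3, "kind": "symptom"},
    "nausea_vomiting": {"items": ["q14", "q15"], "range": 3, "kind": "symptom"},
    "pain": {"items": ["q9", "q19"], "range": 3, "kind": "symptom"},
    "dyspnea": {"items": ["q8"], "range": 3, "kind": "symptom"},
    "insomnia": {"items": ["q11"], "range": 3, "kind": "symptom"},
    "appetite_loss": {"items": ["q13"], "range": 3, "kind": "symptom"},
    "constipation": {"items": ["q16"], "range": 3, "kind": "symptom"},
    "diarrhea": {"items": ["q17"], "range": 3, "kind": "symptom"},
    "financial": {"items": ["q28"], "range": 3, "kind": "symptom"},
}

FUNCTIONAL_SCALES = [k for k, v in SCALES.items() if v["kind"] == "functional"]
SYMPTOM_SCALES = [k for k, v in SCALES.items() if v["kind"] == "symptom"]
SCALE_NAMES = list(SCALES)

#: maximum answer level per item (q29/q30 are 7-point, the rest 4-point)
ITEM_MAX = {c: (7 if c in ("q29", "q30") else 4) for c in ITEM_COLUMNS}


def _as_frame(record) -> tuple[pd.DataFrame, bool]:
    """Coerce a single record (mapping/Series) or a DataFrame to a frame."""
    if isinstance(record, pd.DataFrame):
        return record, False
    if isinstance(record, pd.Series):
        return record.to_frame().T, True
    if isinstance(record, Mapping):
        return pd.DataFrame([record]), True
    raise TypeError(f"cannot score object of type {type(record).__name__}")


def validate_items(df: pd.DataFrame) -> None:
    """Raise ValueError naming the first item whose values leave its range."""
    for col in ITEM_COLUMNS:
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.dropna()
        if len(present) == 0:
            continue
        lo, hi = 1, ITEM_MAX[col]
        bad = present[(present < lo) | (present > hi) | (present != present.round())]
        if len(bad):
            raise ValueError(
                f"item {col}: value {bad.iloc[0]!r} outside the declared range {lo}..{hi}"
            )


def score_qlqc30(record) -> pd.DataFrame | pd.Series:
    """Compute the 15 QLQ-C30 scale scores (0-100, NaN where not computable).

    Accepts a DataFrame with columns q1..q30 (NaN = item not answered), or a
    single record as a mapping/Series.  Returns a DataFrame of scale columns
    (or a Series for a single record).  Scores obey the half-completion
    rule: a scale is missing unless at least half of its items (rounded up)
    were answered; answered items enter through their mean (the raw score).
    """
    df, single = _as_frame(record)
    validate_items(df)
    out = pd.DataFrame(index=df.index)
    for name, sc in SCALES.items():
        items = [c for c in sc["items"]]
        block = pd.DataFrame(
            {c: pd.to_numeric(df[c], errors="coerce") if c in df.columns else np.nan for c in items},
            index=df.index,
        )
        n_items = len(items)
        answered = block.notna().sum(axis=1)
        need = -(-n_items // 2)  # ceil(n/2)
        rs = block.mean(axis=1)  # mean of answered items
        rng = sc["range"]
        if sc["kind"] == "functional":
            score = (1.0 - (rs - 1.0) / rng) * 100.0
        else:  # symptom scales and global health share the direct transform
            score = ((rs - 1.0) / rng) * 100.0
        score[answered < need] = np.nan
        out[name] = score
    if single:
        return out.iloc[0]
    return out


def binarize_v3_items(record):
    """Map q1..q5 from the 4-point v3.0 coding onto the binary v2 coding.

    1 ("not at all") stays 1 ("no"); 2, 3, 4 become 2 ("yes"); missing is
    preserved.  Needed when applying published coefficient sets estimated on
    version 2 questionnaires to version 3 data.  Returns a copy.
    """
    df, single = _as_frame(record)
    validate_items(df)
    df = df.copy()
    for col in ["q1", "q2", "q3", "q4", "q5"]:
        if col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            df[col] = np.where(vals.isna(), np.nan, np.where(vals >= 2, 2.0, 1.0))
    if single:
        return df.iloc[0]
    return df


# --- EQ-5D-3L --------------------------------------------------------------

EQ5D_DOMAINS = ["mobility", "self_care", "usual_activities", "pain_discomfort", "anxiety_depression"]
#: short column aliases used in CSV interchange
EQ5D_ALIASES = {"mo": "mobility", "sc": "self_care", "ua": "usual_activities",
                "pd": "pain_discomfort", "ad": "anxiety_depression"}

_KNOWN_PREDICATES = ("any_gt_1", "any_eq_3")


@dataclass(frozen=True)
class ValueSet:
    """An additive EQ-5D-3L tariff.

    utility(state) = constant - sum(decrements[d][level_d]) - sum of every
    extra term whose predicate the state triggers.  ``any_gt_1`` fires when
    at least one domain is worse than level 1 (the "any dysfunction"
    constant of the MVH-style tariffs); ``any_eq_3`` when at least one
    domain is at level 3 (the "N3" term).
    """

    name: str
    constant: float = 1.0
    decrements: Mapping[str, Mapping[int, float]] = field(default_factory=dict)
    extras: tuple[tuple[str, float], ...] = ()

    def __post_init__(self):
        for domain, table in self.decrements.items():
            if domain not in EQ5D_DOMAINS:
                raise ValueError(f"value set {self.name!r}: unknown domain {domain!r}")
            if float(table.get(1, 0.0)) != 0.0:
                raise ValueError(f"value set {self.name!r}: level-1 decrement must be 0 for {domain}")
        for pred, _ in self.extras:
            if pred not in _KNOWN_PREDICATES:
                raise ValueError(f"value set {self.name!r}: unknown predicate {pred!r}")
        # full health must score exactly 1
        if abs(self.constant - 1.0) > 1e-12:
            raise ValueError(f"value set {self.name!r}: state 1-1-1-1-1 must score 1.0")

    def utility(self, levels: Mapping[str, int] | Iterable[int]) -> float:
        """Utility of a single state given as domain->level or a 5-vector."""
        if not isinstance(levels, Mapping):
            levels = dict(zip(EQ5D_DOMAINS, levels))
        u = self.constant
        any_gt1 = False
        any_eq3 = False
        for d in EQ5D_DOMAINS:
            lv = int(levels[d])
            if lv not in (1, 2, 3):
                raise ValueError(f"domain {d}: level {lv} not in {{1,2,3}}")
            u -= float(self.decrements.get(d, {}).get(lv, 0.0))
            any_gt1 |= lv > 1
            any_eq3 |= lv == 3
        for pred, val in self.extras:
            if (pred == "any_gt_1" and any_gt1) or (pred == "any_eq_3" and any_eq3):
                u -= float(val)
        return u

    def utility_frame(self, df: pd.DataFrame) -> pd.Series:
        """Vectorised utilities for a DataFrame of domain-level columns."""
        cols = {}
        for d in EQ5D_DOMAINS:
            if d in df.columns:
                cols[d] = df[d]
            else:
                alias = {v: k for k, v in EQ5D_ALIASES.items()}[d]
                if alias not in df.columns:
                    raise ValueError(f"missing EQ-5D domain column {d!r} (or alias {alias!r})")
                cols[d] = df[alias]
        lv = pd.DataFrame(cols).astype(int)
        if ((lv < 1) | (lv > 3)).any().any():
            raise ValueError("EQ-5D levels must lie in {1,2,3}")
        u = np.full(len(lv), self.constant)
        for d in EQ5D_DOMAINS:
            table = self.decrements.get(d, {})
            dec = np.zeros(len(lv))
            for level, val in table.items():
                dec[lv[d].to_numpy() == int(level)] = float(val)
            u -= dec
        any_gt1 = (lv > 1).any(axis=1).to_numpy()
        any_eq3 = (lv == 3).any(axis=1).to_numpy()
        for pred, val in self.extras:
            mask = any_gt1 if pred == "any_gt_1" else any_eq3
            u -= float(val) * mask
        return pd.Series(u, index=df.index, name="utility")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "constant": self.constant,
            "decrements": {d: {str(k): v for k, v in t.items()} for d, t in self.decrements.items()},
            "extras": [{"predicate": p, "value": v} for p, v in self.extras],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValueSet":
        try:
            decrements = {
                dom: {int(k): float(v) for k, v in table.items()}
                for dom, table in d.get("decrements", {}).items()
            }
            extras = tuple((e["predicate"], float(e["value"])) for e in d.get("extras", []))
            return cls(name=d["name"], constant=float(d.get("constant", 1.0)),
                       decrements=decrements, extras=extras)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed value-set definition: {exc}") from exc


def eq5d_utility(response, value_set: ValueSet):
    """Score an EQ-5D-3L response (state, mapping or DataFrame) with a tariff."""
    if isinstance(response, pd.DataFrame):
        return value_set.utility_frame(response)
    return value_set.utility(response)


def available_value_sets() -> list[str]:
    """Names of the value sets packaged with qolmap."""
    pkg = resources.files("qolmap").joinpath("data")
    return sorted(
        p.name[len("value_set_"):-len(".json")]
        for p in pkg.iterdir()
        if p.name.startswith("value_set_") and p.name.endswith(".json")
    )


def load_value_set(name_or_path: str) -> ValueSet:
    """Load a packaged value set by name (e.g. ``NL``, ``UK``) or a JSON path."""
    pkg = resources.files("qolmap").joinpath("data")
    candidate = pkg.joinpath(f"value_set_{name_or_path}.json")
    if candidate.is_file():
        return ValueSet.from_dict(json.loads(candidate.read_text()))
    try:
        with open(name_or_path) as fh:
            return ValueSet.from_dict(json.load(fh))
    except FileNotFoundError:
        raise KeyError(
            f"unknown value set {name_or_path!r}; packaged sets: {available_value_sets()}"
        ) from None
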