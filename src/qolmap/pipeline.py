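"""End-to-end study replica: simulate, score, fit, validate, compare, CEA.

``run_study`` executes the full analysis from a single configuration with
one master seed: generate a synthetic paired cohort, score both
instruments, fit the requested mapping families on the complete data,
cross-validate each family's full fitting procedure, evaluate the
scale-score families on an incomplete-questionnaire cohort, and propagate
the observed vs mapped utility sources through the cost-effectiveness
sensitivity layer.  Every stage seed is derived from the master seed, all
artifacts are written under the output directory, and the report JSON is
byte-identical across runs with the same configuration (wall-clock
provenance goes to a side log, not the report).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import qolmap
from qolmap.cea import ArmUtilitySummary, compare_utility_sources
from qolmap.instruments import (
    EQ5D_ALIASES,
    EQ5D_DOMAINS,
    ITEM_COLUMNS,
    load_value_set,
    score_qlqc30,
)
from qolmap.serialize import model_to_dict
from qolmap.synthetic import CohortSpec, generate_cohort
from qolmap.validation import (
    MODEL_FAMILIES,
    cross_validate,
    evaluate_incomplete,
    fit_family,
    predict_family,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_study", "export_tables", "read_cohort_csv", "write_cohort_csv"]

DEFAULT_FAMILIES = ["linear_scales", "linear_items", "linear_dummies",
                    "response_mapping", "beta", "separate_equations"]
INCOMPLETE_FAMILIES = ["linear_scales", "response_mapping", "beta", "separate_equations"]


@dataclass
class RunConfig:
    """Single-file configuration of the full study replica."""

    outdir: str = "study_output"
    seed: int = 7
    families: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    cohort: dict = field(default_factory=dict)          # CohortSpec overrides
    k_folds: int = 5
    value_set: str = "NL"
    incomplete_rows: int = 400                          # raw rows before eligibility
    incomplete_missingness: float = 0.15
    cea: dict = field(default_factory=lambda: {
        # two-arm sensitivity layer: shared incremental cost, per-arm state
        # time and fixed QALY remainder carrying the survival difference
        "incremental_cost": 30163.0,
        "time_in_state": [1.6, 1.6],
        "fixed_qaly": [0.9, 1.063],
        "n_samples": 10000,
    })
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        cfg = cls(**raw)
        # paths are relative to the config file
        cfg.outdir = str((Path(path).parent / cfg.outdir).resolve())
        return cfg


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort in the long CSV interchange layout (mo..ad aliases)."""
    out = cohort.rename(columns={v: k for k, v in EQ5D_ALIASES.items()})
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read the long CSV interchange layout; empty cells are missing items."""
    df = pd.read_csv(path)
    return df.rename(columns=EQ5D_ALIASES)


def _scored(cohort: pd.DataFrame) -> pd.DataFrame:
    scores = score_qlqc30(cohort)
    out = cohort.copy()
    for c in scores.columns:
        out[c] = scores[c]
    return out


def _arm_summary(utilities: pd.Series, source: str) -> ArmUtilitySummary:
    u = np.asarray(utilities, dtype=float)
    return ArmUtilitySummary(mean=float(u.mean()),
                             se=float(u.std(ddof=1) / np.sqrt(len(u))),
                             source=source)


def run_study(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        stream=sys.stderr)
    seed = int(config.seed)
    config_echo = asdict(config)
    config_echo.pop("outdir")  # keep the report byte-stable across output locations
    report: dict = {
        "config": config_echo,
        "provenance": {
            "seed": seed,
            "qolmap": qolmap.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "models": {},
        "cross_validation": {},
    }

    # stage 1: simulate ----------------------------------------------------
    logger.info("stage simulate: generating cohort")
    spec = CohortSpec(seed=seed, **config.cohort)
    cohort = generate_cohort(spec)
    write_cohort_csv(cohort, outdir / "cohort.csv")

    # stage 2: score -------------------------------------------------------
    logger.info("stage score: scoring instruments")
    data = _scored(cohort)
    write_cohort_csv(data, outdir / "scored.csv")
    vs = load_value_set(config.value_set)

    # stage 3: fit every family on the complete data ------------------------
    fitted = {}
    for family in config.families:
        logger.info("stage fit: %s", family)
        try:
            fr = fit_family(family, data, vs)
        except Exception as exc:
            raise RuntimeError(f"stage fit[{family}] failed: {exc}") from exc
        fitted[family] = fr
        model = getattr(fr, "model", fr)
        model_path = outdir / f"model_{family}.json"
        model_path.write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=True) + "\n")
        entry = {"model_file": model_path.name}
        if hasattr(fr, "history"):
            entry["selection_history"] = fr.history
        report["models"][family] = entry

    # stage 4: cross-validate ----------------------------------------------
    for family in config.families:
        logger.info("stage validate: %s", family)
        try:
            cv = cross_validate(family, data, k=config.k_folds, seed=seed + 1,
                                value_set=vs)
        except Exception as exc:
            raise RuntimeError(f"stage validate[{family}] failed: {exc}") from exc
        report["cross_validation"][family] = cv.to_dict()
        cv.predictions.assign(family=family).to_csv(
            outdir / f"cv_predictions_{family}.csv", index=False)
    report["observed_summary"] = {
        "n": int(len(data)),
        "mean": float(data["utility"].mean()),
        "sd": float(data["utility"].std(ddof=1)),
        "min": float(data["utility"].min()),
        "max": float(data["utility"].max()),
    }

    # stage 5: incomplete questionnaires -----------------------------------
    logger.info("stage incomplete: evaluating on incomplete questionnaires")
    inc_spec = CohortSpec(seed=seed + 2, **{**config.cohort,
                                            "n_rows": config.incomplete_rows,
                                            "n_patients": max(config.incomplete_rows // 4, 1),
                                            "item_missingness": config.incomplete_missingness})
    incomplete = generate_cohort(inc_spec)
    families = [f for f in INCOMPLETE_FAMILIES if f in fitted]
    inc_results = evaluate_incomplete(incomplete, {f: fitted[f] for f in families}, vs)
    report["incomplete"] = {
        f: {"n_eligible": r["n_eligible"], "metrics": r["metrics"].to_dict()}
        for f, r in inc_results.items()
    }

    # stage 6: CEA sensitivity ---------------------------------------------
    logger.info("stage cea: utility-source sensitivity")
    # pseudo-arms: patients split deterministically by the fold seed
    rng = np.random.default_rng(np.random.SeedSequence(seed + 3))
    patients = data["patient_id"].unique()
    arm2 = set(rng.permutation(patients)[: len(patients) // 2])
    in_arm2 = data["patient_id"].isin(arm2)
    sources = [(
        _arm_summary(data.loc[~in_arm2, "utility"], "observed"),
        _arm_summary(data.loc[in_arm2, "utility"], "observed"),
    )]
    for family in config.families:
        pred = predict_family(family, fitted[family], data, vs)
        tag = f"mapped:{family}"
        sources.append((_arm_summary(pred[~in_arm2], tag), _arm_summary(pred[in_arm2], tag)))
    cea_cfg = config.cea
    cea_table = compare_utility_sources(
        sources,
        time_in_state=tuple(cea_cfg["time_in_state"]),
        fixed_qaly=tuple(cea_cfg["fixed_qaly"]),
        incremental_cost=float(cea_cfg["incremental_cost"]),
        n_samples=int(cea_cfg["n_samples"]),
        seed=seed + 4,
    )
    cloud_rows = []
    for res in cea_table.attrs["results"]:
        cloud_rows.append(res.cloud.assign(source=res.source))
    pd.concat(cloud_rows, ignore_index=True).to_csv(outdir / "ce_plane_cloud.csv", index=False)
    report["cea"] = cea_table.drop(columns=[]).to_dict(orient="records")

    # report + tables ------------------------------------------------------
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    export_tables(report, outdir)
    logger.info("study complete: %s", report_path)
    return report


_METRIC_ROWS = ["mean", "sd", "min", "max", "rmse", "mae", "spearman", "t_pvalue"]


def export_tables(report: dict, outdir) -> list[Path]:
    """Write the three summary tables as 3-decimal CSVs; idempotent."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    # complete-data performance: observed column plus one per family
    cols = {"observed": {**report["observed_summary"]}}
    for family, cv in report.get("cross_validation", {}).items():
        cols[family] = cv["pooled"]
    tbl = pd.DataFrame({name: {m: vals.get(m) for m in _METRIC_ROWS}
                        for name, vals in cols.items()})
    p = outdir / "table_performance_complete.csv"
    tbl.to_csv(p, float_format="%.3f", index_label="metric")
    written.append(p)

    if "incomplete" in report:
        cols = {}
        for family, entry in report["incomplete"].items():
            cols[family] = {**entry["metrics"], "n_eligible": entry["n_eligible"]}
        tbl = pd.DataFrame({name: {m: vals.get(m) for m in _METRIC_ROWS + ["n_eligible"]}
                            for name, vals in cols.items()})
        p = outdir / "table_performance_incomplete.csv"
        tbl.to_csv(p, float_format="%.3f", index_label="metric")
        written.append(p)

    if "cea" in report:
        tbl = pd.DataFrame(report["cea"])
        p = outdir / "table_cea_sensitivity.csv"
        tbl.to_csv(p, float_format="%.3f", index=False)
        written.append(p)
    return written
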