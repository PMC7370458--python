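"""Coefficient files: saving, loading and applying mapping models.

Mapping models are exchanged as JSON coefficient files so published
algorithms can be applied without refitting.  Every file declares its
``family`` tag, which fixes the required inputs and the prediction rule:

- ``linear_scales`` / ``linear_items`` / ``linear_dummies``:
  ``intercept`` + ``coefficients`` on the utility scale;
- ``response_mapping``: per-domain ordered-logit ``coefficients`` and
  ``thresholds`` plus a prediction ``mode``; needs a tariff at apply time;
- ``beta``: link-scale ``coefficients``, ``precision`` and the
  open-interval ``transform`` calibration ``{"N": ...}``;
- ``separate_equations``: multinomial ``class_coefficients`` plus two
  embedded linear submodels.

The package ships one reference file (``model_mcrc_scale_scores.json``);
external published algorithms are supplied by the user in the same schema.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path

import pandas as pd

from qolmap.beta_mapping import BetaMappingModel, BetaTransformSpec, predict_beta
from qolmap.instruments import ValueSet, load_value_set
from qolmap.linear_models import LINEAR_FAMILIES, LinearMappingModel, predict_linear
from qolmap.response_mapping import (
    OrderedLogitDomainModel,
    ResponseMappingModel,
    predict_response_mapping,
)
from qolmap.selection import FitResult
from qolmap.separate_equations import SeparateEquationsModel, predict_separate_equations

__all__ = ["save_model", "load_model", "apply_published", "packaged_model_path"]


def packaged_model_path(name: str = "mcrc_scale_scores"):
    """Path-like handle to a packaged coefficient file."""
    p = resources.files("qolmap").joinpath(f"data/model_{name}.json")
    if not p.is_file():
        raise KeyError(f"no packaged coefficient file named {name!r}")
    return p


def _linear_to_dict(m: LinearMappingModel) -> dict:
    return {
        "name": m.name,
        "family": m.family,
        "tariff": m.tariff,
        "inputs": m.inputs,
        "intercept": m.intercept,
        "coefficients": dict(m.coefficients),
        "residual_sd": m.residual_sd,
        "random_intercept_var": m.random_intercept_var,
    }


def model_to_dict(model) -> dict:
    if isinstance(model, FitResult):
        model = model.model
    if isinstance(model, LinearMappingModel):
        return _linear_to_dict(model)
    if isinstance(model, BetaMappingModel):
        return {
            "family": "beta",
            "inputs": model.inputs,
            "intercept": model.intercept,
            "coefficients": dict(model.coefficients),
            "precision": model.precision,
            "link": model.link,
            "transform": {"N": model.transform.n},
        }
    if isinstance(model, ResponseMappingModel):
        return {
            "family": "response_mapping",
            "inputs": list(model.scales),
            "mode": model.mode,
            "domains": {
                d: {"coefficients": dict(m.coefficients),
                    "thresholds": {"kappa1": m.kappa1, "kappa2": m.kappa2}}
                for d, m in model.domains.items()
            },
        }
    if isinstance(model, SeparateEquationsModel):
        return {
            "family": "separate_equations",
            "inputs": list(model.class_inputs),
            "threshold": model.threshold,
            "class_coefficients": {k: dict(v) for k, v in model.class_coefficients.items()},
            "submodels": {"low": _linear_to_dict(model.low_model),
                          "mid": _linear_to_dict(model.mid_model)},
        }
    raise TypeError(f"cannot serialize model of type {type(model).__name__}")


def save_model(model, path) -> None:
    """Write a fitted model (or FitResult) as a coefficient JSON file."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def _linear_from_dict(d: dict) -> LinearMappingModel:
    return LinearMappingModel(
        family=d["family"],
        intercept=float(d["intercept"]),
        coefficients={k: float(v) for k, v in d["coefficients"].items()},
        residual_sd=d.get("residual_sd"),
        random_intercept_var=d.get("random_intercept_var"),
        tariff=d.get("tariff"),
        name=d.get("name"),
    )


def model_from_dict(d: dict):
    family = d.get("family")
    if family in LINEAR_FAMILIES:
        return _linear_from_dict(d)
    if family == "beta":
        return BetaMappingModel(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            precision=float(d.get("precision", float("nan"))),
            transform=BetaTransformSpec(n=int(d["transform"]["N"])),
            link=d.get("link", "logit"),
        )
    if family == "response_mapping":
        domains = {}
        for dom, spec in d["domains"].items():
            th = spec["thresholds"]
            domains[dom] = OrderedLogitDomainModel(
                domain=dom,
                coefficients={k: float(v) for k, v in spec["coefficients"].items()},
                kappa1=float(th["kappa1"]),
                kappa2=None if th.get("kappa2") is None else float(th["kappa2"]),
            )
        return ResponseMappingModel(domains=domains, scales=tuple(d.get("inputs", [])),
                                    mode=d.get("mode", "most_likely"))
    if family == "separate_equations":
        return SeparateEquationsModel(
            class_coefficients={k: {n: float(v) for n, v in c.items()}
                                for k, c in d["class_coefficients"].items()},
            class_inputs=list(d["inputs"]),
            low_model=_linear_from_dict(d["submodels"]["low"]),
            mid_model=_linear_from_dict(d["submodels"]["mid"]),
            threshold=float(d.get("threshold", 0.6)),
        )
    raise ValueError(f"unknown model family tag {family!r} in coefficient file")


def load_model(path):
    """Load a coefficient JSON file (path or packaged name) into a model."""
    p = Path(path)
    if p.is_file():
        d = json.loads(p.read_text())
    else:
        d = json.loads(packaged_model_path(str(path)).read_text())
    try:
        return model_from_dict(d)
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed coefficient file {path}: {exc}") from exc


def apply_published(coeff_file, data: pd.DataFrame,
                    value_set: ValueSet | str | None = None) -> pd.Series:
    """Apply a coefficient file to scored (or raw-item) data.

    Dispatches on the file's family tag.  Response-mapping files need a
    tariff: pass a ValueSet or name, or rely on the file's ``tariff`` field.
    """
    model = load_model(coeff_file) if not _is_model(coeff_file) else coeff_file
    if isinstance(model, LinearMappingModel):
        return predict_linear(model, data)
    if isinstance(model, BetaMappingModel):
        return predict_beta(model, data)
    if isinstance(model, SeparateEquationsModel):
        return predict_separate_equations(model, data)
    if isinstance(model, ResponseMappingModel):
        if value_set is None:
            raise ValueError("response-mapping prediction needs a value set (tariff)")
        vs = load_value_set(value_set) if isinstance(value_set, str) else value_set
        return predict_response_mapping(model, data, vs)
    raise ValueError(f"cannot apply object of type {type(model).__name__}")


def _is_model(obj) -> bool:
    return isinstance(obj, (LinearMappingModel, BetaMappingModel,
                            ResponseMappingModel, SeparateEquationsModel))
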