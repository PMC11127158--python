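"""Similarity-model configuration files (YAML or JSON).

A model config lists attributes, each with name, kind, domain, weight and a
local similarity function — either a numeric profile
``{plateau_width, anchors: [[diff, sim], ...]}`` or a table
``{table: [[value_a, value_b, sim], ...]}`` (symmetric pairs listed once;
diagonal implied).  The loader refuses configs that fail validation.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .similarity import (
    AttributeSpec,
    NumericDifference,
    PairTable,
    SimilarityModel,
    validate_model,
)

__all__ = ["ModelConfigError", "load_model", "save_model", "default_model"]

DEFAULT_MODEL_RESOURCE = "default_model.yaml"


class ModelConfigError(ValueError):
    """A model config failed to parse or validate."""


def _fn_from_dict(d: dict) -> NumericDifference | PairTable:
    if "table" in d:
        table = {(row[0], row[1]): float(row[2]) for row in d["table"]}
        return PairTable(table=table, partial=bool(d.get("partial", False)))
    anchors = tuple((float(a), float(s)) for a, s in d.get("anchors", []))
    return NumericDifference(plateau_width=float(d.get("plateau_width", 0.0)), anchors=anchors)


def _fn_to_dict(fn: NumericDifference | PairTable) -> dict:
    if isinstance(fn, PairTable):
        d: dict = {"table": [[a, b, s] for (a, b), s in fn.table.items()]}
        if fn.partial:
            d["partial"] = True
        return d
    return {"plateau_width": fn.plateau_width, "anchors": [list(a) for a in fn.anchors]}


def model_from_dict(cfg: dict) -> SimilarityModel:
    try:
        attrs = tuple(
            AttributeSpec(
                name=a["name"],
                kind=a["kind"],
                domain=tuple(a["domain"]),
                weight=float(a["weight"]),
                local_fn=_fn_from_dict(a["local"]),
            )
            for a in cfg["attributes"]
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelConfigError(f"malformed model config: {exc}") from exc
    model = SimilarityModel(
        attributes=attrs,
        name=str(cfg.get("name", "unnamed")),
        version=str(cfg.get("version", "0")),
    )
    problems = validate_model(model)
    if problems:
        raise ModelConfigError("invalid model config: " + "; ".join(problems))
    return model


def model_to_dict(model: SimilarityModel) -> dict:
    return {
        "name": model.name,
        "version": model.version,
        "attributes": [
            {
                "name": a.name,
                "kind": a.kind,
                "domain": list(a.domain),
                "weight": a.weight,
                "local": _fn_to_dict(a.local_fn),
            }
            for a in model.attributes
        ],
    }


def load_model(path: str | Path) -> SimilarityModel:
    """Load and validate a similarity model from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    return model_from_dict(cfg)


def save_model(model: SimilarityModel, path: str | Path) -> None:
    path = Path(path)
    cfg = model_to_dict(model)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=1))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def default_model() -> SimilarityModel:
    """The shipped 29-attribute schema (see ``data/default_model.yaml``).

    Covers the four attribute domains — sociodemographic, pain and function,
    psychological, health behaviour — with mental distress (HSCL-10)
    carrying the maximum weight 8.  Every attribute is config-editable;
    copy the YAML and pass your own file to :func:`load_model`.
    """
    ref = resources.files("mskcbr") / "data" / DEFAULT_MODEL_RESOURCE
    cfg = yaml.safe_load(ref.read_text())
    return model_from_dict(cfg)
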