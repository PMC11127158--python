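"""Patient cases, the case base, and the successful-outcome criterion.

A case couples one patient's baseline description (attribute values plus
the two reference instruments, ÖMSPQ and MSK-HQ) with the treatment they
received and their 3-month follow-up, so that retrieval can surface what
was done for similar patients whose outcome was good.

Instruments
-----------
ÖMSPQ : short-form Örebro Musculoskeletal Pain Screening Questionnaire,
    0-100, higher = worse long-term disability risk.
MSK-HQ : Musculoskeletal Health Questionnaire, 0-56, higher = better
    musculoskeletal health.
NRS : pain numeric rating scale, 0-10.  PSFS : Patient Specific Functional
    Scale, 0-10, higher = better function.  GPE : global perceived effect,
    here a 7-point scale (1 = very much worse ... 7 = completely recovered).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .similarity import SimilarityModel

__all__ = [
    "REGIONS",
    "GPE_LEVELS",
    "CaseConflictError",
    "CaseValidationError",
    "FollowUpMissingError",
    "FollowUpRecord",
    "PatientCase",
    "SuccessCriterion",
    "CaseBase",
    "retain",
    "evaluate_success",
    "filter_successful",
    "load_case_base",
    "save_case_base",
]

REGIONS = ("neck", "shoulder", "back", "hip", "knee", "complex")

#: 7-point global-perceived-effect scale, worst to best.
GPE_LEVELS = tuple(range(1, 8))


class CaseConflictError(ValueError):
    """A case with this id is already in the case base."""


class CaseValidationError(ValueError):
    """A case violates an instrument range or its attribute schema."""


class FollowUpMissingError(ValueError):
    """Outcome asked of a case that has no follow-up record."""


@dataclass(frozen=True)
class FollowUpRecord:
    """Baseline and 3-month scores needed by the outcome criterion."""

    pain_baseline: float
    pain_3m: float
    function_baseline: float
    function_3m: float
    mskhq_3m: int
    gpe: int

    _RANGES = {
        "pain_baseline": (0, 10),
        "pain_3m": (0, 10),
        "function_baseline": (0, 10),
        "function_3m": (0, 10),
        "mskhq_3m": (0, 56),
        "gpe": (1, 7),
    }

    def validate(self) -> list[str]:
        out = []
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                out.append(f"{name}={v} outside [{lo}, {hi}]")
        return out


@dataclass(frozen=True)
class PatientCase:
    """One patient: baseline attributes, instruments, treatment, follow-up."""

    case_id: str
    attributes: Mapping[str, object]
    region: str
    omspq: float
    mskhq_baseline: int
    followup: FollowUpRecord | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", dict(self.attributes))

    def validate(self, model: SimilarityModel | None = None) -> list[str]:
        out = []
        if not (0 <= self.omspq <= 100):
            out.append(f"{self.case_id}: omspq={self.omspq} outside [0, 100]")
        if not (0 <= self.mskhq_baseline <= 56):
            out.append(f"{self.case_id}: mskhq_baseline={self.mskhq_baseline} outside [0, 56]")
        if self.region not in REGIONS:
            out.append(f"{self.case_id}: unknown region {self.region!r}")
        if self.followup is not None:
            out.extend(f"{self.case_id}: {v}" for v in self.followup.validate())
        if model is not None:
            for name, value in self.attributes.items():
                if value is None or name not in model:
                    continue
                if not model[name].contains(value):
                    out.append(
                        f"{self.case_id}: attribute {name}={value!r} outside schema domain"
                    )
        return out


@dataclass(frozen=True)
class SuccessCriterion:
    """Combined outcome criterion selecting the "successful" cases.

    The default rule is MCID-anchored:

        (pain improved >= 2 NRS points  OR  3-month pain <= 2)
        AND
        (MSK-HQ change >= 6 points  OR  GPE >= 6, i.e. at least "much improved")

    All four thresholds are fields and can be overridden.
    """

    pain_improvement_min: float = 2.0
    pain_followup_max: float = 2.0
    function_improvement_min: float = 2.0
    mskhq_change_min: float = 6.0
    gpe_min: int = 6

    def __call__(self, case: PatientCase) -> bool:
        return evaluate_success(case, self)


def evaluate_success(case: PatientCase, crit: SuccessCriterion) -> bool:
    """Apply the combined outcome rule to one case.

    Raises :class:`FollowUpMissingError` for cases without follow-up —
    "not evaluable" is distinct from "unsuccessful".
    """
    fu = case.followup
    if fu is None:
        raise FollowUpMissingError(f"case {case.case_id!r} has no follow-up record")
    pain_ok = (
        fu.pain_baseline - fu.pain_3m >= crit.pain_improvement_min
        or fu.pain_3m <= crit.pain_followup_max
    )
    outcome_ok = (
        fu.mskhq_3m - case.mskhq_baseline >= crit.mskhq_change_min
        or fu.gpe >= crit.gpe_min
    )
    return pain_ok and outcome_ok


@dataclass(frozen=True)
class CaseBase:
    """Identified, id-unique collection of patient cases."""

    cases: tuple[PatientCase, ...]
    schema_ref: str = ""
    excluded_no_followup: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CaseConflictError(f"duplicate case ids: {dup}")

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self) -> Iterator[PatientCase]:
        return iter(self.cases)

    def __getitem__(self, case_id: str) -> PatientCase:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(c.case_id for c in self.cases)


def retain(cb: CaseBase, case: PatientCase, model: SimilarityModel | None = None) -> CaseBase:
    """Add a solved case to the case base (the CBR *retain* step).

    Returns a new case base; the input is untouched.  Duplicate ids raise
    :class:`CaseConflictError`; schema violations raise
    :class:`CaseValidationError`.
    """
    if case.case_id in cb.case_ids:
        raise CaseConflictError(f"case id {case.case_id!r} already present")
    problems = case.validate(model)
    if problems:
        raise CaseValidationError("; ".join(problems))
    return replace(cb, cases=cb.cases + (case,))


def filter_successful(cb: CaseBase, crit: SuccessCriterion) -> CaseBase:
    """Subset of cases whose outcome satisfies the success criterion.

    Cases without follow-up are excluded (they cannot be evaluated) and
    counted in the result's ``excluded_no_followup``.
    """
    kept = []
    skipped = 0
    for c in cb.cases:
        if c.followup is None:
            skipped += 1
            continue
        if evaluate_success(c, crit):
            kept.append(c)
    return CaseBase(cases=tuple(kept), schema_ref=cb.schema_ref, excluded_no_followup=skipped)


# ---------------------------------------------------------------------------
# serialisation

_FOLLOWUP_FIELDS = (
    "pain_baseline",
    "pain_3m",
    "function_baseline",
    "function_3m",
    "mskhq_3m",
    "gpe",
)
_FIXED_FIELDS = ("case_id", "region", "omspq", "mskhq_baseline", "treatment")


def _case_to_row(case: PatientCase) -> dict:
    row = {
        "case_id": case.case_id,
        "region": case.region,
        "omspq": case.omspq,
        "mskhq_baseline": case.mskhq_baseline,
        "treatment": case.treatment,
    }
    row.update(case.attributes)
    for f in _FOLLOWUP_FIELDS:
        row[f"fu_{f}"] = getattr(case.followup, f) if case.followup is not None else None
    return row


def _row_to_case(row: Mapping[str, object], attr_names: Iterable[str]) -> PatientCase:
    fu_vals = {f: row.get(f"fu_{f}") for f in _FOLLOWUP_FIELDS}
    if all(v is None or (isinstance(v, float) and math.isnan(v)) for v in fu_vals.values()):
        followup = None
    else:
        followup = FollowUpRecord(
            pain_baseline=float(fu_vals["pain_baseline"]),
            pain_3m=float(fu_vals["pain_3m"]),
            function_baseline=float(fu_vals["function_baseline"]),
            function_3m=float(fu_vals["function_3m"]),
            mskhq_3m=int(fu_vals["mskhq_3m"]),
            gpe=int(fu_vals["gpe"]),
        )
    treatment = row.get("treatment")
    if isinstance(treatment, float) and math.isnan(treatment):
        treatment = None
    attributes = {}
    for name in attr_names:
        v = row.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        attributes[name] = v
    return PatientCase(
        case_id=str(row["case_id"]),
        region=str(row["region"]),
        omspq=float(row["omspq"]),
        mskhq_baseline=int(row["mskhq_baseline"]),
        attributes=attributes,
        followup=followup,
        treatment=treatment,
    )


def save_case_base(cb: CaseBase, path: str | Path, fmt: str | None = None) -> None:
    """Write a case base to CSV (one row per case) or JSON (array of objects).

    Missing values are empty fields in CSV and ``null`` in JSON; numeric
    values round-trip at full precision (JSON uses repr-exact floats, CSV
    17 significant digits).
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    rows = [_case_to_row(c) for c in cb.cases]
    if fmt == "csv":
        attr_names = sorted({k for r in rows for k in r} - set(_FIXED_FIELDS)
                            - {f"fu_{f}" for f in _FOLLOWUP_FIELDS})
        cols = list(_FIXED_FIELDS[:4]) + attr_names + [f"fu_{f}" for f in _FOLLOWUP_FIELDS] + ["treatment"]
        df = pd.DataFrame(rows, columns=cols)
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "json":
        payload = {"schema_ref": cb.schema_ref, "cases": rows}
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown case-base format {fmt!r}")


def load_case_base(
    path: str | Path,
    fmt: str | None = None,
    model: SimilarityModel | None = None,
    schema_ref: str = "",
) -> CaseBase:
    """Load a case base from CSV or JSON, validating every case.

    Malformed or out-of-range rows raise :class:`CaseValidationError`
    listing the offending case ids and fields.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        attr_names = [c for c in df.columns
                      if c not in _FIXED_FIELDS and not c.startswith("fu_")]
        rows = df.to_dict(orient="records")
    elif fmt == "json":
        payload = json.loads(path.read_text())
        rows = payload["cases"]
        schema_ref = schema_ref or payload.get("schema_ref", "")
        attr_names = sorted({k for r in rows for k in r} - set(_FIXED_FIELDS)
                            - {f"fu_{f}" for f in _FOLLOWUP_FIELDS})
    else:
        raise ValueError(f"unknown case-base format {fmt!r}")

    cases, problems = [], []
    for i, row in enumerate(rows):
        try:
            case = _row_to_case(row, attr_names)
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
            continue
        problems.extend(f"row {i}: {v}" for v in case.validate(model))
        cases.append(case)
    if problems:
        raise CaseValidationError("; ".join(problems))
    return CaseBase(cases=tuple(cases), schema_ref=schema_ref)
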