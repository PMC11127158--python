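"""Seeded synthetic cohorts of primary-care musculoskeletal-pain patients.

Real cohorts of this kind are not publicly deposited, so the package ships
a generator that emulates one: attribute marginals follow the published
descriptive table of a 105-patient physiotherapy cohort (mean age 46,
SD 15.2; 73.3% women; mean ÖMSPQ 43.1, SD 15.6; mean MSK-HQ 37.7, SD 8.5;
...), and a single latent severity factor s ~ N(0, 1) induces the
correlation structure the evaluation harness needs: severity loads on the
prognostic attributes, raises ÖMSPQ, lowers MSK-HQ, and lowers the
probability of a successful 3-month outcome.

Mechanism per attribute: z = loading * s + sqrt(1 - loading^2) * eps with
eps ~ N(0, 1) i.i.d., then a monotone transform of z to the target
marginal — location/scale plus clamping (and optional rounding) for numeric
attributes, Gaussian-quantile thresholding at the category probabilities
for ordinal/categorical attributes.  Loadings are assumptions (the true
attribute covariance is unpublished), chosen so nearest neighbours under
the default similarity model are materially closer on the instruments than
random pairs.

The module also provides the exact worked-example fixture: the published
five-attribute query-vs-four-patients similarity calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .cases import CaseBase, FollowUpRecord, PatientCase
from .similarity import AttributeSpec, NumericDifference, PairTable, SimilarityModel

__all__ = ["NumericMarginal", "CategoricalMarginal", "CohortModel",
           "default_cohort_model", "generate_cohort", "worked_example_fixture"]


@dataclass(frozen=True)
class NumericMarginal:
    """Target mean/SD for a numeric attribute, clamped to [lo, hi].

    ``decimals`` rounds the generated value (0 for integer scales such as
    the NRS, None to keep full precision).
    """

    mean: float
    sd: float
    lo: float
    hi: float
    decimals: int | None = None

    def transform(self, z: np.ndarray) -> np.ndarray:
        x = self.mean + self.sd * z
        x = np.clip(x, self.lo, self.hi)
        if self.decimals is not None:
            x = np.round(x, self.decimals)
            if self.decimals == 0:
                x = x.astype(int)
        return x


@dataclass(frozen=True)
class CategoricalMarginal:
    """Category labels with target probabilities (must sum to 1).

    Thresholding the latent Gaussian at the probability quantiles makes the
    category index increase with the latent value, so for ordinal scales
    list the labels in scale order.
    """

    labels: tuple
    probs: tuple[float, ...]

    def transform(self, z: np.ndarray) -> np.ndarray:
        cuts = stats.norm.ppf(np.cumsum(self.probs[:-1]))
        idx = np.searchsorted(cuts, z)
        return np.asarray(self.labels, dtype=object)[idx]

    def violations(self, name: str) -> list[str]:
        out = []
        if len(self.labels) != len(self.probs):
            out.append(f"{name}: {len(self.labels)} labels but {len(self.probs)} probabilities")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            out.append(f"{name}: probabilities sum to {sum(self.probs)}, not 1")
        if any(p < 0 for p in self.probs):
            out.append(f"{name}: negative probability")
        return out


Marginal = NumericMarginal | CategoricalMarginal


@dataclass(frozen=True)
class CohortModel:
    """Full recipe for one synthetic cohort.

    ``severity_loadings`` map attribute name -> loading in [-1, 1] on the
    latent severity; ``omspq_map``/``mskhq_map`` are (intercept, slope,
    noise SD) of the linear severity-to-instrument maps (ÖMSPQ slope
    positive — severity worsens it; MSK-HQ slope negative); the outcome
    model shifts every follow-up improvement downwards in severity.
    """

    n: int
    seed: int
    marginals: Mapping[str, Marginal]
    severity_loadings: Mapping[str, float]
    region_marginal: CategoricalMarginal
    region_loading: float = 0.3
    omspq_map: tuple[float, float, float] = (43.1, 13.0, 8.0)
    mskhq_map: tuple[float, float, float] = (37.7, -7.0, 4.8)
    # follow-up improvements: (intercept, severity slope, noise SD)
    pain_change_map: tuple[float, float, float] = (2.2, -1.2, 1.5)
    function_change_map: tuple[float, float, float] = (2.0, -1.0, 1.5)
    mskhq_change_map: tuple[float, float, float] = (6.5, -3.0, 4.0)
    gpe_map: tuple[float, float, float] = (1.5, -0.8, 1.0)
    gpe_cuts: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.2, 1.0, 2.0)
    followup_rate: float = 1.0
    id_prefix: str = "case"

    def violations(self) -> list[str]:
        out = []
        if self.n < 2:
            out.append(f"cohort size must be >= 2, got {self.n}")
        for name, m in self.marginals.items():
            if isinstance(m, CategoricalMarginal):
                out.extend(m.violations(name))
            elif not m.lo < m.hi:
                out.append(f"{name}: numeric range [{m.lo}, {m.hi}] is empty")
        out.extend(self.region_marginal.violations("region"))
        for name, lo in self.severity_loadings.items():
            if not -1.0 <= lo <= 1.0:
                out.append(f"{name}: loading {lo} outside [-1, 1]")
            if name not in self.marginals:
                out.append(f"{name}: loading given but no marginal")
        return out


_TREATMENTS = (
    "advice and reassurance",
    "exercise therapy",
    "exercise therapy + manual therapy",
    "self-management support",
    "exercise therapy + workplace intervention",
    "manual therapy + advice",
)

#: Published descriptive targets plus assumed loadings for the remaining
#: attributes of the default 29-attribute schema.
_DEFAULT_MARGINALS: dict[str, Marginal] = {
    "age": NumericMarginal(46.0, 15.2, 18, 100, 0),
    "sex": CategoricalMarginal(("male", "female"), (0.267, 0.733)),
    "education": CategoricalMarginal(("lower", "higher"), (0.438, 0.562)),
    "bmi": NumericMarginal(26.9, 6.1, 15, 60, 1),
    "work_status": CategoricalMarginal(("working", "sick_leave", "not_working"), (0.60, 0.25, 0.15)),
    "pain_intensity": NumericMarginal(4.7, 2.1, 0, 10, 0),
    "pain_sites": NumericMarginal(3.0, 2.0, 0, 10, 0),
    "pain_duration": CategoricalMarginal(("acute", "subacute", "chronic"), (0.061, 0.110, 0.829)),
    "psfs": NumericMarginal(4.0, 2.7, 0, 10, 0),
    "workability": NumericMarginal(6.2, 2.9, 0, 10, 0),
    "expectations": NumericMarginal(7.0, 2.0, 0, 10, 0),
    "previous_episodes": CategoricalMarginal(("no_prev", "yes_prev"), (0.4, 0.6)),
    "comorbidity_count": NumericMarginal(1.5, 1.5, 0, 10, 0),
    "activity_limitation": NumericMarginal(5.0, 2.5, 0, 10, 0),
    "pain_worst": NumericMarginal(6.5, 2.0, 0, 10, 0),
    "mental_distress": NumericMarginal(1.6, 0.5, 1, 4, 1),
    "sleep_problems": CategoricalMarginal(("Normal", "Slight", "Moderate", "Great"), (0.35, 0.30, 0.25, 0.10)),
    "fear_avoidance": NumericMarginal(4.5, 2.5, 0, 10, 0),
    "catastrophizing": NumericMarginal(3.5, 2.5, 0, 10, 0),
    "self_efficacy": NumericMarginal(6.0, 2.5, 0, 10, 0),
    "stress": NumericMarginal(4.0, 2.5, 0, 10, 0),
    "mood": NumericMarginal(3.5, 2.5, 0, 10, 0),
    "risk_group": CategoricalMarginal(("low", "medium", "high"), (0.416, 0.465, 0.119)),
    "physical_activity": CategoricalMarginal(("6-7", "5", "4", "3", "2", "1", "0"),
                                             (0.15, 0.15, 0.15, 0.20, 0.15, 0.12, 0.08)),
    "smoking": CategoricalMarginal(("non_smoker", "smoker"), (0.914, 0.086)),
    "alcohol_risk": CategoricalMarginal(("not_at_risk", "at_risk"), (0.9, 0.1)),
    "sleep_hours": NumericMarginal(7.0, 1.2, 3, 12, 1),
    "medication_use": CategoricalMarginal(("none", "occasional", "regular"), (0.40, 0.35, 0.25)),
    "social_support": CategoricalMarginal(("good", "moderate", "poor"), (0.50, 0.35, 0.15)),
}

# Sign convention: positive loading = attribute worsens (its latent rises)
# with severity. Scales where high = good (psfs, workability, expectations,
# self-efficacy, sleep hours) load negatively; categorical labels above are
# ordered so that later labels are the "worse" ones.
_DEFAULT_LOADINGS: dict[str, float] = {
    "age": 0.0,
    "sex": 0.1,
    "education": -0.2,
    "bmi": 0.2,
    "work_status": 0.5,
    "pain_intensity": 0.6,
    "pain_sites": 0.5,
    "pain_duration": 0.3,
    "psfs": -0.6,
    "workability": -0.6,
    "expectations": -0.4,
    "previous_episodes": 0.2,
    "comorbidity_count": 0.3,
    "activity_limitation": 0.6,
    "pain_worst": 0.5,
    "mental_distress": 0.7,
    "sleep_problems": 0.5,
    "fear_avoidance": 0.5,
    "catastrophizing": 0.6,
    "self_efficacy": -0.5,
    "stress": 0.5,
    "mood": 0.6,
    "risk_group": 0.7,
    "physical_activity": 0.4,
    "smoking": 0.1,
    "alcohol_risk": 0.0,
    "sleep_hours": -0.3,
    "medication_use": 0.5,
    "social_support": 0.3,
}

_DEFAULT_REGIONS = CategoricalMarginal(
    ("neck", "shoulder", "back", "hip", "knee", "complex"),
    (0.152, 0.171, 0.181, 0.152, 0.125, 0.219),
)


def default_cohort_model(n: int = 105, seed: int = 1,
                         loading_scale: float = 1.0) -> CohortModel:
    """Cohort recipe matching the published marginals and default loadings.

    ``loading_scale`` rescales every severity loading (0 gives a cohort
    where attributes and instruments are mutually independent — the
    negative control for the evaluation harness).
    """
    loadings = {k: v * loading_scale for k, v in _DEFAULT_LOADINGS.items()}
    return CohortModel(
        n=n,
        seed=seed,
        marginals=dict(_DEFAULT_MARGINALS),
        severity_loadings=loadings,
        region_marginal=_DEFAULT_REGIONS,
        region_loading=0.3 * loading_scale,
    )


def generate_cohort(cm: CohortModel) -> CaseBase:
    """Draw one synthetic case base; identical recipes give identical cohorts."""
    problems = cm.violations()
    if problems:
        raise ValueError("invalid cohort model: " + "; ".join(problems))
    rng = np.random.default_rng(cm.seed)
    n = cm.n
    s = rng.standard_normal(n)  # latent severity

    columns: dict[str, np.ndarray] = {}
    for name, marg in cm.marginals.items():
        lo = float(cm.severity_loadings.get(name, 0.0))
        z = lo * s + np.sqrt(1.0 - lo * lo) * rng.standard_normal(n)
        columns[name] = marg.transform(z)

    rz = cm.region_loading * s + np.sqrt(1 - cm.region_loading**2) * rng.standard_normal(n)
    regions = cm.region_marginal.transform(rz)

    def linmap(params, noise_rng):
        a, b, sd = params
        return a + b * s + sd * noise_rng.standard_normal(n)

    omspq = np.clip(linmap(cm.omspq_map, rng), 0, 100)
    mskhq = np.clip(np.round(linmap(cm.mskhq_map, rng)), 0, 56).astype(int)

    pain_change = linmap(cm.pain_change_map, rng)
    fn_change = linmap(cm.function_change_map, rng)
    mskhq_change = linmap(cm.mskhq_change_map, rng)
    gpe_latent = linmap(cm.gpe_map, rng)
    gpe = 1 + np.searchsorted(np.asarray(cm.gpe_cuts), gpe_latent)
    has_fu = rng.random(n) < cm.followup_rate
    treatments = rng.choice(len(_TREATMENTS), size=n)

    width = max(3, len(str(n)))
    cases = []
    for i in range(n):
        attrs = {name: (col[i].item() if hasattr(col[i], "item") else col[i])
                 for name, col in columns.items()}
        followup = None
        if has_fu[i]:
            pain_b = float(attrs["pain_intensity"])
            func_b = float(attrs["psfs"])
            followup = FollowUpRecord(
                pain_baseline=pain_b,
                pain_3m=float(np.clip(round(pain_b - pain_change[i]), 0, 10)),
                function_baseline=func_b,
                function_3m=float(np.clip(round(func_b + fn_change[i]), 0, 10)),
                mskhq_3m=int(np.clip(round(mskhq[i] + mskhq_change[i]), 0, 56)),
                gpe=int(gpe[i]),
            )
        cases.append(
            PatientCase(
                case_id=f"{cm.id_prefix}{i:0{width}d}",
                attributes=attrs,
                region=str(regions[i]),
                omspq=float(omspq[i]),
                mskhq_baseline=int(mskhq[i]),
                followup=followup,
                treatment=_TREATMENTS[treatments[i]],
            )
        )
    return CaseBase(cases=tuple(cases), schema_ref="msk-default/1.0")


# ---------------------------------------------------------------------------
# exact worked-example fixture

def worked_example_fixture() -> tuple[SimilarityModel, PatientCase, CaseBase]:
    """The published five-attribute worked example: query vs patients A-D.

    Weights 8 (mental distress), 4 (expectations), 2 (pain sites),
    4 (sleep), 4 (work ability).  The local functions reproduce every local
    similarity cell of the worked example; the sleep table is deliberately
    *partial* — defined only on the exhibited value pairs plus the diagonal,
    so looking up an unexhibited pair raises a domain error.

    Returns ``(model, query, case_base)``; the expected similarity scores
    are A 0.93, B 0.87, C 0.73, D 0.62 (2 dp), total weighted scores 20.4,
    19.2, 16.0, 13.6.
    """
    attrs = (
        AttributeSpec(
            "mental_distress", "numeric", (1, 4), 8,
            NumericDifference(0.0, ((0.2, 0.8), (0.5, 0.6), (1.0, 0.3), (3.0, 0.0))),
        ),
        AttributeSpec(
            "expectations", "numeric", (0, 10), 4,
            NumericDifference(1.0, ((2, 0.8), (4, 0.3), (10, 0.0))),
        ),
        AttributeSpec(
            "pain_sites", "numeric", (0, 10), 2,
            NumericDifference(0.0, ((1, 0.8), (2, 0.6), (5, 0.2), (10, 0.0))),
        ),
        AttributeSpec(
            "sleep_problems", "ordinal", ("Normal", "Slight", "Moderate", "Great"), 4,
            PairTable(
                {("Moderate", "Great"): 0.6,
                 ("Moderate", "Slight"): 0.8,
                 ("Moderate", "Normal"): 0.4},
                partial=True,
            ),
        ),
        AttributeSpec(
            "workability", "numeric", (0, 10), 4,
            NumericDifference(1.0, ((2, 0.8), (3, 0.6), (6, 0.2), (10, 0.0))),
        ),
    )
    model = SimilarityModel(attributes=attrs, name="worked-example", version="1")

    def make(case_id, md, exp, sites, sleep, work, omspq, mskhq):
        return PatientCase(
            case_id=case_id,
            attributes={
                "mental_distress": md,
                "expectations": exp,
                "pain_sites": sites,
                "sleep_problems": sleep,
                "workability": work,
            },
            region="back",
            omspq=omspq,
            mskhq_baseline=mskhq,
        )

    query = make("query", 2.0, 8, 3, "Moderate", 6, 45.0, 36)
    cb = CaseBase(
        cases=(
            make("A", 1.8, 7, 3, "Moderate", 5, 42.0, 38),
            make("B", 2.0, 6, 2, "Great", 7, 47.0, 35),
            make("C", 1.5, 9, 4, "Slight", 3, 39.0, 40),
            make("D", 2.2, 4, 5, "Normal", 4, 55.0, 30),
        ),
        schema_ref="worked-example/1",
    )
    return model, query, cb
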