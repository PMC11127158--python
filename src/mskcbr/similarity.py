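"""Local-global patient similarity model.

The model follows the local-global principle used in case-based reasoning
for clinical decision support: each attribute (age, pain intensity, mental
distress, ...) carries a *local* similarity function mapping a pair of
attribute values to a degree of similarity in [0, 1], and a positive weight
expressing its prognostic relevance. The *global* (amalgamated) similarity
between a query patient Q and a stored case C is the weighted mean

    sim(Q, C) = sum_i w_i * sim_i(q_i, c_i) / sum_i w_i

taken over the attributes present in both records, so the score always lies
in [0, 1] and equals 1 for identical complete records.

Two families of local functions are provided:

* :class:`NumericDifference` — similarity depends only on the absolute
  difference of the two values.  Differences up to a plateau width (typically
  the instrument's minimal clinically important difference, MCID) count as
  fully similar; beyond it, similarity decreases piecewise-linearly through a
  list of (difference, similarity) anchors.
* :class:`PairTable` — an explicit table of value pairs, which can express
  position-dependent similarity on ordinal scales (the same absolute
  difference may matter more at one end of the scale than the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "DomainError",
    "UndefinedSimilarityError",
    "NumericDifference",
    "PairTable",
    "AttributeSpec",
    "SimilarityModel",
    "local_similarity",
    "amalgamated_similarity",
    "validate_model",
]


class DomainError(ValueError):
    """A value fell outside an attribute's declared domain."""


class UndefinedSimilarityError(ValueError):
    """No attribute was present in both records; the score is undefined."""


@dataclass(frozen=True)
class NumericDifference:
    """Difference-based local similarity for numeric attributes.

    Parameters
    ----------
    plateau_width:
        Non-negative width (in attribute units) of the full-similarity
        plateau: absolute differences ``<= plateau_width`` score 1.0.
        Conventionally set to the attribute's MCID.
    anchors:
        Ordered ``(difference, similarity)`` pairs with strictly increasing
        differences (all greater than ``plateau_width``) and non-increasing
        similarities.  Between the plateau edge and the first anchor, and
        between consecutive anchors, similarity is interpolated linearly;
        beyond the last anchor it stays at that anchor's (floor) similarity.
    """

    plateau_width: float = 0.0
    anchors: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchors", tuple((float(d), float(s)) for d, s in self.anchors))

    def __call__(self, a: float, b: float) -> float:
        d = abs(float(a) - float(b))
        if d <= self.plateau_width:
            return 1.0
        if not self.anchors:
            return 1.0
        xp = [self.plateau_width] + [d_ for d_, _ in self.anchors]
        fp = [1.0] + [s for _, s in self.anchors]
        return float(np.interp(d, xp, fp))

    def violations(self, name: str) -> list[str]:
        out = []
        if self.plateau_width < 0:
            out.append(f"{name}: plateau_width must be non-negative, got {self.plateau_width}")
        diffs = [d for d, _ in self.anchors]
        sims = [s for _, s in self.anchors]
        if any(d <= self.plateau_width for d in diffs):
            out.append(f"{name}: anchor differences must exceed the plateau width")
        if any(d2 <= d1 for d1, d2 in zip(diffs, diffs[1:])):
            out.append(f"{name}: anchor differences must be strictly increasing")
        if any(s2 > s1 for s1, s2 in zip(sims, sims[1:])):
            out.append(f"{name}: anchor similarities must be non-increasing")
        if any(not 0.0 <= s <= 1.0 for s in sims):
            out.append(f"{name}: anchor similarities must lie in [0, 1]")
        return out


def _sympair(a: Hashable, b: Hashable) -> tuple[Hashable, Hashable]:
    return (a, b)


@dataclass(frozen=True)
class PairTable:
    """Tabulated local similarity over a finite value set.

    ``table`` maps ordered value pairs to similarities.  Lookups fall back to
    the reversed pair, so a symmetric function needs each unordered pair only
    once; diagonal pairs default to 1.0 (reflexivity) and need not be listed.

    With ``partial=True`` the table may cover only a subset of pairs; looking
    up an uncovered pair raises :class:`DomainError`.  Partial tables are
    meant for worked examples where only the exhibited pairs are defined.
    """

    table: Mapping[tuple[Hashable, Hashable], float]
    partial: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "table", dict(self.table))

    def __call__(self, a: Hashable, b: Hashable) -> float:
        if a == b:
            return float(self.table.get((a, b), 1.0))
        if (a, b) in self.table:
            return float(self.table[(a, b)])
        if (b, a) in self.table:
            return float(self.table[(b, a)])
        raise DomainError(f"no similarity defined for value pair ({a!r}, {b!r})")

    def violations(self, name: str, domain: Sequence[Hashable] | None = None) -> list[str]:
        out = []
        for pair, s in self.table.items():
            if not 0.0 <= float(s) <= 1.0:
                out.append(f"{name}: table entry {pair} = {s} outside [0, 1]")
            if pair[0] == pair[1] and float(s) != 1.0:
                out.append(f"{name}: diagonal entry {pair} = {s} must be 1.0 (reflexivity)")
        if domain is not None and not self.partial:
            for a in domain:
                for b in domain:
                    if a != b and (a, b) not in self.table and (b, a) not in self.table:
                        out.append(f"{name}: missing table entry for pair ({a!r}, {b!r})")
        return out


LocalSimilarityFunction = Union[NumericDifference, PairTable]


@dataclass(frozen=True)
class AttributeSpec:
    """One clinical attribute: kind, domain, prognostic weight, local function.

    ``kind`` is one of ``numeric``, ``ordinal``, ``categorical``.  Numeric
    domains are inclusive ``(lo, hi)`` ranges; ordinal/categorical domains are
    finite value tuples (ordinal tuples are in scale order).  Weights are
    positive; the shipped schema uses integers 1-8, higher = more relevant.
    """

    name: str
    kind: str
    domain: tuple
    weight: float
    local_fn: LocalSimilarityFunction

    def contains(self, value) -> bool:
        if self.kind == "numeric":
            lo, hi = self.domain
            try:
                v = float(value)
            except (TypeError, ValueError):
                return False
            return lo <= v <= hi
        return value in self.domain

    def check_value(self, value) -> None:
        if not self.contains(value):
            raise DomainError(
                f"value {value!r} outside domain of attribute {self.name!r}"
            )

    def violations(self) -> list[str]:
        out = []
        if not self.weight > 0:
            out.append(f"{self.name}: weight must be positive, got {self.weight}")
        if self.kind not in ("numeric", "ordinal", "categorical"):
            out.append(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "numeric":
            if len(self.domain) != 2 or not self.domain[0] < self.domain[1]:
                out.append(f"{self.name}: numeric domain must be (lo, hi) with lo < hi")
            if isinstance(self.local_fn, PairTable):
                out.append(f"{self.name}: numeric attribute requires a NumericDifference function")
            else:
                out.extend(self.local_fn.violations(self.name))
        else:
            if len(self.domain) == 0:
                out.append(f"{self.name}: empty value domain")
            if isinstance(self.local_fn, NumericDifference):
                out.append(f"{self.name}: {self.kind} attribute requires a PairTable function")
            else:
                out.extend(self.local_fn.violations(self.name, domain=self.domain))
                for pair in self.local_fn.table:
                    for v in pair:
                        if v not in self.domain:
                            out.append(
                                f"{self.name}: table value {v!r} not in attribute domain"
                            )
        return out


@dataclass(frozen=True)
class SimilarityModel:
    """Ordered collection of weighted attributes (the global measure)."""

    attributes: tuple[AttributeSpec, ...]
    name: str = "unnamed"
    version: str = "0"
    _by_name: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "_by_name", {a.name: a for a in self.attributes})

    def __getitem__(self, name: str) -> AttributeSpec:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    @property
    def total_weight(self) -> float:
        return float(sum(a.weight for a in self.attributes))


def local_similarity(fn: LocalSimilarityFunction, q_value, c_value) -> float:
    """Similarity in [0, 1] between two values of one attribute.

    Reflexive by construction: identical values score 1.0.
    """
    return fn(q_value, c_value)


def amalgamated_similarity(
    model: SimilarityModel,
    query: Mapping[str, object],
    case: Mapping[str, object],
) -> float:
    """Weighted-sum global similarity between two attribute-value records.

    Attributes missing from either record are dropped from both the
    numerator and the denominator (weight renormalisation), so partially
    observed records still score in [0, 1].

    Raises
    ------
    UndefinedSimilarityError
        If no model attribute is present in both records.
    DomainError
        If a shared value lies outside its attribute's domain.
    """
    num = 0.0
    den = 0.0
    for spec in model.attributes:
        if spec.name not in query or spec.name not in case:
            continue
        q, c = query[spec.name], case[spec.name]
        if q is None or c is None:
            continue
        spec.check_value(q)
        spec.check_value(c)
        num += spec.weight * spec.local_fn(q, c)
        den += spec.weight
    if den == 0.0:
        raise UndefinedSimilarityError(
            "no attribute present in both records; similarity undefined"
        )
    return num / den


def weighted_score(
    model: SimilarityModel,
    query: Mapping[str, object],
    case: Mapping[str, object],
) -> float:
    """Un-normalised weighted sum ``sum_i w_i * sim_i`` over shared attributes.

    This is the "total score" column of a worked similarity calculation;
    dividing by the total weight of the shared attributes gives
    :func:`amalgamated_similarity`.
    """
    total = 0.0
    for spec in model.attributes:
        if spec.name not in query or spec.name not in case:
            continue
        q, c = query[spec.name], case[spec.name]
        if q is None or c is None:
            continue
        spec.check_value(q)
        spec.check_value(c)
        total += spec.weight * spec.local_fn(q, c)
    return total


def validate_model(model: SimilarityModel) -> list[str]:
    """Check every attribute and local-function invariant.

    Returns a list of human-readable violations, each naming the offending
    attribute and rule; an empty list means the model is valid.
    """
    out: list[str] = []
    if len(model.attributes) == 0:
        out.append("model has no attributes")
    seen: set[str] = set()
    for a in model.attributes:
        if a.name in seen:
            out.append(f"duplicate attribute name {a.name!r}")
        seen.add(a.name)
        out.extend(a.violations())
    return out
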