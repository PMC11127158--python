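"""Ranked retrieval of the most similar patients from a case base.

Case bases in this setting are a few hundred patients, so retrieval is an
exhaustive comparison of the query against every stored case, sorted by
descending amalgamated similarity.  Ties are broken by case id
(lexicographic), which makes rankings deterministic and independent of the
case-base insertion order.  A stored case sharing the query's id is skipped,
which is what leave-one-out evaluation and a retained patient re-querying
both need.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cases import CaseBase, PatientCase, SuccessCriterion, filter_successful
from .similarity import SimilarityModel, amalgamated_similarity

__all__ = ["RetrievalResult", "retrieve", "retrieve_successful"]


@dataclass(frozen=True)
class RetrievalResult:
    """Descending-similarity ranking of case ids for one query."""

    query_id: str
    ranking: tuple[tuple[str, float], ...]
    k: int
    empty_case_base: bool = False
    treatments: tuple[str | None, ...] | None = None

    def __len__(self) -> int:
        return len(self.ranking)

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.ranking)

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(s for _, s in self.ranking)


def _ranked(model: SimilarityModel, cb: CaseBase, query: PatientCase) -> list[tuple[str, float]]:
    scored = [
        (c.case_id, amalgamated_similarity(model, query.attributes, c.attributes))
        for c in cb.cases
        if c.case_id != query.case_id
    ]
    # descending score, ascending case_id on ties
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


def retrieve(
    model: SimilarityModel,
    cb: CaseBase,
    query: PatientCase,
    k: int = 10,
) -> RetrievalResult:
    """Top-``k`` most similar cases to ``query``, highest similarity first.

    ``k`` larger than the case base returns everything; an empty case base
    yields an empty ranking with ``empty_case_base=True``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    problems = query.validate(model)
    if problems:
        from .cases import CaseValidationError

        raise CaseValidationError("; ".join(problems))
    scored = _ranked(model, cb, query)
    if not scored:
        return RetrievalResult(query_id=query.case_id, ranking=(), k=k, empty_case_base=True)
    return RetrievalResult(query_id=query.case_id, ranking=tuple(scored[:k]), k=k)


def retrieve_successful(
    model: SimilarityModel,
    cb: CaseBase,
    query: PatientCase,
    crit: SuccessCriterion,
    k: int = 10,
) -> RetrievalResult:
    """Top-``k`` among the *successful* cases only, with their treatments.

    Identical to :func:`retrieve` applied to ``filter_successful(cb, crit)``;
    each hit additionally carries the treatment description that the similar,
    successfully treated patient received.
    """
    successful = filter_successful(cb, crit)
    result = retrieve(model, successful, query, k)
    treatments = tuple(successful[cid].treatment for cid in result.case_ids)
    return RetrievalResult(
        query_id=result.query_id,
        ranking=result.ranking,
        k=k,
        empty_case_base=result.empty_case_base,
        treatments=treatments,
    )
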