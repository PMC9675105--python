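"""Scoring and selecting GO terms from propagated partner scores.

Functional partners of a target protein are the other proteins left with
a positive propagated score.  A candidate term fn coming from any
partner is scored by summing the scores of the partners annotated with
it,

    S(fn) = sum over partners j annotated with fn of pr(j),

and candidates are ranked by score descending (term ID ascending breaks
ties).  The number of terms to predict, L, copies the annotation count
of the highest-scoring annotated partner -- the rationale being that a
protein tends to share a similar number of functions with its closest
functional partner; on score ties the larger term count wins.  Domain
nodes influence the ranking only through propagation: they carry no GO
terms themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .io import AnnotationCatalog

__all__ = [
    "RankedFunctionList",
    "Prediction",
    "aggregate_function_scores",
    "determine_L",
    "predict_functions",
]


@dataclass
class RankedFunctionList:
    """Candidate terms ordered by (score desc, term ID asc)."""

    entries: tuple[tuple[str, float], ...]
    n_partners: int

    def __post_init__(self) -> None:
        self.entries = tuple((str(t), float(s)) for t, s in self.entries)
        if any(s < 0 for _, s in self.entries):
            raise ValueError("term scores must be nonnegative")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Prediction:
    """The top-L terms selected for a target protein."""

    target: str
    terms: tuple[str, ...]
    scores: tuple[float, ...]
    L: int
    ranked: RankedFunctionList
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)
    iterations: int = 0
    converged: bool = True

    @property
    def term_set(self) -> frozenset[str]:
        return frozenset(self.terms)


def _positive_partners(
    scores: Mapping[str, float], target: str, min_score: float
) -> dict[str, float]:
    return {
        p: float(s)
        for p, s in scores.items()
        if p != target and float(s) > min_score
    }


def aggregate_function_scores(
    scores: Mapping[str, float],
    annotations: AnnotationCatalog,
    target: str,
    min_score: float = 0.0,
) -> RankedFunctionList:
    """Rank the union of the partners' terms by summed partner score.

    ``scores`` maps every protein to its propagated score; the target is
    excluded from its own partner list.  Partners without annotations
    stay in the partner count but contribute no terms.  No partner with
    a positive score yields an empty list, not an error.
    """
    partners = _positive_partners(scores, target, min_score)
    term_scores: dict[str, float] = {}
    for partner, pr in partners.items():
        for term in annotations.terms(partner):
            term_scores[term] = term_scores.get(term, 0.0) + pr
    ordered = sorted(term_scores.items(), key=lambda e: (-e[1], e[0]))
    return RankedFunctionList(tuple(ordered), len(partners))


def determine_L(
    scores: Mapping[str, float],
    annotations: AnnotationCatalog,
    target: str,
    min_score: float = 0.0,
) -> int:
    """L = term count of the highest-scoring annotated partner.

    Ties at the top score resolve to the maximum term count among the
    tied partners; no annotated partner gives L = 0.
    """
    partners = _positive_partners(scores, target, min_score)
    best_score = None
    best_count = 0
    for partner, pr in partners.items():
        count = len(annotations.terms(partner))
        if count == 0:
            continue
        if best_score is None or pr > best_score:
            best_score, best_count = pr, count
        elif pr == best_score and count > best_count:
            best_count = count
    return best_count


def _provenance(
    partners: Mapping[str, float],
    annotations: AnnotationCatalog,
    terms: tuple[str, ...],
) -> dict[str, tuple[str, ...]]:
    out: dict[str, tuple[str, ...]] = {}
    for term in terms:
        contributors = [
            p for p in partners if term in annotations.terms(p)
        ]
        contributors.sort(key=lambda p: (-partners[p], p))
        out[term] = tuple(contributors)
    return out


def predict_functions(
    target: str,
    scores: Mapping[str, float],
    annotations: AnnotationCatalog,
    min_score: float = 0.0,
    iterations: int = 0,
    converged: bool = True,
) -> Prediction:
    """Assemble the top-L prediction from propagated protein scores.

    The selected terms are a prefix of the ranked list of length
    min(L, number of candidates).
    """
    ranked = aggregate_function_scores(scores, annotations, target, min_score)
    L = determine_L(scores, annotations, target, min_score)
    selected = ranked.entries[: min(L, len(ranked))]
    partners = _positive_partners(scores, target, min_score)
    terms = tuple(t for t, _ in selected)
    return Prediction(
        target=target,
        terms=terms,
        scores=tuple(s for _, s in selected),
        L=L,
        ranked=ranked,
        provenance=_provenance(partners, annotations, terms),
        iterations=iterations,
        converged=converged,
    )
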