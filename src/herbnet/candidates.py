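"""Candidate-target mapping and high-confidence interactor expansion.

Candidate targets are the intersection of the ingredient target universe
with the disease-gene set — the genes a formula's ingredients can reach
that are also implicated in the disease.  The candidate set is then
expanded with proteins interacting with a candidate above a confidence
cut-off, in the style of a STITCH/STRING neighborhood query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .datatypes import DiseaseGeneSet, ScoredEdge, ValidationError
from .targets import Compendium


@dataclass
class CandidateSet:
    """Candidates, their evidence class, and the PPI expansion around them."""

    candidates: set[str] = field(default_factory=set)
    evidence_of: dict[str, str] = field(default_factory=dict)
    interactors: set[str] = field(default_factory=set)
    kept_edges: set[ScoredEdge] = field(default_factory=set)

    def __post_init__(self) -> None:
        if set(self.evidence_of) != self.candidates:
            raise ValidationError("evidence_of keys must equal the candidate set")
        if self.interactors & self.candidates:
            raise ValidationError("interactors must be disjoint from candidates")


def map_candidates(c: Compendium, d: DiseaseGeneSet) -> CandidateSet:
    """Intersect the target universe with the disease genes.

    Each candidate is classified ``validated`` if any validated association
    reaches it, else ``predicted``.  An empty intersection is legal (the
    pipeline warns rather than fails).
    """
    candidates = c.target_universe & d.genes
    if not candidates:
        warnings.warn(
            "candidate set is empty: no overlap between ingredient targets "
            "and disease genes",
            stacklevel=2,
        )
    evidence = {g: c.evidence_of(g) for g in candidates}
    return CandidateSet(candidates=candidates, evidence_of=evidence)


def expand_interactors(
    cands: CandidateSet,
    edges: list[ScoredEdge],
    score_min: float = 0.9,
    include_interactor_interactor: bool = True,
) -> CandidateSet:
    """Attach high-confidence PPI edges and the interactors they introduce.

    An edge is kept when its score strictly exceeds ``score_min`` and at
    least one endpoint is a candidate; endpoints that are not candidates
    become interactors.  With ``include_interactor_interactor`` (the
    default, matching neighborhood-query exports) edges between two
    interactors are also retained, provided both endpoints were introduced
    by a candidate-touching edge.
    """
    candidate_touching = [
        e
        for e in edges
        if e.score > score_min and (e.a in cands.candidates or e.b in cands.candidates)
    ]
    interactors = {
        n for e in candidate_touching for n in e.pair if n not in cands.candidates
    }
    kept = set(candidate_touching)
    if include_interactor_interactor:
        kept |= {
            e
            for e in edges
            if e.score > score_min and e.a in interactors and e.b in interactors
        }
    return CandidateSet(
        candidates=set(cands.candidates),
        evidence_of=dict(cands.evidence_of),
        interactors=interactors,
        kept_edges=kept,
    )
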