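"""Assembly of the deduplicated ingredient→target compendium.

Two evidence routes feed the compendium: validated associations
(literature-curated) and predicted associations (3D-structure similarity
searches, filtered on the search's similarity and prediction scores).
Duplicate (ingredient, gene) pairs collapse to a single association, with
validated evidence winning over predicted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .datatypes import IngredientRecord, TargetAssociation, ValidationError


def filter_predicted(
    assocs: list[TargetAssociation],
    sim_min: float = 1.0,
    score_min: float = 0.0,
) -> list[TargetAssociation]:
    """Apply the similarity-search score filter to predicted associations.

    A predicted association is kept iff ``similarity > sim_min`` and
    ``prediction_score > score_min`` (both strict).  Validated associations
    pass through untouched.  Note the similarity score of the upstream 3D
    search can exceed 1, so ``sim_min=1.0`` is a meaningful strict bound.
    """
    kept: list[TargetAssociation] = []
    for a in assocs:
        if a.evidence == "validated":
            kept.append(a)
            continue
        if a.similarity is None or a.prediction_score is None:
            raise ValidationError(
                f"predicted association ({a.ingredient_id!r}, {a.gene!r}) "
                "lacks similarity/prediction scores"
            )
        if a.similarity > sim_min and a.prediction_score > score_min:
            kept.append(a)
    return kept


@dataclass
class Compendium:
    """Deduplicated ingredient→gene mapping with derived indexes.

    ``associations`` holds (ingredient, gene, evidence) triples after the
    validated-wins dedup rule; ``per_ingredient`` and ``per_gene_herbs``
    are derived views (gene sets per ingredient; herbs reaching each gene
    through any ingredient).
    """

    associations: set[tuple[str, str, str]] = field(default_factory=set)
    target_universe: set[str] = field(default_factory=set)
    per_ingredient: dict[str, set[str]] = field(default_factory=dict)
    per_gene_herbs: dict[str, set[str]] = field(default_factory=dict)

    def evidence_of(self, gene: str) -> str:
        """Best evidence class reaching ``gene``: validated beats predicted."""
        classes = {ev for (_, g, ev) in self.associations if g == gene}
        if not classes:
            raise KeyError(gene)
        return "validated" if "validated" in classes else "predicted"


def build_compendium(
    validated: list[TargetAssociation],
    predicted_kept: list[TargetAssociation],
    ingredients: list[IngredientRecord],
) -> Compendium:
    """Merge both evidence routes into one deduplicated compendium.

    Every association's ingredient must appear in ``ingredients`` (the
    screened active set); the herb membership of those records is composed
    through the associations to yield ``per_gene_herbs``.
    """
    by_id = {r.ingredient_id: r for r in ingredients}
    evidence: dict[tuple[str, str], str] = {}
    for a in list(validated) + list(predicted_kept):
        if a.ingredient_id not in by_id:
            raise ValidationError(
                f"association references unknown ingredient {a.ingredient_id!r}"
            )
        key = (a.ingredient_id, a.gene)
        if evidence.get(key) == "validated":
            continue  # validated wins on conflict
        if a.evidence == "validated" or key not in evidence:
            evidence[key] = a.evidence

    c = Compendium()
    for (ing, gene), ev in evidence.items():
        c.associations.add((ing, gene, ev))
        c.target_universe.add(gene)
        c.per_ingredient.setdefault(ing, set()).add(gene)
        c.per_gene_herbs.setdefault(gene, set()).update(by_id[ing].herbs)
    return c


def coverage_stats(c: Compendium) -> pd.DataFrame:
    """Per-ingredient target counts as a share of the whole target universe.

    Columns ``ingredient``, ``n_targets``, ``pct_of_universe`` (percent,
    one decimal), sorted by target count descending then name.
    """
    if not c.target_universe:
        raise ValidationError("compendium is empty")
    universe = len(c.target_universe)
    rows = [
        {
            "ingredient": ing,
            "n_targets": len(genes),
            "pct_of_universe": round(100.0 * len(genes) / universe, 1),
        }
        for ing, genes in c.per_ingredient.items()
    ]
    df = pd.DataFrame(rows, columns=["ingredient", "n_targets", "pct_of_universe"])
    return df.sort_values(
        ["n_targets", "ingredient"], ascending=[False, True], ignore_index=True
    )


def common_targets_by_herb_count(
    c: Compendium, min_herbs: int = 1
) -> dict[int, set[str]]:
    """Bucket target genes by how many herbs reach them.

    Gene ``g`` lands in bucket ``len(per_gene_herbs[g])``; only buckets with
    count >= ``min_herbs`` are returned.
    """
    if min_herbs < 1:
        raise ValidationError(f"min_herbs must be >= 1, got {min_herbs}")
    buckets: dict[int, set[str]] = {}
    for gene, herbs in c.per_gene_herbs.items():
        n = len(herbs)
        if n >= min_herbs:
            buckets.setdefault(n, set()).add(gene)
    return buckets
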