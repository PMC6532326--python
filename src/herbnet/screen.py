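"""ADME screening of herbal ingredients and cross-database merging.

Systems-pharmacology databases report two pharmacokinetic screens per
compound: oral bioavailability (OB, percent) and drug-likeness (DL, a
unitless Tanimoto-style score in [0, 1]).  Compounds passing both
thresholds are treated as "active ingredients"; curated-bioactivity
sources (whose entries are literature-validated rather than
ADME-predicted) bypass the screen and are merged in afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import IngredientRecord, ValidationError


@dataclass
class ScreenConfig:
    """Thresholds for the ADME screen.

    ``inclusive`` controls the boundary: kept iff ``ob >= ob_min`` and
    ``dl >= dl_min`` when true (the default), strict ``>`` otherwise.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValidationError(f"ob_min must be >= 0, got {self.ob_min}")
        if not (0.0 <= self.dl_min <= 1.0):
            raise ValidationError(f"dl_min must be in [0,1], got {self.dl_min}")


def screen_adme(
    records: list[IngredientRecord], cfg: ScreenConfig | None = None
) -> list[IngredientRecord]:
    """Keep ingredients passing both the OB and DL thresholds, order preserved.

    Every record must carry non-null ``ob`` and ``dl``.
    """
    cfg = cfg or ScreenConfig()
    for r in records:
        if r.ob is None or r.dl is None:
            raise ValidationError(
                f"ingredient {r.ingredient_id!r} has no OB/DL scores; "
                "cannot apply the ADME screen"
            )
    if cfg.inclusive:
        return [r for r in records if r.ob >= cfg.ob_min and r.dl >= cfg.dl_min]
    return [r for r in records if r.ob > cfg.ob_min and r.dl > cfg.dl_min]


def merge_sources(
    screened: list[IngredientRecord], curated: list[IngredientRecord]
) -> list[IngredientRecord]:
    """Union two ingredient lists keyed by canonicalized name.

    Herb memberships are unioned; an ingredient present in both lists gets
    ``source="both"`` and keeps the ADME scores from whichever record has
    them.  Output is sorted by ingredient id for determinism.
    """
    merged: dict[str, IngredientRecord] = {}
    for rec in list(screened) + list(curated):
        if rec.ingredient_id not in merged:
            merged[rec.ingredient_id] = IngredientRecord(
                ingredient_id=rec.ingredient_id,
                herbs=set(rec.herbs),
                ob=rec.ob,
                dl=rec.dl,
                source=rec.source,
            )
        else:
            prev = merged[rec.ingredient_id]
            prev.herbs |= rec.herbs
            if prev.ob is None:
                prev.ob = rec.ob
            if prev.dl is None:
                prev.dl = rec.dl
            if prev.source != rec.source:
                prev.source = "both"
    return sorted(merged.values(), key=lambda r: r.ingredient_id)


def herb_overlap_table(
    merged: list[IngredientRecord], overlap_only: bool = True
) -> pd.DataFrame:
    """Tabulate how many herbs contribute each ingredient.

    One row per ingredient with columns ``ingredient``, ``herb_count`` and a
    comma-joined ``herbs`` column, sorted by herb count descending then name.
    With ``overlap_only`` (default) only ingredients found in at least two
    herbs are listed — the shared ingredients of the formula.
    """
    if not merged:
        raise ValidationError("merged ingredient list is empty")
    rows = [
        {
            "ingredient": r.ingredient_id,
            "herb_count": len(r.herbs),
            "herbs": ", ".join(sorted(r.herbs)),
        }
        for r in merged
        if not overlap_only or len(r.herbs) >= 2
    ]
    df = pd.DataFrame(rows, columns=["ingredient", "herb_count", "herbs"])
    return df.sort_values(
        ["herb_count", "ingredient"], ascending=[False, True], ignore_index=True
    )
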