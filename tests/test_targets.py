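"""Target-compendium assembly, score filtering and coverage statistics."""

from __future__ import annotations

import numpy as np
import pytest

from herbnet.datatypes import IngredientRecord, TargetAssociation, ValidationError
from herbnet.targets import (
    build_compendium,
    common_targets_by_herb_count,
    coverage_stats,
    filter_predicted,
)


def ingredient(name, herbs=("H1",)):
    return IngredientRecord(name, set(herbs), ob=40.0, dl=0.3)


def predicted(ing, gene, sim, score):
    return TargetAssociation(ing, gene, "predicted", similarity=sim, prediction_score=score)


class TestFilterPredicted:
    def test_passing_record_kept(self):
        assert len(filter_predicted([predicted("i", "G", 1.2, 0.5)])) == 1

    def test_similarity_boundary_is_strict(self):
        assert filter_predicted([predicted("i", "G", 1.0, 0.5)]) == []

    def test_score_boundary_is_strict(self):
        assert filter_predicted([predicted("i", "G", 1.2, 0.0)]) == []

    def test_validated_pass_through(self):
        v = TargetAssociation("i", "G", "validated")
        assert filter_predicted([v, predicted("i", "H", 0.2, -0.1)]) == [v]

    def test_null_scores_rejected(self):
        bad = TargetAssociation("i", "G", "predicted")
        with pytest.raises(ValidationError, match="lacks similarity"):
            filter_predicted([bad])

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(7)
        assocs = [
            predicted(
                f"i{k}", f"G{k}", float(rng.uniform(0, 2)), float(rng.uniform(-1, 1))
            )
            for k in range(50)
        ]
        kept = filter_predicted(assocs)
        expected = [a for a in assocs if a.similarity > 1.0 and a.prediction_score > 0.0]
        assert kept == expected


class TestBuildCompendium:
    def test_validated_wins_on_conflict(self):
        ing = [ingredient("i1")]
        c = build_compendium(
            [TargetAssociation("i1", "AKT1", "validated")],
            [predicted("i1", "AKT1", 1.5, 0.5)],
            ing,
        )
        assert c.associations == {("i1", "AKT1", "validated")}
        assert c.evidence_of("AKT1") == "validated"

    def test_conflict_rule_order_independent(self):
        ing = [ingredient("i1")]
        c = build_compendium(
            [TargetAssociation("i1", "AKT1", "validated")],
            [predicted("i1", "AKT1", 1.5, 0.5)],
            ing,
        )
        c2 = build_compendium(
            [], [predicted("i1", "AKT1", 1.5, 0.5)], ing
        )
        assert c.evidence_of("AKT1") == "validated"
        assert c2.evidence_of("AKT1") == "predicted"

    def test_empty_inputs(self):
        c = build_compendium([], [], [ingredient("i1")])
        assert not c.target_universe and not c.associations

    def test_orphan_association_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            build_compendium(
                [TargetAssociation("ghost", "G", "validated")], [], [ingredient("i1")]
            )

    def test_per_gene_herbs_matches_hand_composition(self):
        ings = [
            ingredient("i1", herbs=("H1", "H2")),
            ingredient("i2", herbs=("H2",)),
            ingredient("i3", herbs=("H3",)),
        ]
        c = build_compendium(
            [
                TargetAssociation("i1", "A", "validated"),
                TargetAssociation("i2", "A", "validated"),
                TargetAssociation("i3", "B", "validated"),
            ],
            [predicted("i2", "C", 1.5, 0.5)],
            ings,
        )
        # hand-composed gene -> herbs via gene -> ingredients -> herbs
        assert c.per_gene_herbs == {
            "A": {"H1", "H2"},
            "B": {"H3"},
            "C": {"H2"},
        }

    def test_universe_is_union_of_per_ingredient(self):
        ings = [ingredient("i1"), ingredient("i2")]
        c = build_compendium(
            [TargetAssociation("i1", "A", "validated")],
            [predicted("i2", "B", 1.5, 0.5)],
            ings,
        )
        assert c.target_universe == set().union(*c.per_ingredient.values())


class TestCoverageStats:
    def _compendium_with_counts(self, counts: dict[str, int], universe: int):
        """Compendium whose per-ingredient target counts and universe size
        are exactly as requested (a filler ingredient covers the rest)."""
        genes = [f"G{i:04d}" for i in range(universe)]
        ings = [ingredient(name) for name in counts] + [ingredient("filler")]
        validated = []
        for name, n in counts.items():
            validated += [TargetAssociation(name, g, "validated") for g in genes[:n]]
        validated += [TargetAssociation("filler", g, "validated") for g in genes]
        return build_compendium(validated, [], ings)

    def test_published_percentages(self):
        c = self._compendium_with_counts({"quercetin": 308, "baicalein": 244}, 898)
        table = coverage_stats(c)
        pct = dict(zip(table["ingredient"], table["pct_of_universe"]))
        assert pct["quercetin"] == 34.3
        assert pct["baicalein"] == 27.2

    def test_full_owner_is_100(self):
        c = self._compendium_with_counts({}, 10)
        table = coverage_stats(c)
        assert table.iloc[0]["pct_of_universe"] == 100.0

    def test_percentages_bounded_and_top_is_max(self):
        c = self._compendium_with_counts({"a": 5, "b": 9}, 20)
        table = coverage_stats(c)
        assert (table["pct_of_universe"] <= 100.0).all()
        assert table.iloc[0]["n_targets"] == max(
            len(g) for g in c.per_ingredient.values()
        )

    def test_empty_compendium_rejected(self):
        with pytest.raises(ValidationError):
            coverage_stats(build_compendium([], [], []))


class TestHerbCountBuckets:
    def _fixture(self):
        rng = np.random.default_rng(11)
        herbs = [f"H{i}" for i in range(12)]
        ings = [
            ingredient(f"i{k}", herbs=rng.choice(herbs, size=int(rng.integers(1, 5)), replace=False))
            for k in range(30)
        ]
        validated = [
            TargetAssociation(f"i{k}", f"G{int(g)}", "validated")
            for k in range(30)
            for g in rng.choice(40, size=6, replace=False)
        ]
        return build_compendium(validated, [], ings)

    def test_gene_hit_by_all_herbs_lands_in_top_bucket(self):
        herbs = [f"H{i}" for i in range(12)]
        ings = [ingredient(f"i{k}", herbs=(herbs[k],)) for k in range(12)]
        validated = [TargetAssociation(f"i{k}", "OMNI", "validated") for k in range(12)]
        c = build_compendium(validated, [], ings)
        buckets = common_targets_by_herb_count(c, 1)
        assert buckets[12] == {"OMNI"}

    def test_buckets_match_brute_force_recount(self):
        c = self._fixture()
        buckets = common_targets_by_herb_count(c, 2)
        for count, genes in buckets.items():
            for g in genes:
                assert len(c.per_gene_herbs[g]) == count
        expected_total = sum(
            1 for g, hs in c.per_gene_herbs.items() if len(hs) >= 2
        )
        assert sum(len(v) for v in buckets.values()) == expected_total

    def test_low_count_gene_absent_at_high_threshold(self):
        c = self._fixture()
        buckets = common_targets_by_herb_count(c, 7)
        assert all(count >= 7 for count in buckets)

    def test_min_herbs_validated(self):
        with pytest.raises(ValidationError):
            common_targets_by_herb_count(self._fixture(), 0)
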