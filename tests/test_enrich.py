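"""Hypergeometric over-representation, BH adjustment and kappa grouping."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from herbnet.datatypes import GeneSet, GeneSetCollection, ValidationError
from herbnet.enrich import (
    cohens_kappa,
    hypergeom_enrich,
    kappa_group,
    significant_rows,
    summarize_categories,
)


def collection(term_genes: dict[str, set[str]], category="kegg"):
    return GeneSetCollection(
        {
            tid: GeneSet(name=f"term {tid}", category=category, genes=set(genes))
            for tid, genes in term_genes.items()
        }
    )


def upper_tail_by_enumeration(N, K, n, k):
    """P[X >= k] by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    marked = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(universe, n) if len(marked & set(draw)) >= k
    )
    return hits / math.comb(N, n)


class TestHypergeom:
    def test_closed_form_full_overlap(self):
        # drawing all 5 marked genes in 5 draws from 20: p = 1/C(20,5)
        background = {f"G{i}" for i in range(20)}
        term = {f"G{i}" for i in range(5)}
        rows = hypergeom_enrich(term, collection({"T": term}), background)
        assert rows[0].p == pytest.approx(1 / 15504, rel=1e-9)

    def test_zero_overlap_term_omitted(self):
        background = {f"G{i}" for i in range(10)}
        sets = collection({"T1": {"G0"}, "T2": {"G9"}})
        rows = hypergeom_enrich({"G0"}, sets, background)
        assert [r.term_id for r in rows] == ["T1"]

    def test_matches_exhaustive_enumeration_n10(self):
        N, K, n = 10, 5, 5
        background = {f"G{i}" for i in range(N)}
        term = {f"G{i}" for i in range(K)}
        for k in range(1, min(K, n) + 1):
            query = {f"G{i}" for i in range(k)} | {f"G{i}" for i in range(K, K + n - k)}
            rows = hypergeom_enrich(query, collection({"T": term}), background)
            assert rows[0].k == k
            assert rows[0].p == pytest.approx(
                upper_tail_by_enumeration(N, K, n, k), rel=1e-9
            )

    def test_invariant_to_genes_outside_background(self):
        background = {f"G{i}" for i in range(12)}
        term = {"G0", "G1", "G2", "ALIEN1", "ALIEN2"}
        query = {"G0", "G1", "G5"}
        rows = hypergeom_enrich(query, collection({"T": term}), background)
        rows2 = hypergeom_enrich(
            query, collection({"T": term & background}), background
        )
        assert rows[0].p == rows2[0].p
        assert rows[0].K == 3

    def test_bh_is_monotone_in_p_rank_and_capped(self):
        rng = np.random.default_rng(13)
        background = {f"G{i}" for i in range(50)}
        sets = collection(
            {
                f"T{j}": set(rng.choice(sorted(background), size=10, replace=False))
                for j in range(20)
            }
        )
        query = set(rng.choice(sorted(background), size=12, replace=False))
        rows = [r for r in hypergeom_enrich(query, sets, background)]
        rows.sort(key=lambda r: r.p)
        qs = [r.q for r in rows]
        assert all(q1 <= q2 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q <= 1.0 and r.q >= r.p for r in rows)

    def test_bh_within_category(self):
        background = {f"G{i}" for i in range(30)}
        kegg = collection({"T1": {"G0", "G1", "G2"}})
        mf = collection({"M1": {"G0", "G1", "G2"}, "M2": set(list(background)[:15])},
                        category="molecular_function")
        sets = GeneSetCollection({**kegg.terms, **mf.terms})
        rows = hypergeom_enrich({"G0", "G1", "G2"}, sets, background)
        by_id = {r.term_id: r for r in rows}
        # the lone kegg term is unadjusted; the same term in the 2-term
        # molecular_function family cannot have a smaller q
        assert by_id["T1"].q == pytest.approx(by_id["T1"].p)
        assert by_id["M1"].q >= by_id["T1"].q

    def test_empty_query_or_background_rejected(self):
        sets = collection({"T": {"G0"}})
        with pytest.raises(ValidationError):
            hypergeom_enrich(set(), sets, {"G0"})
        with pytest.raises(ValidationError):
            hypergeom_enrich({"G0"}, sets, set())
        with pytest.raises(ValidationError, match="missing from background"):
            hypergeom_enrich({"NOT_THERE"}, sets, {"G0"})


class TestKappa:
    def test_identical_memberships(self):
        u = {f"G{i}" for i in range(10)}
        x = {"G0", "G1", "G2"}
        assert cohens_kappa(x, set(x), u) == pytest.approx(1.0)

    def test_disjoint_memberships_nonpositive(self):
        u = {f"G{i}" for i in range(10)}
        assert cohens_kappa({"G0", "G1"}, {"G2", "G3"}, u) <= 0.0

    def test_hand_computed_two_by_two(self):
        # universe of 6; x = {a,b,c}, y = {b,c,d}: a=2, b=1, c=1, d=2
        u = {"a", "b", "c", "d", "e", "f"}
        x = {"a", "b", "c"}
        y = {"b", "c", "d"}
        po = 4 / 6
        pe = (3 * 3 + 3 * 3) / 36
        expected = (po - pe) / (1 - pe)
        assert cohens_kappa(x, y, u) == pytest.approx(expected)
        assert expected == pytest.approx(1 / 3)

    def test_degenerate_universe(self):
        u = {"a", "b"}
        assert cohens_kappa({"a", "b"}, {"a", "b"}, u) == 1.0


class TestKappaGrouping:
    def _rows(self, term_genes, query, background):
        sets = collection(term_genes)
        rows = hypergeom_enrich(query, sets, background)
        return rows, sets

    def test_identical_terms_share_group(self):
        background = {f"G{i}" for i in range(20)}
        genes = {"G0", "G1", "G2"}
        rows, sets = self._rows({"T1": genes, "T2": set(genes)}, genes, background)
        grouped = kappa_group(rows, sets, genes)
        assert grouped[0].group_id == grouped[1].group_id
        assert grouped[0].group_share == 1.0

    def test_disjoint_terms_separate_groups(self):
        background = {f"G{i}" for i in range(20)}
        q = {"G0", "G1", "G10", "G11"}
        rows, sets = self._rows(
            {"T1": {"G0", "G1"}, "T2": {"G10", "G11"}}, q, background
        )
        grouped = kappa_group(rows, sets, q)
        assert grouped[0].group_id != grouped[1].group_id
        assert all(r.group_share == 0.5 for r in grouped)

    def test_group_named_by_lowest_p_member(self):
        background = {f"G{i}" for i in range(30)}
        q = {"G0", "G1", "G2", "G3", "G4", "G5"}
        rows, sets = self._rows(
            {
                "BIG": {"G0", "G1", "G2", "G3"},
                "SMALL": {"G0", "G1", "G2"},
                "OTHER": {"G4", "G5"},
            },
            q,
            background,
        )
        grouped = kappa_group(rows, sets, q, kappa_min=0.3)
        by_id = {r.term_id: r for r in grouped}
        # BIG and SMALL agree (kappa 2/3 over the 6-gene hit universe) and
        # the lower-p member (BIG) names the group; OTHER stands alone
        assert by_id["SMALL"].group_id == "BIG"
        assert by_id["BIG"].group_id == "BIG"
        assert by_id["OTHER"].group_id == "OTHER"

    def test_member_counts_sum_to_significant_terms(self):
        rng = np.random.default_rng(44)
        background = {f"G{i}" for i in range(40)}
        sets = collection(
            {
                f"T{j}": set(rng.choice(sorted(background), size=8, replace=False))
                for j in range(12)
            }
        )
        query = set(rng.choice(sorted(background), size=10, replace=False))
        rows = hypergeom_enrich(query, sets, background)
        grouped = kappa_group(rows, sets, query)
        groups: dict[str, int] = {}
        for r in grouped:
            groups[r.group_id] = groups.get(r.group_id, 0) + 1
        assert sum(groups.values()) == len(grouped)


class TestSummaries:
    def test_single_term_is_full_share(self):
        background = {f"G{i}" for i in range(20)}
        genes = {"G0", "G1", "G2"}
        sets = collection({"T1": genes})
        rows = hypergeom_enrich(genes, sets, background)
        grouped = kappa_group(rows, sets, genes)
        summary = summarize_categories(grouped)
        assert summary["kegg"].iloc[0]["group_share_pct"] == 100.0

    def test_empty_rows_warn(self):
        with pytest.warns(UserWarning, match="empty"):
            assert summarize_categories([]) == {}

    def test_shares_sum_to_100_per_category(self):
        rng = np.random.default_rng(5)
        background = {f"G{i}" for i in range(40)}
        sets = collection(
            {
                f"T{j}": set(rng.choice(sorted(background), size=8, replace=False))
                for j in range(10)
            }
        )
        query = set(rng.choice(sorted(background), size=12, replace=False))
        rows = hypergeom_enrich(query, sets, background)
        grouped = kappa_group(rows, sets, query)
        summary = summarize_categories(grouped)
        for df in summary.values():
            assert df["group_share_pct"].sum() == pytest.approx(100.0, abs=0.3)

    def test_planted_term_dominates(self):
        # query over-samples one term's genes at 5x the background rate
        recovered = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            background = [f"G{i}" for i in range(200)]
            planted = set(rng.choice(background, size=25, replace=False))
            sets = collection(
                {
                    "PLANTED": planted,
                    **{
                        f"T{j}": set(rng.choice(background, size=25, replace=False))
                        for j in range(8)
                    },
                }
            )
            weights = np.array([5.0 if g in planted else 1.0 for g in background])
            weights /= weights.sum()
            query = set(rng.choice(background, size=25, replace=False, p=weights))
            rows = hypergeom_enrich(query, sets, set(background))
            best = min(rows, key=lambda r: r.p)
            recovered += best.term_id == "PLANTED"
        assert recovered >= 9
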