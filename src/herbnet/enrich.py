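"""Over-representation analysis with kappa-statistic term grouping.

For a query gene set (typically the key targets of the network) each
annotation term is tested with the hypergeometric upper tail:

    p = P[X >= k],  X ~ Hypergeometric(N, K, n)

where N is the background size, K the term size within the background,
n the query size and k the overlap.  Benjamini–Hochberg correction is
applied within each category (pathways and molecular functions are
separate analyses).  Significant terms are then clustered by pairwise
Cohen's kappa of their gene memberships — the grouping convention of
ClueGO-style enrichment tools — and each group is named after its
lowest-p ("leading") term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetCollection, ValidationError


@dataclass
class EnrichmentRow:
    """One tested term with its counts, p-values and kappa group."""

    term_id: str
    name: str
    category: str
    k: int  # query genes in term
    K: int  # term size within background
    n: int  # query size
    N: int  # background size
    p: float
    q: float = 1.0
    group_id: str | None = None
    group_share: float | None = None


def hypergeom_enrich(
    query: set[str],
    sets: GeneSetCollection,
    background: set[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of ``query`` against every term.

    Terms are intersected with the background before testing; terms with
    zero query overlap are omitted.  BH adjustment runs within each
    category separately.  Rows are sorted by (category, p, term_id).
    """
    if not query:
        raise ValidationError("query gene set is empty")
    if not background:
        raise ValidationError("background gene set is empty")
    stray = query - background
    if stray:
        raise ValidationError(
            f"query genes missing from background: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(query)

    rows: list[EnrichmentRow] = []
    for term_id in sorted(sets.terms):
        term = sets[term_id]
        term_genes = term.genes & background
        K = len(term_genes)
        k = len(term_genes & query)
        if k == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                name=term.name,
                category=term.category,
                k=k,
                K=K,
                n=n,
                N=N,
                p=min(max(p, 0.0), 1.0),
            )
        )

    for category in sorted({r.category for r in rows}):
        cat_rows = [r for r in rows if r.category == category]
        _, qvals, _, _ = multipletests([r.p for r in cat_rows], method="fdr_bh")
        for r, qv in zip(cat_rows, qvals):
            r.q = float(qv)

    rows.sort(key=lambda r: (r.category, r.p, r.term_id))
    return rows


def significant_rows(rows: list[EnrichmentRow], q_max: float = 0.05) -> list[EnrichmentRow]:
    """Rows passing the adjusted-p cut used for grouping."""
    return [r for r in rows if r.q < q_max]


def cohens_kappa(x: set[str], y: set[str], universe: set[str]) -> float:
    """Cohen's kappa between two gene memberships over a finite universe.

    Agreement is computed from the 2x2 contingency of membership
    indicators.  When chance agreement is 1 (both memberships constant),
    kappa is defined as 1 for identical vectors and 0 otherwise.
    """
    if not universe:
        raise ValidationError("kappa universe is empty")
    t = len(universe)
    xm = x & universe
    ym = y & universe
    a = len(xm & ym)
    b = len(xm - ym)
    c = len(ym - xm)
    d = t - a - b - c
    po = (a + d) / t
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (t * t)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def kappa_group(
    rows: list[EnrichmentRow],
    sets: GeneSetCollection,
    query: set[str],
    kappa_min: float = 0.4,
) -> list[EnrichmentRow]:
    """Cluster significant terms by gene-membership kappa, per category.

    Membership vectors are binary indicators over the union of query-hit
    genes of the category's significant terms (the genes driving the
    signal, not the full background — the ClueGO convention).  Terms with
    pairwise kappa >= ``kappa_min`` are linked; groups are the connected
    components, labelled by their lowest-p member; ``group_share`` is the
    group's fraction of the category's significant terms.
    """
    if not rows:
        raise ValidationError("no significant rows to group")
    for category in sorted({r.category for r in rows}):
        cat_rows = [r for r in rows if r.category == category]
        hits = {r.term_id: sets[r.term_id].genes & query for r in cat_rows}
        universe: set[str] = set().union(*hits.values())
        g = nx.Graph()
        g.add_nodes_from(hits)
        ids = sorted(hits)
        for i, t1 in enumerate(ids):
            for t2 in ids[i + 1 :]:
                if cohens_kappa(hits[t1], hits[t2], universe) >= kappa_min:
                    g.add_edge(t1, t2)
        total = len(cat_rows)
        by_id = {r.term_id: r for r in cat_rows}
        for component in nx.connected_components(g):
            leader = min(component, key=lambda tid: (by_id[tid].p, tid))
            share = len(component) / total
            for tid in component:
                by_id[tid].group_id = leader
                by_id[tid].group_share = share
    return rows


def summarize_categories(rows: list[EnrichmentRow]) -> dict[str, pd.DataFrame]:
    """Per-category group summary (the stacked-share chart behind it).

    For each category: one row per kappa group with the leading term's
    name, the member terms, and the group's share of the category's
    significant terms in percent (shares sum to 100 per category).
    """
    if not rows:
        warnings.warn("no significant terms; summary is empty", stacklevel=2)
        return {}
    out: dict[str, pd.DataFrame] = {}
    for category in sorted({r.category for r in rows}):
        cat_rows = [r for r in rows if r.category == category]
        if any(r.group_id is None for r in cat_rows):
            raise ValidationError("rows must be kappa-grouped before summarizing")
        by_id = {r.term_id: r for r in cat_rows}
        groups: dict[str, list[EnrichmentRow]] = {}
        for r in cat_rows:
            groups.setdefault(r.group_id, []).append(r)
        recs = []
        for leader_id, members in groups.items():
            leader = by_id[leader_id]
            recs.append(
                {
                    "group_id": leader_id,
                    "group_name": leader.name,
                    "n_terms": len(members),
                    "group_share_pct": round(100.0 * len(members) / len(cat_rows), 1),
                    "min_p": min(m.p for m in members),
                    "member_terms": ", ".join(sorted(m.term_id for m in members)),
                }
            )
        df = pd.DataFrame(recs).sort_values(
            ["n_terms", "min_p"], ascending=[False, True], ignore_index=True
        )
        out[category] = df
    return out


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Flat TSV-ready table of all row fields."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "name": r.name,
                "category": r.category,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "group_id": r.group_id if r.group_id is not None else "",
                "group_share": r.group_share if r.group_share is not None else "",
            }
            for r in rows
        ],
        columns=[
            "term_id",
            "name",
            "category",
            "k",
            "K",
            "n",
            "N",
            "p",
            "q",
            "group_id",
            "group_share",
        ],
    )
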