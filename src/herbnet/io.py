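"""Readers and writers for every external format the pipeline touches.

All tabular inputs are TSV with a header row; gene sets use the GMT dialect;
networks export to SIF, GraphML and a flat node table.  Readers
canonicalize identifiers on the way in (ingredient names lower-cased,
gene symbols upper-cased) and validate against the domain types, so a
successfully loaded object satisfies its invariants.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    FormatError,
    GeneSet,
    GeneSetCollection,
    IngredientRecord,
    ScoredEdge,
    TargetAssociation,
    TripartiteNetwork,
    canonical_name,
    canonical_symbol,
)

NETWORK_FORMATS = ("sif", "graphml", "node_table")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def _parse_float(raw, column: str, line: int, path) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise FormatError(
            f"{path}, line {line}: non-numeric {column} value {raw!r}"
        ) from None


def read_ingredient_table(path, source_tag: str) -> list[IngredientRecord]:
    """Load a herb→ingredient TSV into deduplicated ingredient records.

    Expects columns ``herb``, ``ingredient``, ``ob``, ``dl`` (``ob``/``dl``
    may be empty, e.g. for curated-bioactivity exports).  Rows sharing a
    canonicalized ingredient name are merged, with herbs unioned; the first
    non-null ob/dl value per ingredient wins.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("herb", "ingredient", "ob", "dl"), path)

    records: dict[str, IngredientRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        name = canonical_name(row.ingredient)
        ob = _parse_float(row.ob, "ob", line, path)
        dl = _parse_float(row.dl, "dl", line, path)
        herb = row.herb.strip()
        if name in records:
            rec = records[name]
            rec.herbs.add(herb)
            if rec.ob is None:
                rec.ob = ob
            if rec.dl is None:
                rec.dl = dl
        else:
            records[name] = IngredientRecord(
                ingredient_id=name, herbs={herb}, ob=ob, dl=dl, source=source_tag
            )
    return list(records.values())


def write_ingredient_table(records: Iterable[IngredientRecord], path) -> None:
    rows = [
        {
            "ingredient": r.ingredient_id,
            "herbs": ",".join(sorted(r.herbs)),
            "ob": "" if r.ob is None else f"{r.ob:g}",
            "dl": "" if r.dl is None else f"{r.dl:g}",
            "source": r.source,
        }
        for r in sorted(records, key=lambda r: r.ingredient_id)
    ]
    pd.DataFrame(rows, columns=["ingredient", "herbs", "ob", "dl", "source"]).to_csv(
        path, sep="\t", index=False
    )


def read_association_table(path, evidence: str | None = None) -> list[TargetAssociation]:
    """Load ingredient→gene associations.

    Requires columns ``ingredient``, ``gene``; optional ``evidence``
    (defaulted from the ``evidence`` argument), ``similarity`` and
    ``prediction_score`` for predicted associations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("ingredient", "gene"), path)
    has_evidence = "evidence" in df.columns
    if not has_evidence and evidence is None:
        raise FormatError(f"{path}: no evidence column and no default evidence given")

    out: list[TargetAssociation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        ev = (row.evidence.strip() if has_evidence else "") or evidence
        if not ev:
            raise FormatError(f"{path}, line {line}: missing evidence class")
        sim = _parse_float(getattr(row, "similarity", ""), "similarity", line, path)
        score = _parse_float(
            getattr(row, "prediction_score", ""), "prediction_score", line, path
        )
        out.append(
            TargetAssociation(
                ingredient_id=canonical_name(row.ingredient),
                gene=canonical_symbol(row.gene),
                evidence=ev,
                similarity=sim if ev == "predicted" else None,
                prediction_score=score if ev == "predicted" else None,
            )
        )
    return out


def write_association_table(assocs: Iterable[TargetAssociation], path) -> None:
    rows = [
        {
            "ingredient": a.ingredient_id,
            "gene": a.gene,
            "evidence": a.evidence,
            "similarity": "" if a.similarity is None else f"{a.similarity:g}",
            "prediction_score": ""
            if a.prediction_score is None
            else f"{a.prediction_score:g}",
        }
        for a in sorted(assocs, key=lambda a: (a.ingredient_id, a.gene, a.evidence))
    ]
    pd.DataFrame(
        rows, columns=["ingredient", "gene", "evidence", "similarity", "prediction_score"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    genes: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            genes.add(canonical_symbol(line))
    return genes


def read_expression(matrix_path, groups_path) -> ExpressionMatrix:
    """Load a genes × samples log2-intensity TSV plus a sample→group TSV.

    The matrix's first column holds gene symbols; remaining columns are
    samples.  The groups file has columns ``sample`` and ``group`` with
    values ``case``/``control``.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", dtype=str)
    _require_columns(groups, ("sample", "group"), groups_path)
    group = dict(zip(groups["sample"], groups["group"]))
    genes = [canonical_symbol(g) for g in mat.index]
    return ExpressionMatrix(
        genes=genes, samples=list(mat.columns), group=group, values=mat.to_numpy()
    )


def write_expression(m: ExpressionMatrix, matrix_path, groups_path) -> None:
    df = pd.DataFrame(m.values, index=pd.Index(m.genes, name="gene"), columns=m.samples)
    df.to_csv(matrix_path, sep="\t", float_format="%.6f")
    pd.DataFrame(
        {"sample": m.samples, "group": [m.group[s] for s in m.samples]}
    ).to_csv(groups_path, sep="\t", index=False)


def read_edge_table(path, scores_0_999: bool = False) -> list[ScoredEdge]:
    """Load a scored protein–protein edge TSV (columns ``a``, ``b``, ``score``).

    With ``scores_0_999`` the score column is in the 0–999 integer dialect
    used by STITCH/STRING exports and is divided by 1000 at load.  Duplicate
    edges (after canonical ordering) keep the highest score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("a", "b", "score"), path)
    best: dict[tuple[str, str], ScoredEdge] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        score = _parse_float(row.score, "score", i + 2, path)
        if score is None:
            raise FormatError(f"{path}, line {i + 2}: empty score")
        if scores_0_999:
            score /= 1000.0
        edge = ScoredEdge(canonical_symbol(row.a), canonical_symbol(row.b), score)
        prev = best.get(edge.pair)
        if prev is None or edge.score > prev.score:
            best[edge.pair] = edge
    return sorted(best.values())


def write_edge_table(edges: Iterable[ScoredEdge], path) -> None:
    rows = [{"a": e.a, "b": e.b, "score": f"{e.score:.4f}"} for e in sorted(edges)]
    pd.DataFrame(rows, columns=["a", "b", "score"]).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: ``term_id TAB description TAB gene1 TAB gene2 ...``.

    The description field may carry a ``category|name`` prefix written by
    :func:`write_gmt`; otherwise the category defaults to ``kegg``.  Genes
    are upper-cased and deduplicated per term.
    """
    collection = GeneSetCollection()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}, line {lineno}: GMT line needs >= 3 tab-separated fields"
            )
        term_id, desc = fields[0], fields[1]
        if "|" in desc:
            category, name = desc.split("|", 1)
        else:
            category, name = "kegg", desc
        genes = {canonical_symbol(g) for g in fields[2:] if g.strip()}
        collection.add(term_id, GeneSet(name=name, category=category, genes=genes))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(collection.terms):
            term = collection[term_id]
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term_id}\t{term.category}|{term.name}\t{genes}\n")


def write_network(
    net: TripartiteNetwork,
    degrees: Mapping[str, int],
    path,
    format: str,
    key_nodes: Iterable[str] = (),
) -> None:
    """Export the tripartite network for downstream graph tools.

    ``sif`` writes one ``A pp B`` line per edge; ``graphml`` carries the
    node attributes ``layer``, ``degree`` and ``is_key``; ``node_table`` is
    a TSV of (id, layer, degree, is_key).
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )
    key = set(key_nodes)
    if format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(net.edges):
                fh.write(f"{a}\tpp\t{b}\n")
    elif format == "graphml":
        import networkx as nx

        g = net.to_networkx()
        for node in g.nodes:
            g.nodes[node]["degree"] = int(degrees.get(node, 0))
            g.nodes[node]["is_key"] = node in key
        nx.write_graphml(g, path)
    else:  # node_table
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", "layer", "degree", "is_key"])
            for node in sorted(net.nodes):
                writer.writerow(
                    [node, net.nodes[node], int(degrees.get(node, 0)), node in key]
                )


def read_network(path, format: str) -> TripartiteNetwork:
    """Inverse of :func:`write_network` for the graph-bearing formats.

    ``sif`` has no layer information, so all nodes load as ``protein``;
    ``graphml`` round-trips layers exactly.  ``node_table`` carries no
    edges and is not readable back into a network.
    """
    if format == "graphml":
        import networkx as nx

        g = nx.read_graphml(path)
        net = TripartiteNetwork()
        for node, data in g.nodes(data=True):
            net.add_node(node, data.get("layer", "protein"))
        for a, b in g.edges():
            net.add_edge(a, b)
        return net
    if format == "sif":
        net = TripartiteNetwork()
        for raw in Path(path).read_text().splitlines():
            if not raw.strip():
                continue
            fields = raw.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}: malformed SIF line {raw!r}")
            a, _, b = fields
            for node in (a, b):
                if node not in net.nodes:
                    net.add_node(node, "protein")
            net.add_edge(a, b)
        return net
    raise ValueError(f"cannot read network from format {format!r}")
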