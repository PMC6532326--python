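"""Shared domain types for the herb–ingredient–target–disease inference chain.

The pipeline moves through a fixed sequence of typed containers: screened
herbal ingredients (:class:`IngredientRecord`), ingredient→gene associations
(:class:`TargetAssociation`), a two-group expression matrix
(:class:`ExpressionMatrix`), a provenance-tagged disease-gene set
(:class:`DiseaseGeneSet`), scored protein interactions (:class:`ScoredEdge`),
the tripartite ingredient–target–protein network
(:class:`TripartiteNetwork`) and annotation gene sets
(:class:`GeneSetCollection`).  Every container validates its own invariants
at construction so downstream stages can assume well-formed input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "FormatError",
    "ValidationError",
    "canonical_name",
    "canonical_symbol",
    "IngredientRecord",
    "TargetAssociation",
    "ExpressionMatrix",
    "DiseaseGeneSet",
    "ScoredEdge",
    "TripartiteNetwork",
    "GeneSet",
    "GeneSetCollection",
    "CURATED_SOURCES",
    "LAYERS",
]

#: Recognized curated disease-gene sources; "deg" marks expression-derived genes.
CURATED_SOURCES = ("ttd", "drugbank", "kegg", "disgenet", "omim")

#: Node layers of the tripartite network.
LAYERS = ("ingredient", "candidate_target", "protein")

_WS = re.compile(r"\s+")


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """A record or container violates a domain invariant."""


def canonical_name(name: str) -> str:
    """Canonicalize an ingredient name: trim, lower-case, collapse whitespace.

    Idempotent: ``canonical_name(canonical_name(x)) == canonical_name(x)``.
    """
    return _WS.sub(" ", name.strip()).lower()


def canonical_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol: trim and upper-case (HGNC convention)."""
    return symbol.strip().upper()


@dataclass
class IngredientRecord:
    """One herbal compound with its herb membership and ADME scores.

    ``ob`` is oral bioavailability in percent (30 means 30%); ``dl`` is the
    unitless drug-likeness score in [0, 1].  Either may be null for sources
    that do not report ADME values (curated bioactivity databases).
    """

    ingredient_id: str
    herbs: set[str]
    ob: float | None = None
    dl: float | None = None
    source: str = "tcmsp"

    def __post_init__(self) -> None:
        if not self.ingredient_id:
            raise ValidationError("ingredient_id must be nonempty")
        if not self.herbs:
            raise ValidationError(
                f"ingredient {self.ingredient_id!r}: herbs must be nonempty"
            )
        self.herbs = set(self.herbs)
        if self.ob is not None and self.ob < 0:
            raise ValidationError(
                f"ingredient {self.ingredient_id!r}: ob must be >= 0, got {self.ob}"
            )
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValidationError(
                f"ingredient {self.ingredient_id!r}: dl must be in [0,1], got {self.dl}"
            )
        if self.source not in ("tcmsp", "hit", "both"):
            raise ValidationError(f"unknown source {self.source!r}")


@dataclass
class TargetAssociation:
    """An ingredient→gene link with its evidence class.

    Validated associations are literature-curated; predicted ones come from
    3D-structure similarity searches and carry the search's similarity and
    prediction scores (null for validated associations).
    """

    ingredient_id: str
    gene: str
    evidence: str
    similarity: float | None = None
    prediction_score: float | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene must be nonempty")
        if self.evidence not in ("validated", "predicted"):
            raise ValidationError(f"unknown evidence class {self.evidence!r}")
        if self.evidence == "validated" and (
            self.similarity is not None or self.prediction_score is not None
        ):
            raise ValidationError(
                f"validated association ({self.ingredient_id!r}, {self.gene!r}) "
                "must not carry similarity/prediction scores"
            )
        if self.similarity is not None and self.similarity < 0:
            raise ValidationError(
                f"association ({self.ingredient_id!r}, {self.gene!r}): "
                f"similarity must be >= 0, got {self.similarity}"
            )


class ExpressionMatrix:
    """A genes × samples matrix of log2 intensities with a two-group design.

    Parameters
    ----------
    genes, samples
        Ordered unique identifiers for rows and columns.
    group
        Per-sample label, each ``"case"`` or ``"control"``; at least two
        samples per group.
    values
        2-D array-like of log2 intensities, no missing values.
    """

    def __init__(
        self,
        genes: Iterable[str],
        samples: Iterable[str],
        group: Mapping[str, str],
        values,
    ) -> None:
        import numpy as np

        self.genes = list(genes)
        self.samples = list(samples)
        self.group = dict(group)
        self.values = np.asarray(values, dtype=float)

        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("sample ids must be unique")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.isnan(self.values).any():
            raise ValidationError("expression matrix contains missing values")
        missing = [s for s in self.samples if s not in self.group]
        if missing:
            raise ValidationError(f"samples without group label: {missing}")
        bad = {s: g for s, g in self.group.items() if g not in ("case", "control")}
        if bad:
            raise ValidationError(f"group labels must be case/control, got {bad}")
        for label in ("case", "control"):
            n = sum(1 for s in self.samples if self.group[s] == label)
            if n < 2:
                raise ValidationError(f"group {label!r} has {n} samples, need >= 2")

    def group_columns(self, label: str) -> list[int]:
        """Column indices of the samples belonging to ``label``."""
        return [i for i, s in enumerate(self.samples) if self.group[s] == label]


@dataclass
class DiseaseGeneSet:
    """Merged disease genes, each tagged with every source that reported it."""

    genes: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != self.genes:
            raise ValidationError("provenance keys must equal the gene set")
        empty = [g for g, tags in self.provenance.items() if not tags]
        if empty:
            raise ValidationError(f"genes without any source tag: {sorted(empty)}")


@dataclass(frozen=True, order=True)
class ScoredEdge:
    """An undirected protein interaction with a confidence score in [0, 1].

    Endpoints are stored in canonical (sorted) order so edge sets are
    insensitive to the orientation in which edges were read.
    """

    a: str
    b: str
    score: float

    def __init__(self, a: str, b: str, score: float) -> None:
        if a == b:
            raise ValidationError(f"self-loop edge on {a!r}")
        score = float(score)
        if not (0.0 <= score <= 1.0):
            raise ValidationError(
                f"edge ({a!r}, {b!r}): score must be in [0,1], got {score}"
            )
        if b < a:
            a, b = b, a
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "score", score)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


class TripartiteNetwork:
    """Typed undirected network over ingredients, candidate targets and proteins.

    Nodes carry a layer label; edges are unordered pairs with no self-loops
    or duplicates.  Conversion to :mod:`networkx` is provided for export and
    graph statistics.
    """

    def __init__(
        self,
        nodes: Mapping[str, str] | None = None,
        edges: Iterable[tuple[str, str]] | None = None,
    ) -> None:
        self.nodes: dict[str, str] = {}
        self.edges: set[tuple[str, str]] = set()
        if nodes:
            for node, layer in nodes.items():
                self.add_node(node, layer)
        if edges:
            for a, b in edges:
                self.add_edge(a, b)

    def add_node(self, node: str, layer: str) -> None:
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer {layer!r} for node {node!r}")
        existing = self.nodes.get(node)
        if existing is not None and existing != layer:
            raise ValidationError(
                f"node {node!r} already registered in layer {existing!r}"
            )
        self.nodes[node] = layer

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValidationError(f"self-loop on {a!r}")
        for endpoint in (a, b):
            if endpoint not in self.nodes:
                raise ValidationError(f"edge endpoint {endpoint!r} not a known node")
        self.edges.add((a, b) if a < b else (b, a))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for node, layer in self.nodes.items():
            g.add_node(node, layer=layer)
        g.add_edges_from(self.edges)
        return g


@dataclass
class GeneSet:
    """One annotation term: a named gene set in a category."""

    name: str
    category: str
    genes: set[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"term {self.name!r}: gene set must be nonempty")


class GeneSetCollection:
    """Container for annotation terms keyed by unique term id."""

    def __init__(self, terms: Mapping[str, GeneSet] | None = None) -> None:
        self.terms: dict[str, GeneSet] = dict(terms) if terms else {}

    def add(self, term_id: str, term: GeneSet) -> None:
        if term_id in self.terms:
            raise ValidationError(f"duplicate term id {term_id!r}")
        self.terms[term_id] = term

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.terms[term_id]

    def by_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection(
            {tid: t for tid, t in self.terms.items() if t.category == category}
        )
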