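"""Tripartite network construction and degree-centrality hub selection.

The "active ingredients – candidate targets – proteins" network links each
ingredient to the candidate targets it hits and overlays the kept
high-confidence PPI edges.  Key (hub) nodes are those whose degree
strictly exceeds twice the network-wide mean degree — the standard
degree-centrality rule used with Cytoscape's NetworkAnalyzer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .candidates import CandidateSet
from .datatypes import TripartiteNetwork, ValidationError
from .targets import Compendium


@dataclass
class NetworkStats:
    """Degree summary of a simple undirected network.

    ``mean_degree`` is ``2 * n_edges / n_nodes`` (the handshake identity
    for simple graphs); ``key_threshold`` is exactly twice that.
    """

    n_nodes: int
    n_edges: int
    mean_degree: float
    key_threshold: float
    degrees: dict[str, int]


def build_network(cands: CandidateSet, c: Compendium) -> TripartiteNetwork:
    """Assemble the tripartite network.

    Nodes: every ingredient with at least one candidate target (ingredients
    hitting none would be isolated and would only depress the mean degree),
    all candidates, and all interactors.  Edges: one (ingredient, candidate)
    edge per association whose gene is a candidate, plus the kept PPI
    edges.  Simple undirected graph — duplicates collapse, no self-loops.
    """
    net = TripartiteNetwork()
    for gene in cands.candidates:
        net.add_node(gene, "candidate_target")
    for protein in cands.interactors:
        net.add_node(protein, "protein")

    ingredient_edges = [
        (ing, gene)
        for (ing, gene, _ev) in c.associations
        if gene in cands.candidates
    ]
    for ing, _gene in ingredient_edges:
        if ing not in net.nodes:
            net.add_node(ing, "ingredient")
    for ing, gene in ingredient_edges:
        net.add_edge(ing, gene)
    for e in cands.kept_edges:
        if e.a not in net.nodes or e.b not in net.nodes:
            raise ValidationError(
                f"kept PPI edge ({e.a!r}, {e.b!r}) references a node outside "
                "candidates ∪ interactors"
            )
        net.add_edge(e.a, e.b)
    return net


def network_stats(net: TripartiteNetwork) -> NetworkStats:
    """Per-node degrees, mean degree and the 2x-mean key threshold."""
    if net.n_nodes < 1:
        raise ValidationError("network has no nodes")
    degrees = dict.fromkeys(net.nodes, 0)
    for a, b in net.edges:
        degrees[a] += 1
        degrees[b] += 1
    mean_degree = sum(degrees.values()) / net.n_nodes
    return NetworkStats(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        mean_degree=mean_degree,
        key_threshold=2.0 * mean_degree,
        degrees=degrees,
    )


def select_key_nodes(
    net: TripartiteNetwork, stats: NetworkStats
) -> tuple[list[str], list[str], list[str]]:
    """Hub nodes per layer: degree strictly greater than twice the mean.

    Returns (key_ingredients, key_candidate_targets, key_proteins), each
    sorted by degree descending with lexicographic tie-break.  A pooled
    "key targets" view (candidates + proteins together) is available via
    :func:`pooled_key_targets`, since reported hub-target lists typically
    mix candidate targets and interacting proteins.
    """
    selected = [n for n, d in stats.degrees.items() if d > stats.key_threshold]
    selected.sort(key=lambda n: (-stats.degrees[n], n))
    by_layer: dict[str, list[str]] = {
        "ingredient": [],
        "candidate_target": [],
        "protein": [],
    }
    for node in selected:
        by_layer[net.nodes[node]].append(node)
    return by_layer["ingredient"], by_layer["candidate_target"], by_layer["protein"]


def pooled_key_targets(
    key_targets: list[str], key_proteins: list[str], stats: NetworkStats
) -> list[str]:
    """Candidate targets and interacting proteins pooled into one hub list."""
    pooled = list(key_targets) + list(key_proteins)
    pooled.sort(key=lambda n: (-stats.degrees[n], n))
    return pooled
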