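"""GO-function overlap network (GOFN) construction and topology.

Two GO functions are linked when their gene sets share more genes than
hypergeometric chance in the whole-genome universe would predict, at
FDR < 0.05 across all tested pairs.  Every significant term is a node even
when isolated, so node count equals the significant-term count.  Edges
record the shared genes and, separately, the shared genes that are also
disease risk genes — the basis for dissecting how a hub term connects to
its neighbourhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .enrichment import (
    EnrichmentRecord,
    HypergeomInputs,
    bh_fdr,
    hypergeometric_enrichment_p,
)
from .errors import InputError, LookupError_, UsageError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "TermNetwork",
    "pairwise_term_test",
    "build_gofn",
    "node_degree",
    "node_betweenness",
    "dissect_term",
]


@dataclass
class TermNetwork:
    """An FDR-thresholded term-overlap network over an undirected graph.

    Node attributes: name, enrichment p/q.  Edge attributes: overlap x,
    pairwise p/q, shared_genes, shared_risk_genes.
    """

    graph: nx.Graph
    fdr: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def pairwise_term_test(
    term_a: set[str], term_b: set[str], M: int
) -> tuple[int, float]:
    """Overlap test between two gene sets in a universe of size ``M``.

    Symmetric in its arguments: x = |A ∩ B|, upper-tail hypergeometric p
    with K = |A|, N = |B|.
    """
    if not term_a or not term_b:
        raise InputError("pairwise term test requires non-empty gene sets")
    if len(term_a) > M or len(term_b) > M:
        raise InputError("gene set larger than the universe")
    x = len(term_a & term_b)
    p = hypergeometric_enrichment_p(
        HypergeomInputs(x=x, M=M, K=len(term_a), N=len(term_b))
    )
    return x, p


def build_gofn(
    terms: list[EnrichmentRecord],
    annotation: GeneSetCollection,
    universe: set[str],
    fdr: float = 0.05,
    risk_genes: set[str] | None = None,
) -> TermNetwork:
    """Construct the term-overlap network from significant enrichment records.

    All C(n,2) unordered term pairs are tested once in the full universe;
    BH runs across all tested pairs; edges keep q < ``fdr``.  Isolated
    significant terms remain as nodes.
    """
    risk_genes = risk_genes or set()
    if len(terms) < 2:
        logger.warning("fewer than 2 terms; the network has no testable pairs")
    M = len(universe)
    graph = nx.Graph()
    for rec in terms:
        graph.add_node(rec.term, name=rec.name, p=rec.p, q=rec.q, kind="term")

    gene_sets = {
        rec.term: annotation[rec.term].genes & universe
        for rec in terms
        if rec.term in annotation
    }
    missing = [rec.term for rec in terms if rec.term not in annotation]
    if missing:
        logger.warning("%d significant terms missing from annotation", len(missing))

    pairs = [
        (a, b)
        for a, b in combinations(sorted(gene_sets), 2)
        if gene_sets[a] and gene_sets[b]
    ]
    if not pairs:
        return TermNetwork(graph=graph, fdr=fdr)

    results = []
    for a, b in pairs:
        x, p = pairwise_term_test(gene_sets[a], gene_sets[b], M)
        results.append((a, b, x, p))
    qvals = bh_fdr([r[3] for r in results])
    for (a, b, x, p), q in zip(results, qvals):
        if q < fdr:
            shared = frozenset(gene_sets[a] & gene_sets[b])
            graph.add_edge(
                a, b,
                x=x, p=p, q=float(q),
                shared_genes=shared,
                shared_risk_genes=frozenset(shared & risk_genes),
            )
    return TermNetwork(graph=graph, fdr=fdr)


def _as_graph(network) -> nx.Graph:
    return network if isinstance(network, nx.Graph) else network.graph


def node_degree(network) -> pd.Series:
    """Incident-edge count per node, sorted by node id."""
    graph = _as_graph(network)
    degrees = dict(graph.degree())
    return pd.Series(degrees, name="degree").sort_index().astype(int)


def node_betweenness(network, mode: str = "fractional") -> pd.Series:
    """Unnormalized shortest-path betweenness per node.

    ``fractional`` (default) is the standard definition
    sum_{s<t} sigma_st(v)/sigma_st — what igraph and Cytoscape's
    NetworkAnalyzer compute.  ``raw-counts`` sums the raw number of
    shortest s-t paths through v instead (the literal "sum of the numbers
    of the shortest paths" reading).  Disconnected pairs contribute 0.
    """
    graph = _as_graph(network)
    if mode == "fractional":
        bc = nx.betweenness_centrality(graph, normalized=False)
    elif mode == "raw-counts":
        bc = _raw_count_betweenness(graph)
    else:
        raise UsageError(f"unknown betweenness mode {mode!r}")
    return pd.Series(bc, name="betweenness").sort_index().astype(float)


def _raw_count_betweenness(graph: nx.Graph) -> dict:
    counts = {v: 0.0 for v in graph}
    nodes = sorted(graph.nodes, key=str)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if not nx.has_path(graph, s, t):
                continue
            for path in nx.all_shortest_paths(graph, s, t):
                for v in path[1:-1]:
                    counts[v] += 1.0
    return counts


@dataclass
class TermDissection:
    """Ego view of one hub term: neighbours split by risk-gene-carried edges."""

    focus: str
    subnetwork: nx.Graph
    neighbors_via_risk: list[str]
    neighbors_without_risk: list[str]
    risk_genes_on_edges: frozenset[str]


def dissect_term(network: TermNetwork, focus: str) -> TermDissection:
    """Extract the ego sub-network of ``focus`` and partition its neighbours.

    Neighbours whose connecting edge carries at least one shared risk gene
    go to ``neighbors_via_risk``; the union of those risk genes is
    reported.
    """
    graph = network.graph
    if focus not in graph:
        raise LookupError_(f"term {focus!r} not in the network")
    neighbors = sorted(graph.neighbors(focus))
    sub = graph.subgraph([focus, *neighbors]).copy()
    via_risk, without = [], []
    risk_union: set[str] = set()
    for nbr in neighbors:
        shared_risk = graph.edges[focus, nbr].get("shared_risk_genes", frozenset())
        if shared_risk:
            via_risk.append(nbr)
            risk_union |= set(shared_risk)
        else:
            without.append(nbr)
    return TermDissection(
        focus=focus,
        subnetwork=sub,
        neighbors_via_risk=via_risk,
        neighbors_without_risk=without,
        risk_genes_on_edges=frozenset(risk_union),
    )
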