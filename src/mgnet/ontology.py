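"""GO DAG parsing and term-level computation.

The annotation filter used throughout the pipeline keeps only terms at a
fixed depth ("GO level") of the is_a DAG.  "Level" is the number of is_a
edges on the *shortest* path from the namespace root (root = level 0),
the commonest convention among GO-level tools; a longest-path mode is
available because the convention is not universal.  Only ``is_a`` edges
are considered — ``part_of`` and other relations are a documented
limitation, and obsolete terms are dropped at parse time.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

from .errors import DataError, LookupError_
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["OntologyGraph", "parse_obo", "term_level", "filter_terms_by_level"]


@dataclass
class OntologyGraph:
    """An is_a-only ontology DAG.

    ``parents`` maps each term to its is_a parents; ``roots`` holds the
    per-namespace root term (a term with no is_a parents).
    """

    terms: set[str]
    parents: dict[str, set[str]]
    roots: dict[str, str]
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    _levels_shortest: dict[str, int] = field(default_factory=dict, repr=False)
    _levels_longest: dict[str, int] = field(default_factory=dict, repr=False)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def children_map(self) -> dict[str, set[str]]:
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for term, parents in self.parents.items():
            for p in parents:
                children[p].add(term)
        return children

    def _compute_levels(self, mode: str) -> dict[str, int]:
        """Per-term level by BFS (shortest) or DAG relaxation (longest)."""
        cache = self._levels_shortest if mode == "shortest" else self._levels_longest
        if cache:
            return cache
        children = self.children_map()
        levels: dict[str, int] = {}
        if mode == "shortest":
            queue = deque()
            for root in self.roots.values():
                levels[root] = 0
                queue.append(root)
            while queue:
                node = queue.popleft()
                for child in children[node]:
                    if child not in levels:
                        levels[child] = levels[node] + 1
                        queue.append(child)
        else:
            order = self._topological_order()
            for term in order:
                if not self.parents.get(term):
                    levels[term] = 0
                else:
                    levels[term] = 1 + max(
                        levels[p] for p in self.parents[term] if p in levels
                    )
        cache.update(levels)
        return cache

    def _topological_order(self) -> list[str]:
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for term, parents in self.parents.items():
            for p in parents:
                graph.add_edge(p, term)
        return list(nx.topological_sort(graph))


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 file, keeping only is_a edges and live terms.

    Raises :class:`DataError` with one offending cycle if the is_a graph
    is cyclic.
    """
    # obonet drops is_obsolete terms by default and edges point child->parent
    net = obonet.read_obo(str(path))
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for term, data in net.nodes(data=True):
        terms.add(term)
        names[term] = data.get("name", term)
        namespaces[term] = data.get("namespace", "biological_process")
        parents[term] = set()
    for child, parent, key in net.edges(keys=True):
        if key == "is_a" and parent in terms:
            parents[child].add(parent)

    dag = nx.DiGraph()
    dag.add_nodes_from(terms)
    for child, ps in parents.items():
        for p in ps:
            dag.add_edge(p, child)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise DataError(f"is_a cycle detected: {' -> '.join(str(e[0]) for e in cycle)}")

    roots: dict[str, str] = {}
    for term in sorted(terms):
        if not parents[term]:
            ns = namespaces[term]
            if ns in roots:
                logger.warning(
                    "namespace %s has multiple roots (%s, %s); keeping the first",
                    ns, roots[ns], term,
                )
            else:
                roots[ns] = term
    return OntologyGraph(
        terms=terms, parents=parents, roots=roots, names=names, namespaces=namespaces
    )


def term_level(
    ontology: OntologyGraph, term: str, mode: str = "shortest"
) -> int:
    """Depth of ``term`` below its namespace root (root = 0).

    ``mode="shortest"`` (default) counts the minimum number of is_a edges
    from the root; ``mode="longest"`` the maximum over root paths.
    """
    if term not in ontology:
        raise LookupError_(f"unknown term {term!r}")
    levels = ontology._compute_levels(mode)
    if term not in levels:
        raise LookupError_(f"term {term!r} does not reach a namespace root")
    return levels[term]


def filter_terms_by_level(
    annotation: GeneSetCollection,
    ontology: OntologyGraph,
    level: int,
    mode: str = "shortest",
    namespace: str | None = "biological_process",
) -> GeneSetCollection:
    """Keep only annotation sets whose term sits at the requested level.

    Set ids absent from the ontology are dropped with a warning; terms of
    namespaces other than ``namespace`` (biological_process by default)
    are dropped as well.  Pass ``namespace=None`` to keep all namespaces.
    """
    kept = []
    for entry in annotation:
        if entry.set_id not in ontology:
            logger.warning("annotation term %s not in ontology; dropped", entry.set_id)
            continue
        if namespace is not None and ontology.namespaces.get(entry.set_id) != namespace:
            continue
        if term_level(ontology, entry.set_id, mode=mode) == level:
            kept.append(entry)
    return GeneSetCollection(kept)
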