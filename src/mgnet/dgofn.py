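"""Bipartite drug-GO-function network (DGOFN) in the risk-gene universe.

Drugs enter only if at least ``min_targets`` of their targets are disease
risk genes, and they keep only those risk-gene targets.  Each surviving
drug is tested against each disease-significant term with the
hypergeometric universe set to the risk-gene catalog itself:
M = |risk genes|, K = |term ∩ risk genes|, N = |drug targets|,
x = |targets ∩ term|.  Restricting K to risk genes is the only reading
under which K cannot exceed M.  Edges keep BH q < FDR across all tested
pairs; drugs and terms left with no edge are dropped from the network but
reported separately.

The degree distribution of the resulting network is summarized by an
ordinary least-squares power-law fit on log-log binned counts,
f(k) = a * k^b.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import (
    EnrichmentRecord,
    HypergeomInputs,
    bh_fdr,
    hypergeometric_enrichment_p,
)
from .errors import FitError, UsageError
from .io_formats import DrugTargetTable, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNetwork",
    "DegreeHistogram",
    "PowerLawFit",
    "filter_drugs",
    "drug_term_test",
    "build_dgofn",
    "degree_histogram",
    "fit_power_law",
]


@dataclass
class BipartiteNetwork:
    """FDR-thresholded drug-term network; zero-degree entities excluded.

    ``dropped_drugs`` / ``dropped_terms`` record entities that were tested
    but kept no significant edge.
    """

    graph: nx.Graph
    fdr: float
    dropped_drugs: list[str]
    dropped_terms: list[str]

    @property
    def drugs(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "drug"
        )

    @property
    def terms(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == "term"
        )

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_drugs(
    table: DrugTargetTable, risk_genes: set[str], min_targets: int = 3
) -> DrugTargetTable:
    """Restrict each drug to risk-gene targets; drop sparsely-targeting drugs.

    A drug survives only if it hits at least ``min_targets`` risk genes,
    and its surviving rows are exactly those risk-gene targets.
    Idempotent.
    """
    rows = table.rows
    kept = rows[rows["target"].isin(risk_genes)]
    counts = kept.groupby("drug_id")["target"].nunique()
    surviving = set(counts[counts >= min_targets].index)
    out = kept[kept["drug_id"].isin(surviving)].reset_index(drop=True)
    return DrugTargetTable(out)


def drug_term_test(
    drug_targets: set[str], term_genes: set[str], risk_genes: set[str]
) -> tuple[int, float] | None:
    """Overlap test of one drug's (risk-gene) targets with one term.

    Returns ``None`` when the term has no risk genes (K = 0, nothing to
    test).  The universe is the risk-gene catalog.
    """
    if not drug_targets <= risk_genes:
        raise AssertionError("drug targets must be risk genes (run filter_drugs)")
    M = len(risk_genes)
    K = len(term_genes & risk_genes)
    N = len(drug_targets)
    if K == 0:
        return None
    assert N <= M and K <= M
    x = len(drug_targets & term_genes)
    p = hypergeometric_enrichment_p(HypergeomInputs(x=x, M=M, K=K, N=N))
    return x, p


def build_dgofn(
    drugs: DrugTargetTable,
    terms: list[EnrichmentRecord],
    annotation: GeneSetCollection,
    risk_genes: set[str],
    fdr: float = 0.05,
) -> BipartiteNetwork:
    """Test every (drug, term) pair with K >= 1; keep edges at BH q < fdr."""
    by_drug = drugs.by_drug()
    if not by_drug or not terms:
        logger.warning("no drugs or no terms; the drug-term network is empty")
    term_genes = {
        rec.term: annotation[rec.term].genes for rec in terms if rec.term in annotation
    }

    tested: list[tuple[str, str, int, float]] = []
    for drug_id in sorted(by_drug):
        targets = by_drug[drug_id]
        for term in sorted(term_genes):
            result = drug_term_test(targets, term_genes[term], risk_genes)
            if result is None:
                continue
            x, p = result
            tested.append((drug_id, term, x, p))

    graph = nx.Graph()
    edge_drugs: set[str] = set()
    edge_terms: set[str] = set()
    if tested:
        qvals = bh_fdr([t[3] for t in tested])
        for (drug_id, term, x, p), q in zip(tested, qvals):
            if q < fdr:
                if drug_id not in graph:
                    graph.add_node(drug_id, kind="drug", name=drugs.name_of(drug_id))
                if term not in graph:
                    graph.add_node(term, kind="term")
                shared = frozenset(by_drug[drug_id] & term_genes[term])
                graph.add_edge(drug_id, term, x=x, p=p, q=float(q), shared_genes=shared)
                edge_drugs.add(drug_id)
                edge_terms.add(term)
    dropped_drugs = sorted(set(by_drug) - edge_drugs)
    dropped_terms = sorted(set(term_genes) - edge_terms)
    return BipartiteNetwork(
        graph=graph, fdr=fdr, dropped_drugs=dropped_drugs, dropped_terms=dropped_terms
    )


@dataclass
class DegreeHistogram:
    """(degree, node count) pairs with strictly increasing degree >= 1."""

    degrees: np.ndarray
    counts: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.degrees, "count": self.counts})


def degree_histogram(network, node_class: str = "all") -> DegreeHistogram:
    """Node count per degree within a class; degree-0 nodes excluded.

    ``node_class`` is one of ``all``, ``drugs``, ``terms``.
    """
    graph = network if isinstance(network, nx.Graph) else network.graph
    if node_class == "all":
        nodes = list(graph.nodes)
    elif node_class in ("drugs", "terms"):
        kind = node_class[:-1]
        nodes = [n for n, d in graph.nodes(data=True) if d.get("kind") == kind]
    else:
        raise UsageError(f"unknown node class {node_class!r}")
    degrees = [graph.degree(n) for n in nodes if graph.degree(n) >= 1]
    if not degrees:
        return DegreeHistogram(np.array([], dtype=int), np.array([], dtype=int))
    ks, counts = np.unique(degrees, return_counts=True)
    return DegreeHistogram(ks.astype(int), counts.astype(int))


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10(count) on log10(degree): count = a * degree^b."""

    a: float
    b: float
    r2: float


def fit_power_law(hist: DegreeHistogram) -> PowerLawFit:
    """Least-squares line on the log-log degree histogram.

    Requires at least two distinct degrees with positive counts.  Returns
    prefactor a = 10^intercept, exponent b = slope, and the coefficient of
    determination on the log-log scale.
    """
    mask = hist.counts > 0
    k = hist.degrees[mask].astype(float)
    n = hist.counts[mask].astype(float)
    if len(np.unique(k)) < 2:
        raise FitError("power-law fit needs >= 2 distinct degrees with counts")
    lx, ly = np.log10(k), np.log10(n)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(a=float(10 ** intercept), b=float(slope), r2=r2)
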