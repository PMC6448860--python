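"""Cumulative hypergeometric enrichment with Benjamini-Hochberg FDR.

The core question: drawing ``N`` query genes from a universe of ``M`` of
which ``K`` are annotated to a term, how surprising is an overlap of at
least ``x``?  The upper tail

    P(X >= x) = sum_{i=x}^{min(K,N)} C(K,i) C(M-K, N-i) / C(M,N)

is the enrichment p-value used everywhere in the pipeline.  A
``printed-lower`` tail (the cumulative sum from 0 to x) is exposed for
auditability; it measures depletion, and upper(x) + printed-lower(x-1) = 1.

Computation goes through :mod:`scipy.stats.hypergeom` survival/cdf
functions, which work in log-space internally — no overflow for
universes of 1e5 genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import EmptyInputError, InputError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "HypergeomInputs",
    "EnrichmentRecord",
    "hypergeometric_enrichment_p",
    "bh_fdr",
    "enrich_terms",
]


@dataclass(frozen=True)
class HypergeomInputs:
    """One overlap test: x of N query genes fall in a K-gene set, universe M."""

    x: int
    M: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise InputError(f"universe size M={self.M} must be positive")
        if not (0 <= self.K <= self.M):
            raise InputError(f"annotated-set size K={self.K} outside [0, M={self.M}]")
        if not (0 <= self.N <= self.M):
            raise InputError(f"query size N={self.N} outside [0, M={self.M}]")
        lo = max(0, self.K + self.N - self.M)
        hi = min(self.K, self.N)
        if not (lo <= self.x <= hi):
            raise InputError(
                f"overlap x={self.x} outside feasible range [{lo}, {hi}] "
                f"for (M={self.M}, K={self.K}, N={self.N})"
            )


@dataclass(frozen=True)
class EnrichmentRecord:
    """One term's enrichment result: counts, raw p, BH q, overlapping genes."""

    term: str
    name: str
    inputs: HypergeomInputs
    overlap_genes: frozenset[str]
    p: float
    q: float
    significant: bool


def hypergeometric_enrichment_p(inputs: HypergeomInputs, tail: str = "upper") -> float:
    """Cumulative hypergeometric probability for one overlap.

    ``tail="upper"`` returns P(X >= x), the enrichment p-value.
    ``tail="printed-lower"`` returns P(X <= x), the literal cumulative sum
    from zero (a depletion measure), kept for auditing the convention.
    """
    x, M, K, N = inputs.x, inputs.M, inputs.K, inputs.N
    if tail == "upper":
        p = float(hypergeom.sf(x - 1, M, K, N))
    elif tail == "printed-lower":
        p = float(hypergeom.cdf(x, M, K, N))
    else:
        raise InputError(f"unknown tail {tail!r}")
    return min(max(p, 0.0), 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1; ties share a value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_terms(
    query: set[str],
    annotation: GeneSetCollection,
    universe: set[str],
    alpha: float = 0.05,
    min_query_genes: int = 5,
    tail: str = "upper",
) -> list[EnrichmentRecord]:
    """Test every annotated term for over-representation of ``query`` genes.

    Terms overlapping the query by fewer than ``min_query_genes`` genes are
    not tested (mirrors the catalog-construction rule of dropping sparsely
    hit functions).  BH adjustment runs across exactly the tested terms.
    Records are sorted by raw p ascending, ties broken by term id;
    ``significant`` flags raw p < alpha.
    """
    if not universe:
        raise EmptyInputError("empty universe")
    if not query:
        raise EmptyInputError("empty query gene set")
    dropped = query - universe
    if dropped:
        logger.warning(
            "%d query genes outside the universe dropped: %s",
            len(dropped), ", ".join(sorted(dropped)[:5]),
        )
    query_in = query & universe
    if not query_in:
        raise EmptyInputError("no query genes remain inside the universe")
    if tail == "printed-lower":
        logger.warning(
            "tail='printed-lower' is the literal depletion-measuring sum; "
            "enrichment uses the upper tail"
        )

    M = len(universe)
    N = len(query_in)
    tested: list[tuple[str, str, HypergeomInputs, frozenset[str]]] = []
    for entry in annotation:
        term_genes = entry.genes & universe
        overlap = frozenset(term_genes & query_in)
        if len(overlap) < min_query_genes:
            continue
        inputs = HypergeomInputs(x=len(overlap), M=M, K=len(term_genes), N=N)
        tested.append((entry.set_id, entry.name, inputs, overlap))

    if not tested:
        return []
    pvals = np.array(
        [hypergeometric_enrichment_p(t[2], tail=tail) for t in tested]
    )
    qvals = bh_fdr(pvals)
    records = [
        EnrichmentRecord(
            term=term,
            name=name,
            inputs=inputs,
            overlap_genes=overlap,
            p=float(p),
            q=float(q),
            significant=bool(p < alpha),
        )
        for (term, name, inputs, overlap), p, q in zip(tested, pvals, qvals)
    ]
    records.sort(key=lambda r: (r.p, r.term))
    return records
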