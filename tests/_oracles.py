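"""Independent brute-force oracles used by the test suite.

Everything here is deliberately implemented by a different route than the
package: exhaustive subset enumeration and exact integer arithmetic for
hypergeometric tails, a literal step-up for BH, explicit path enumeration
for betweenness, and naive double loops for network construction.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb


def enum_upper_tail(x: int, M: int, K: int, N: int) -> float:
    """P(X >= x) by enumerating every N-subset of an M-universe."""
    marked = set(range(K))
    total = 0
    at_least = 0
    for draw in combinations(range(M), N):
        total += 1
        if len(marked.intersection(draw)) >= x:
            at_least += 1
    return at_least / total


def comb_upper_tail(x: int, M: int, K: int, N: int) -> float:
    """P(X >= x) from the exact pmf with integer binomial coefficients."""
    hi = min(K, N)
    num = sum(comb(K, i) * comb(M - K, N - i) for i in range(x, hi + 1))
    return num / comb(M, N)


def reference_bh(pvalues):
    """Literal BH step-up: sort, p*(m/rank), cumulative min from the end."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, pvalues[idx] * m / rank)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def path_enum_betweenness(edges, nodes):
    """Fractional betweenness by explicit enumeration of shortest paths.

    For every unordered pair (s, t): BFS gives the shortest distance, a
    depth-limited DFS enumerates every path of that length, and each
    interior node v accumulates (paths through v) / (all paths).
    """
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def bfs_dist(src):
        dist = {src: 0}
        queue = deque([src])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist

    def all_paths(src, dst, limit):
        paths = []

        def dfs(node, path):
            if len(path) - 1 > limit:
                return
            if node == dst and len(path) - 1 == limit:
                paths.append(list(path))
                return
            for nxt in adj[node]:
                if nxt not in path:
                    path.append(nxt)
                    dfs(nxt, path)
                    path.pop()

        dfs(src, [src])
        return paths

    scores = {n: 0.0 for n in nodes}
    node_list = sorted(nodes, key=str)
    for i, s in enumerate(node_list):
        dist = bfs_dist(s)
        for t in node_list[i + 1:]:
            if t not in dist:
                continue
            paths = all_paths(s, t, dist[t])
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p[1:-1])
                if through:
                    scores[v] += through / sigma
    return scores


def brute_force_gofn_edges(gene_sets: dict, M: int, fdr: float):
    """Naive double loop + exact-comb p + reference BH; returns edge set."""
    pairs = []
    pvals = []
    ids = sorted(gene_sets)
    for a, b in combinations(ids, 2):
        A, B = gene_sets[a], gene_sets[b]
        x = len(A & B)
        pairs.append((a, b))
        pvals.append(comb_upper_tail(x, M, len(A), len(B)))
    qvals = reference_bh(pvals)
    return {pair for pair, q in zip(pairs, qvals) if q < fdr}


def brute_force_dgofn_edges(drug_targets: dict, term_genes: dict, risk, fdr: float):
    """Naive drug x term loop in the risk-gene universe; returns edge set."""
    risk = set(risk)
    M = len(risk)
    pairs = []
    pvals = []
    for drug in sorted(drug_targets):
        targets = drug_targets[drug]
        for term in sorted(term_genes):
            K = len(term_genes[term] & risk)
            if K == 0:
                continue
            x = len(targets & term_genes[term])
            pairs.append((drug, term))
            pvals.append(comb_upper_tail(x, M, K, len(targets)))
    qvals = reference_bh(pvals)
    return {pair for pair, q in zip(pairs, qvals) if q < fdr}
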