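"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (rank-then-Pearson, exhaustive subset
enumeration, textbook formulas) and shares no code with the implementation
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def spearman_oracle(a, b) -> float:
    """Spearman rho as Pearson correlation of average ranks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(len(x), dtype=float)
        i = 0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = math.sqrt(float(ra @ ra) * float(rb @ rb))
    return float(ra @ rb) / denom if denom else math.nan


def bh_oracle(pvals):
    """Benjamini-Hochberg adjusted p-values by the step-up definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = val
        prev = val
    return adj


def maximal_cliques_oracle(nodes, edges) -> set[frozenset]:
    """All maximal cliques (size >= 2) by exhaustive subset enumeration."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)

    def complete(subset) -> bool:
        return all(b in adj[a] for a, b in itertools.combinations(subset, 2))

    cliques = set()
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if not complete(subset):
                continue
            extendable = any(
                all(n in adj[o] for n in subset) for o in nodes if o not in subset
            )
            if not extendable:
                cliques.add(frozenset(subset))
    return cliques


def two_proportion_z_oracle(x1, n1, x2, n2):
    """Pooled two-proportion z and two-sided normal p, textbook form."""
    from scipy.stats import norm

    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0 or p1 == p2:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(var)
    return z, 2 * norm.sf(abs(z))


def random_split_graph_inputs(rng: np.random.Generator, max_nodes: int = 12):
    """Random mixed graph respecting the split-graph edge classes.

    Returns (taxon labels, module labels, taxon-taxon edges with weights,
    taxon-module edges with weights); never creates a module-module edge.
    """
    n_total = int(rng.integers(2, max_nodes + 1))
    n_modules = int(rng.integers(0, max(1, n_total // 3) + 1))
    n_taxa = n_total - n_modules
    if n_taxa < 2:
        n_taxa, n_modules = 2, n_total - 2
    taxa = [f"t{i}" for i in range(n_taxa)]
    modules = [f"m{i}" for i in range(n_modules)]
    p_edge = float(rng.uniform(0.2, 0.7))
    clique_edges = []
    for a, b in itertools.combinations(taxa, 2):
        if rng.random() < p_edge:
            rho = float(rng.uniform(0.6, 1.0)) * (1 if rng.random() < 0.9 else -1)
            clique_edges.append((a, b, rho))
    cross_edges = []
    for t in taxa:
        for m in modules:
            if rng.random() < p_edge:
                cross_edges.append((t, m, float(rng.uniform(0.6, 1.0))))
    return taxa, modules, clique_edges, cross_edges
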