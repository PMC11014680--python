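"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, direct summation,
numerical quadrature) and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy import integrate, stats


def poisson_upper_tail(observed: int, lam: float, terms: int = 4000) -> float:
    """P(X >= observed) by direct pmf summation (complement for far tails)."""
    if observed == 0:
        return 1.0
    # sum the lower tail and complement: fewer terms, no truncation of the tail
    k = np.arange(0, observed)
    return float(1.0 - np.exp(stats.poisson.logpmf(k, lam)).sum())


def fisher_two_sided_p(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided p by enumerating all tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {
        k: math.comb(col1, k)
        * math.comb(n - col1, row1 - k)
        / math.comb(n, row1)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def bayes_factor_quadrature(
    x: int, lam: float, gamma_mean: float, beta: float
) -> float:
    """Class Bayes factor by numerical integration over the relative risk."""
    shape = gamma_mean * beta

    def integrand(g: float) -> float:
        return stats.poisson.pmf(x, lam * g) * stats.gamma.pdf(g, a=shape, scale=1.0 / beta)

    # the integrand's mass follows the posterior Gamma(shape + x, beta + lam)
    upper = stats.gamma.ppf(1 - 1e-14, a=shape + x, scale=1.0 / (beta + lam))
    num, _ = integrate.quad(integrand, 0.0, upper, limit=800, epsabs=0, epsrel=1e-10)
    return num / stats.poisson.pmf(x, lam)


def bayesian_fdr_bruteforce(bfs: np.ndarray, pi: float) -> np.ndarray:
    """q-values by explicit sort / cumulative mean / tie-block maximisation."""
    post = (1 - pi) / ((1 - pi) + pi * np.asarray(bfs, dtype=float))
    order = np.argsort(-np.asarray(bfs, dtype=float), kind="stable")
    q_sorted = np.cumsum(post[order]) / np.arange(1, len(bfs) + 1)
    # tie blocks on BF share the block's worst q
    sorted_bfs = np.asarray(bfs, dtype=float)[order]
    q_tied = q_sorted.copy()
    i = 0
    while i < len(bfs):
        j = i
        while j + 1 < len(bfs) and sorted_bfs[j + 1] == sorted_bfs[i]:
            j += 1
        q_tied[i : j + 1] = q_sorted[i : j + 1].max()
        i = j + 1
    out = np.empty(len(bfs))
    out[order] = np.minimum(q_tied, 1.0)
    return out


def cross_edges_bruteforce(edges, set_a, set_b) -> int:
    """Edge count between disjointified sets by a double loop."""
    a = set(set_a)
    b = set(set_b) - a
    return sum(1 for u, v in edges if (u in a and v in b) or (v in a and u in b))


def enumerate_connectivity_p(graph_edges, nodes, size_a, set_b, s_obs) -> float:
    """Exact permutation p by enumerating every size-a subset of nodes."""
    total = 0
    hits = 0
    for subset in combinations(nodes, size_a):
        s = cross_edges_bruteforce(graph_edges, subset, set_b)
        total += 1
        if s >= s_obs:
            hits += 1
    return hits / total


def betweenness_bruteforce(graph) -> dict:
    """Unnormalized betweenness by enumerating all shortest paths."""
    import networkx as nx

    out = {v: 0.0 for v in graph.nodes}
    nodes = list(graph.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in graph.nodes:
                if v in (s, t):
                    continue
                frac = sum(1 for p in paths if v in p) / len(paths)
                out[v] += frac
    return out


def stress_bruteforce(graph) -> dict:
    """Stress centrality by counting shortest paths through each node."""
    import networkx as nx

    out = {v: 0.0 for v in graph.nodes}
    nodes = list(graph.nodes)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            try:
                paths = list(nx.all_shortest_paths(graph, s, t))
            except nx.NetworkXNoPath:
                continue
            for v in graph.nodes:
                if v in (s, t):
                    continue
                out[v] += sum(1 for p in paths if v in p)
    return out


def mcc_bruteforce(graph) -> dict:
    """MCC by enumerating all maximal cliques over node subsets (tiny graphs)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    cliques = []
    for size in range(2, n + 1):
        for subset in combinations(nodes, size):
            if all(graph.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques if not any(c < other for other in cliques)
    ]
    out = {v: 0.0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            out[v] += w
    return out


def signed_rank_two_sided_p(diffs: np.ndarray) -> float:
    """Exact Wilcoxon signed-rank two-sided p over all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0), "oracle requires no zero differences"
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    total = n * (n + 1) / 2
    w_obs = ranks[d > 0].sum()
    w_min = min(w_obs, total - w_obs)
    hits = 0
    for signs in product((1.0, -1.0), repeat=n):
        w = ranks[np.array(signs) > 0].sum()
        if w <= w_min + 1e-9 or w >= total - w_min - 1e-9:
            hits += 1
    return hits / 2**n


def mean_rank_consensus(rankings, k):
    """Consensus top-k by explicit mean-rank computation."""
    genes = sorted({g for r in rankings for g in r})
    mean = {
        g: np.mean([(list(r).index(g) + 1) if g in r else len(r) + 1 for r in rankings])
        for g in genes
    }
    return sorted(genes, key=lambda g: (mean[g], g))[:k]
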