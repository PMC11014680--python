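"""Weighted PPI graph construction, connectivity permutation tests, hub ranking.

Graphs follow the STRING convention: an edge list with integer combined
scores in [0, 1000], thresholded at a confidence score strictly above 600 by
default. The connectivity statistic between two gene sets counts edges with
one endpoint in each set (genes shared between the sets are removed from the
second set first). Significance is assessed by redrawing the first set
uniformly from the node universe and recomputing the statistic.

Hub ranking implements six of the centralities used by the CytoHubba
plug-in: degree, closeness, betweenness, stress, eccentricity and maximal
clique centrality (MCC). MCC(v) is the sum over maximal cliques C containing
v (|C| >= 2) of (|C| - 1)!; an isolated node scores 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSet

logger = logging.getLogger(__name__)

#: STRING-style confidence threshold: edges must score strictly above this.
DEFAULT_MIN_SCORE = 600

CENTRALITY_METHODS = ("degree", "closeness", "betweenness", "stress", "eccentricity", "mcc")

#: Whether a larger score means a more central node, per method. Eccentricity
#: is the exception: central nodes have small eccentricity.
HIGHER_IS_CENTRAL = {m: m != "eccentricity" for m in CENTRALITY_METHODS}


@dataclass(frozen=True)
class ConnectivityTestResult:
    observed_links: int
    null_mean: float
    empirical_p: float
    n_perm: int
    seed: int


def build_graph(
    edge_table: pd.DataFrame | str | Path,
    min_score: int = DEFAULT_MIN_SCORE,
) -> nx.Graph:
    """Build a weighted graph from a (GeneA, GeneB, CombinedScore) edge table.

    Edges with score strictly greater than ``min_score`` are retained;
    duplicate pairs keep the maximal score; self-loops are dropped and
    counted. Accepts a frame or a TSV path.
    """
    if not isinstance(edge_table, pd.DataFrame):
        edge_table = pd.read_csv(edge_table, sep="\t")
    for col in ("GeneA", "GeneB", "CombinedScore"):
        if col not in edge_table.columns:
            raise ValueError(f"edge table is missing column {col!r}")
    g = nx.Graph()
    n_self = 0
    for i, (a, b, score) in enumerate(
        edge_table[["GeneA", "GeneB", "CombinedScore"]].itertuples(index=False), start=1
    ):
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise ValueError(f"edge table line {i}: unparseable score {score!r}") from None
        if not 0 <= score <= 1000:
            raise ValueError(f"edge table line {i}: score {score} outside [0, 1000]")
        if a == b:
            n_self += 1
            continue
        if score <= min_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    if n_self:
        logger.info("dropped %d self-loops while building graph", n_self)
    return g


def connectivity_statistic(
    graph: nx.Graph,
    set_a: GeneSet | Iterable[str],
    set_b: GeneSet | Iterable[str],
) -> int:
    """Count graph edges with one endpoint in set_a and the other in set_b.

    Genes shared between the sets are removed from set_b first, so the two
    sets are disjoint when counting. Raises if neither set intersects the
    graph.
    """
    a = set(set_a) & set(graph.nodes)
    b = (set(set_b) - set(set_a)) & set(graph.nodes)
    if not a and not b:
        raise ValueError("both gene sets are disjoint from the graph")
    return sum(1 for u, v in graph.edges if (u in a and v in b) or (v in a and u in b))


def connectivity_permutation_test(
    graph: nx.Graph,
    set_a: GeneSet | Iterable[str],
    set_b: GeneSet | Iterable[str],
    n_perm: int = 1_000_000,
    seed: int | None = None,
    universe: str | Sequence[str] = "graph_nodes",
) -> ConnectivityTestResult:
    """Permutation test for excess connectivity between two gene sets.

    Each permutation redraws set_a uniformly without replacement from the
    universe (default: all graph nodes), keeping its size, and recomputes
    the cross-set edge count with the same shared-gene removal rule as the
    observed statistic. p = (1 + #{S* >= S_obs}) / (n_perm + 1).
    """
    if seed is None:
        raise ValueError("seed is mandatory for the permutation test")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; the empirical p will be unstable", n_perm)
    nodes = list(graph.nodes)
    node_index = {g: i for i, g in enumerate(nodes)}
    if universe == "graph_nodes":
        universe_idx = np.arange(len(nodes))
    else:
        universe_idx = np.array([node_index[g] for g in universe if g in node_index])
    a_in_graph = [g for g in set(set_a) if g in node_index]
    k = len(a_in_graph)
    if k == 0:
        raise ValueError("set_a is disjoint from the graph")
    if k > universe_idx.size:
        raise ValueError("set_a is larger than the permutation universe")
    s_obs = connectivity_statistic(graph, set_a, set_b)

    # vectorized statistic: boolean membership over the edge index arrays
    edges = np.array([(node_index[u], node_index[v]) for u, v in graph.edges])
    u_idx, v_idx = (edges[:, 0], edges[:, 1]) if len(edges) else (np.array([], int),) * 2
    in_b_base = np.zeros(len(nodes), dtype=bool)
    for g in set(set_b):
        if g in node_index:
            in_b_base[node_index[g]] = True

    rng = np.random.default_rng(seed)
    hits = 0
    null_sum = 0.0
    in_a = np.zeros(len(nodes), dtype=bool)
    for _ in range(n_perm):
        draw = rng.choice(universe_idx, size=k, replace=False)
        in_a[:] = False
        in_a[draw] = True
        in_b = in_b_base & ~in_a
        s = int(
            np.count_nonzero(
                (in_a[u_idx] & in_b[v_idx]) | (in_a[v_idx] & in_b[u_idx])
            )
        )
        null_sum += s
        if s >= s_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return ConnectivityTestResult(s_obs, null_sum / n_perm, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def _stress_centrality(graph: nx.Graph) -> dict[str, float]:
    """Stress centrality: number of shortest paths passing through each node.

    Computed from all-pairs BFS distances and shortest-path counts; each
    unordered (s, t) pair contributes sigma_sv * sigma_vt when v lies on a
    shortest s-t path. O(n^2) memory, O(n^3) time — intended for the modest
    graphs hub analysis is run on.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    idx = {g: i for i, g in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        # BFS with path counting (Brandes' forward pass)
        queue = [si]
        while queue:
            nxt = []
            for vi in queue:
                for w in graph.neighbors(nodes[vi]):
                    wi = idx[w]
                    if math.isinf(dist[si, wi]):
                        dist[si, wi] = dist[si, vi] + 1
                        nxt.append(wi)
                    if dist[si, wi] == dist[si, vi] + 1:
                        sigma[si, wi] += sigma[si, vi]
            queue = nxt
    out: dict[str, float] = {}
    for v in nodes:
        vi = idx[v]
        # sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t)
        through = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        contrib = (sigma[:, vi][:, None] * sigma[vi, :][None, :]) * through
        mask = np.ones(n, dtype=bool)
        mask[vi] = False
        sub = contrib[np.ix_(mask, mask)]
        # s == t cells are zero already (through is false off v); halve ordered sum
        out[v] = (sub.sum() - np.trace(sub)) / 2.0
    return out


def _mcc(graph: nx.Graph) -> dict[str, float]:
    """Maximal clique centrality: sum over maximal cliques (size >= 2) of (|C|-1)!."""
    out = {v: 0.0 for v in graph.nodes}
    for clique in nx.find_cliques(graph):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def _eccentricity(graph: nx.Graph) -> dict[str, float]:
    out: dict[str, float] = {}
    for comp in nx.connected_components(graph):
        out.update(nx.eccentricity(graph.subgraph(comp)))
    return out


def centrality_scores(graph: nx.Graph, method: str) -> dict[str, float]:
    """Node centrality scores under one of the supported methods.

    Methods: degree (edge count), closeness (within-component), betweenness
    (unnormalized shortest-path betweenness), stress, eccentricity (raw max
    distance within the component; note smaller = more central, see
    HIGHER_IS_CENTRAL), mcc.
    """
    if method == "degree":
        return {v: float(d) for v, d in graph.degree()}
    if method == "closeness":
        return nx.closeness_centrality(graph, wf_improved=False)
    if method == "betweenness":
        return nx.betweenness_centrality(graph, normalized=False)
    if method == "stress":
        return _stress_centrality(graph)
    if method == "eccentricity":
        return _eccentricity(graph)
    if method == "mcc":
        return _mcc(graph)
    raise ValueError(
        f"unknown centrality method {method!r}; supported: {CENTRALITY_METHODS}"
    )


def rank_by_centrality(graph: nx.Graph, method: str) -> list[str]:
    """Genes ordered most-central first, ties broken lexicographically."""
    scores = centrality_scores(graph, method)
    sign = -1.0 if HIGHER_IS_CENTRAL[method] else 1.0
    return [g for g, _ in sorted(scores.items(), key=lambda kv: (sign * kv[1], kv[0]))]


def consensus_top_k(rankings: Sequence[Sequence[str]], k: int = 10) -> list[str]:
    """Top-k genes by mean rank across rankings; ties lexicographic.

    A gene missing from a ranking is assigned rank len(ranking) + 1.
    """
    if not rankings:
        raise ValueError("at least one ranking is required")
    genes = sorted({g for r in rankings for g in r})
    mean_rank: dict[str, float] = {}
    for g in genes:
        ranks = [
            (list(r).index(g) + 1) if g in r else len(r) + 1 for r in rankings
        ]
        mean_rank[g] = sum(ranks) / len(ranks)
    ordered = sorted(genes, key=lambda g: (mean_rank[g], g))
    return ordered[:k]


def hub_genes(
    graph: nx.Graph,
    methods: Sequence[str] = CENTRALITY_METHODS,
    k: int = 10,
) -> list[str]:
    """Consensus top-k hub genes across centrality methods."""
    return consensus_top_k([rank_by_centrality(graph, m) for m in methods], k=k)


def write_edge_table(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"GeneA": u, "GeneB": v, "CombinedScore": int(d["score"])}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["GeneA", "GeneB", "CombinedScore"]).sort_values(
        ["GeneA", "GeneB"]
    ).to_csv(path, sep="\t", index=False)
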