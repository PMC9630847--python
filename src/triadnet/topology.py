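"""Network topology: MCC hub scoring, core extraction, and MCL modules.

The refined feed-forward-loop network, projected to an undirected simple
graph, is summarised two ways:

* **Maximal Clique Centrality (MCC)** — for each node v,
  ``MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!``.
  High-MCC nodes define the core subnetwork (top-k induced subgraph).
  Maximal cliques come from Bron-Kerbosch with pivoting
  (``networkx.find_cliques``).
* **Markov clustering (MCL)** — alternating expansion (matrix squaring)
  and inflation (entrywise power + column renormalisation) of the
  column-stochastic flow matrix with self-loops, read out as modules from
  the attractor structure.

Degree and exact Brandes betweenness support hub/bottleneck labelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Hashable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CentralityReport",
    "ClusterAssignment",
    "maximal_cliques",
    "mcc_scores",
    "top_k_core",
    "mcl_cluster",
    "hubs_bottlenecks",
]


@dataclass(frozen=True)
class CentralityReport:
    """Per-node MCC, degree and betweenness as an index-aligned DataFrame."""

    table: pd.DataFrame  # columns: mcc, degree, betweenness

    def top(self, k: int) -> list:
        order = sorted(
            self.table.index, key=lambda v: (-self.table.at[v, "mcc"], str(v))
        )
        return order[:k]


@dataclass(frozen=True)
class ClusterAssignment:
    """Node -> cluster id map from MCL; ``converged`` False on max_iter."""

    labels: dict[Hashable, int]
    converged: bool
    n_iter: int

    def clusters(self) -> list[set]:
        out: dict[int, set] = {}
        for node, c in self.labels.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


def _check_simple(g: nx.Graph) -> None:
    if any(u == v for u, v in g.edges):
        raise ValueError("graph must be simple (no self-loops)")


def maximal_cliques(g: nx.Graph) -> list[frozenset]:
    """All maximal cliques (Bron-Kerbosch with pivoting).

    Isolated nodes count as cliques of size 1; the empty graph yields an
    empty list.
    """
    _check_simple(g)
    return [frozenset(c) for c in nx.find_cliques(g)]


def mcc_scores(g: nx.Graph) -> CentralityReport:
    """Maximal Clique Centrality with degree and betweenness per node.

    MCC(v) = sum of (|C| - 1)! over maximal cliques C containing v.  An
    isolated node lies only in its own 1-clique, scoring 0! = 1 by the raw
    formula; following the cytoHubba convention isolated nodes are scored
    0.  Betweenness is the exact unnormalised Brandes count.
    """
    mcc = {v: 0 for v in g.nodes}
    for clique in maximal_cliques(g):
        if len(clique) == 1:
            continue
        contrib = factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += contrib
    btw = nx.betweenness_centrality(g, normalized=False)
    table = pd.DataFrame(
        {
            "mcc": pd.Series(mcc),
            "degree": pd.Series(dict(g.degree)),
            "betweenness": pd.Series(btw),
        }
    )
    return CentralityReport(table=table)


def top_k_core(g: nx.Graph, report: CentralityReport, k: int) -> nx.Graph:
    """Induced subgraph on the k highest-MCC nodes.

    Ties at rank k break lexicographically on the node id (deterministic).
    k >= |V| returns a copy of the whole graph.
    """
    return g.subgraph(report.top(k)).copy()


def mcl_cluster(
    g: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterAssignment:
    """Markov clustering of an undirected graph.

    Self-loops of weight 1 are added (standard remedy for periodicity),
    the adjacency matrix is column-normalised, and expansion (M @ M) is
    alternated with inflation (entrywise power ``inflation`` followed by
    column renormalisation) until the matrix changes by less than ``tol``
    (max absolute entry) or ``max_iter`` is hit, in which case the current
    clustering is returned with ``converged=False``.

    Each attractor row (nonzero diagonal mass) of the limit matrix seeds a
    cluster; every node joins the attractor carrying the most flow from its
    column, so the assignment is a partition even for overlapping attractor
    supports.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(g.nodes, key=str)
    if not nodes:
        raise ValueError("empty graph")
    _check_simple(g)
    n = len(nodes)
    m = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    m += np.eye(n)
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expanded = m @ m
        inflated = expanded**inflation
        inflated /= inflated.sum(axis=0, keepdims=True)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated

    attractors = [i for i in range(n) if m[i, i] > tol]
    if not attractors:  # pathological non-convergence; fall back to argmax rows
        attractors = sorted(set(int(np.argmax(m[:, j])) for j in range(n)))
    # merge attractors that share flow into the same cluster
    parent = {a: a for a in attractors}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for j in range(n):
        owners = [a for a in attractors if m[a, j] > tol]
        for a in owners[1:]:
            ra, rb = find(owners[0]), find(a)
            if ra != rb:
                parent[rb] = ra

    labels: dict[Hashable, int] = {}
    cluster_ids: dict[int, int] = {}
    for j, node in enumerate(nodes):
        best = max(attractors, key=lambda a: (m[a, j], -a))
        root = find(best)
        cluster_ids.setdefault(root, len(cluster_ids))
        labels[node] = cluster_ids[root]
    return ClusterAssignment(labels=labels, converged=converged, n_iter=it)


def hubs_bottlenecks(
    g: nx.Graph,
    degree_quantile: float = 0.9,
    betweenness_quantile: float = 0.9,
) -> tuple[set, set]:
    """Nodes above the degree / betweenness quantile thresholds.

    Returns
    -------
    (hubs, bottlenecks) — nodes strictly above the respective quantile of
    the per-node degree and exact betweenness distributions.
    """
    if g.number_of_nodes() == 0:
        return set(), set()
    deg = pd.Series(dict(g.degree), dtype=float)
    btw = pd.Series(nx.betweenness_centrality(g, normalized=False), dtype=float)
    hubs = set(deg[deg > deg.quantile(degree_quantile)].index)
    bottlenecks = set(btw[btw > btw.quantile(betweenness_quantile)].index)
    return hubs, bottlenecks
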