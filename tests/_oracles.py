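"""Independent brute-force oracles used across the test suite.

Each function here recomputes a quantity by direct enumeration or a closed
form, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bh_step_up(p):
    """BH adjusted p-values via the min-step-up definition.

    adj_(k) = min_{j >= k} ( p_(j) * m / j ), capped at 1, mapped back to
    input order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (p[order] * m / np.arange(1, m + 1))[::-1]
    )[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def spearman_no_ties(x, y):
    """Classical 1 - 6*sum(d^2)/(n*(n^2-1)) for tie-free vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = x.size
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = ((rx - ry) ** 2).sum()
    return 1.0 - 6.0 * d2 / (n * (n**2 - 1))


def exact_ranksum_p(a, b):
    """Two-sided exact permutation p of the rank-sum / Mann-Whitney test.

    Enumerates all C(n, m) group labelings of the pooled tie-free sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle assumes no ties"
    m, n = a.size, b.size
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    idx = range(m + n)
    for subset in itertools.combinations(idx, m):
        grp = pooled[list(subset)]
        rest = np.delete(pooled, list(subset))
        us.append(sum(1 for x in grp for y in rest if x > y))
    us = np.asarray(us, dtype=float)
    total = comb(m + n, m)
    p = 2.0 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return min(p, 1.0)


def brute_force_ffls(tf_gene, mirna_gene, tf_mirna, mirna_tf):
    """Triple-loop FFL enumeration returning {(tf, mirna, gene): type}."""
    tf_gene, mirna_gene = set(tf_gene), set(mirna_gene)
    tf_mirna, mirna_tf = set(tf_mirna), set(mirna_tf)
    tfs = {t for t, _ in tf_gene} | {t for t, _ in tf_mirna} | {t for _, t in mirna_tf}
    mirnas = {m for m, _ in mirna_gene} | {m for _, m in tf_mirna} | {m for m, _ in mirna_tf}
    genes = {g for _, g in tf_gene} | {g for _, g in mirna_gene}
    out = {}
    for t in tfs:
        for m in mirnas:
            for g in genes:
                if g in (t, m):
                    continue
                if (t, g) not in tf_gene or (m, g) not in mirna_gene:
                    continue
                fwd = (t, m) in tf_mirna
                bwd = (m, t) in mirna_tf
                if fwd and bwd:
                    out[(t, m, g)] = "composite-FFL"
                elif fwd:
                    out[(t, m, g)] = "TF-FFL"
                elif bwd:
                    out[(t, m, g)] = "miRNA-FFL"
    return out


def brute_force_maximal_cliques(nodes, edges):
    """All maximal cliques by subset enumeration (|V| <= ~15)."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset((a, b)) in edge_set for a, b in itertools.combinations(sub, 2))

    cliques = [
        frozenset(sub)
        for r in range(1, len(nodes) + 1)
        for sub in itertools.combinations(nodes, r)
        if is_clique(sub)
    ]
    return {c for c in cliques if not any(c < d for d in cliques)}


def brute_force_betweenness(nodes, edges):
    """Exact betweenness by BFS shortest-path counting on tiny graphs."""
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    btw = dict.fromkeys(nodes, 0.0)
    for s in nodes:
        for t in nodes:
            if s >= t:
                continue
            # enumerate all shortest s-t paths by BFS layering
            dist = {s: 0}
            frontier = [s]
            while frontier:
                nxt = []
                for v in frontier:
                    for w in adj[v]:
                        if w not in dist:
                            dist[w] = dist[v] + 1
                            nxt.append(w)
                frontier = nxt
            if t not in dist:
                continue
            paths = [[s]]
            complete = []
            while paths:
                path = paths.pop()
                v = path[-1]
                if v == t:
                    complete.append(path)
                    continue
                for w in adj[v]:
                    if dist.get(w) == dist[v] + 1 and dist[w] <= dist[t]:
                        paths.append(path + [w])
            for path in complete:
                for v in path[1:-1]:
                    btw[v] += 1.0 / len(complete)
    return btw


def word_score_tail(disc_matrix, s_int, background):
    """P(score >= s_int) by enumerating all 4^w words on a discretized
    integer score matrix."""
    w = disc_matrix.shape[0]
    total = 0.0
    for word in itertools.product(range(4), repeat=w):
        score = sum(disc_matrix[i, b] for i, b in enumerate(word))
        if score >= s_int:
            total += np.prod([background[b] for b in word])
    return total
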