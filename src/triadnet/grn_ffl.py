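"""Feed-forward-loop (FFL) network construction and expression refinement.

An FFL is a three-node motif in which a transcription factor (TF) and a
miRNA both regulate a common target gene while also regulating one another.
Triads are classified by the direction of the TF-miRNA cross edge:

* TF-FFL        -- only TF -> miRNA,
* miRNA-FFL     -- only miRNA -> TF,
* composite-FFL -- both directions.

miRNA->target priors from multiple prediction databases are integrated by
keeping pairs supported by at least two sources.  Raw triads (from the
integrated priors plus promoter-scan TF edges) are then refined per sample
group with signed Spearman filters on expression: a miRNA->gene edge must
show Rs < 0 with p < 0.05 (repression) and a TF->gene edge Rs > 0 with
p < 0.05 (activation); a triad survives only if all of its filtered edges
pass.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .stats_core import CorrelationResult, spearman

__all__ = [
    "RegulatoryEdge",
    "FFLTriad",
    "RefinedNetwork",
    "integrate_mirna_priors",
    "enumerate_ffls",
    "refine_ffls",
    "pan_cancer_merge",
    "triads_to_graph",
    "write_edges_tsv",
    "read_edges_tsv",
    "write_triads_tsv",
]

FFL_TYPES = ("TF-FFL", "miRNA-FFL", "composite-FFL")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A directed regulator -> target relation with provenance.

    ``regulator_class`` is "TF" or "miRNA"; ``target_class`` is "TF",
    "miRNA" or "gene".  ``evidence`` records supporting sources (for
    database priors) or the motif p-value (for scanned TF edges).
    Self-edges are invalid.
    """

    regulator: str
    regulator_class: str
    target: str
    target_class: str
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.regulator_class not in ("TF", "miRNA"):
            raise ValueError(f"bad regulator_class {self.regulator_class!r}")
        if self.target_class not in ("TF", "miRNA", "gene"):
            raise ValueError(f"bad target_class {self.target_class!r}")
        if self.regulator == self.target:
            raise ValueError(f"self-edge on {self.regulator!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.regulator, self.target)


@dataclass(frozen=True)
class FFLTriad:
    """A (TF, miRNA, target gene) motif with its type label.

    ``edge_stats`` maps each constituent directed pair to the Spearman
    result computed during refinement (empty before refinement).
    """

    tf: str
    mirna: str
    target: str
    ffl_type: str
    edge_stats: Mapping[tuple[str, str], CorrelationResult] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if self.ffl_type not in FFL_TYPES:
            raise ValueError(f"bad ffl_type {self.ffl_type!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.tf, self.mirna, self.target)

    def edges(self) -> list[tuple[str, str]]:
        """Directed pairs making up the triad, cross edge(s) included."""
        pairs = [(self.tf, self.target), (self.mirna, self.target)]
        if self.ffl_type in ("TF-FFL", "composite-FFL"):
            pairs.append((self.tf, self.mirna))
        if self.ffl_type in ("miRNA-FFL", "composite-FFL"):
            pairs.append((self.mirna, self.tf))
        return pairs


@dataclass(frozen=True)
class RefinedNetwork:
    """Triads surviving expression refinement within one sample group."""

    group: str
    triads: tuple[FFLTriad, ...]
    skipped: tuple[tuple[tuple[str, str, str], str], ...] = ()

    def nodes_by_class(self) -> dict[str, set[str]]:
        roster: dict[str, set[str]] = {"TF": set(), "miRNA": set(), "gene": set()}
        for t in self.triads:
            roster["TF"].add(t.tf)
            roster["miRNA"].add(t.mirna)
            roster["gene"].add(t.target)
        return roster


def integrate_mirna_priors(
    sources: Mapping[str, Iterable[tuple[str, str]]],
    min_sources: int = 2,
    target_classes: Mapping[str, str] | None = None,
) -> list[RegulatoryEdge]:
    """Keep miRNA->target pairs supported by at least ``min_sources``.

    Parameters
    ----------
    sources : map source name -> set of (mirna, target) pairs.
    min_sources : minimum number of distinct supporting sources (default 2,
        the at-least-two-databases integration rule).
    target_classes : optional map target id -> class ("gene" default).

    Returns
    -------
    Edges sorted lexicographically, each with its supporting source list as
    evidence.
    """
    if len(sources) < min_sources:
        raise ValueError(
            f"need >= {min_sources} sources, got {len(sources)}"
        )
    support: dict[tuple[str, str], list[str]] = defaultdict(list)
    for name in sorted(sources):
        for pair in set(map(tuple, sources[name])):
            support[pair].append(name)
    edges = []
    for (mirna, target), names in sorted(support.items()):
        if len(names) >= min_sources:
            cls = target_classes.get(target, "gene") if target_classes else "gene"
            edges.append(
                RegulatoryEdge(
                    regulator=mirna,
                    regulator_class="miRNA",
                    target=target,
                    target_class=cls,
                    evidence=",".join(names),
                )
            )
    return edges


def _as_pairs(edges: Iterable) -> set[tuple[str, str]]:
    out = set()
    for e in edges:
        pair = e.pair if isinstance(e, RegulatoryEdge) else (e[0], e[1])
        if pair[0] == pair[1]:
            raise ValueError(f"self-edge on {pair[0]!r}")
        out.add(pair)
    return out


def enumerate_ffls(
    tf_gene: Iterable,
    mirna_gene: Iterable,
    tf_mirna: Iterable,
    mirna_tf: Iterable,
) -> list[FFLTriad]:
    """Enumerate all FFL triads implied by four directed edge sets.

    A triad (t, m, g) is emitted iff t->g and m->g both exist and at least
    one cross edge t->m or m->t exists; the type label follows the cross
    edge direction(s).  Edge sets may be RegulatoryEdge lists or plain
    (regulator, target) pairs.  Output is lexicographically ordered by
    (tf, mirna, target).
    """
    tg = _as_pairs(tf_gene)
    mg = _as_pairs(mirna_gene)
    tm = _as_pairs(tf_mirna)
    mt = _as_pairs(mirna_tf)

    genes_by_tf: dict[str, set[str]] = defaultdict(set)
    for t, g in tg:
        genes_by_tf[t].add(g)
    genes_by_mirna: dict[str, set[str]] = defaultdict(set)
    for m, g in mg:
        genes_by_mirna[m].add(g)

    triads = []
    cross = {(t, m) for t, m in tm} | {(t, m) for m, t in mt}
    for t, m in sorted(cross):
        forward = (t, m) in tm
        backward = (m, t) in mt
        if forward and backward:
            ffl_type = "composite-FFL"
        elif forward:
            ffl_type = "TF-FFL"
        else:
            ffl_type = "miRNA-FFL"
        for g in sorted(genes_by_tf.get(t, set()) & genes_by_mirna.get(m, set())):
            if g in (t, m):
                continue
            triads.append(FFLTriad(tf=t, mirna=m, target=g, ffl_type=ffl_type))
    triads.sort(key=lambda x: x.key)
    return triads


def refine_ffls(
    triads: Sequence[FFLTriad],
    expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    group_samples: Sequence[str] | None = None,
    group: str = "all",
    p_threshold: float = 0.05,
    filter_cross_edges: bool = False,
) -> RefinedNetwork:
    """Refine raw triads with signed Spearman filters within one group.

    Each miRNA->X edge must satisfy p < ``p_threshold`` and Rs < 0; each
    TF->X edge p < ``p_threshold`` and Rs > 0.  By default only the two
    target-incident edges (TF->gene, miRNA->gene) are filtered — the
    correlations of the TF-miRNA cross edge(s) are recorded but not
    required to pass, since a composite triad's single TF-miRNA correlation
    cannot be both positive and negative.  Set ``filter_cross_edges=True``
    to additionally require TF->miRNA edges to pass the activation rule and
    miRNA->TF edges the repression rule.

    A triad survives iff all of its filtered edges pass (strict AND).
    Triads with features missing from the matrices, or with degenerate
    (constant) expression, are reported in ``skipped`` with a reason code
    rather than raising.
    """
    if group_samples is None:
        group_samples = list(expr.columns)
    if len(group_samples) < 3:
        raise ValueError("group needs at least 3 samples")

    def row(feature: str):
        if feature in expr.index:
            return expr.loc[feature, group_samples].to_numpy(dtype=float)
        if feature in mirna_expr.index:
            return mirna_expr.loc[feature, group_samples].to_numpy(dtype=float)
        return None

    cache: dict[tuple[str, str], CorrelationResult | None] = {}

    def corr(a: str, b: str):
        key = (a, b)
        if key not in cache:
            xa, xb = row(a), row(b)
            cache[key] = None if xa is None or xb is None else spearman(xa, xb)
        return cache[key]

    surviving = []
    skipped = []
    for triad in triads:
        stats: dict[tuple[str, str], CorrelationResult] = {}
        reason = None
        for a, b in triad.edges():
            res = corr(a, b)
            if res is None:
                reason = f"missing_feature:{a if row(a) is None else b}"
                break
            stats[(a, b)] = res
            is_cross = {a, b} == {triad.tf, triad.mirna}
            if is_cross and not filter_cross_edges:
                continue
            if not res.ok:
                reason = f"degenerate_expression:{a}->{b}"
                break
            negative = a == triad.mirna  # miRNA-source edges are repressive
            if res.p_value >= p_threshold or (res.rho >= 0 if negative else res.rho <= 0):
                reason = f"filter_failed:{a}->{b}"
                break
        if reason is None:
            surviving.append(replace(triad, edge_stats=stats))
        elif reason.startswith("filter_failed"):
            continue  # removed by refinement, not an anomaly
        else:
            skipped.append((triad.key, reason))
    return RefinedNetwork(
        group=group, triads=tuple(surviving), skipped=tuple(skipped)
    )


def pan_cancer_merge(
    networks: Sequence[RefinedNetwork],
) -> tuple[list[tuple[FFLTriad, frozenset[str]]], dict[str, set[str]]]:
    """Union refined networks across groups.

    Returns
    -------
    (triads, roster) where ``triads`` pairs each distinct triad with the
    set of group labels in which it survived, and ``roster`` is the merged
    node roster by class.
    """
    by_key: dict[tuple[str, str, str], tuple[FFLTriad, set[str]]] = {}
    roster: dict[str, set[str]] = {"TF": set(), "miRNA": set(), "gene": set()}
    for net in networks:
        for cls, nodes in net.nodes_by_class().items():
            roster[cls] |= nodes
        for triad in net.triads:
            if triad.key in by_key:
                by_key[triad.key][1].add(net.group)
            else:
                by_key[triad.key] = (triad, {net.group})
    merged = [
        (triad, frozenset(groups))
        for triad, groups in (by_key[k] for k in sorted(by_key))
    ]
    return merged, roster


def triads_to_graph(triads: Iterable[FFLTriad]) -> nx.Graph:
    """Project triads to an undirected simple graph for topology analysis.

    Each regulator-target pair of each triad becomes one undirected edge;
    nodes carry a ``node_class`` attribute (TF / miRNA / gene).
    """
    g = nx.Graph()
    for triad in triads:
        g.add_node(triad.tf, node_class="TF")
        g.add_node(triad.mirna, node_class="miRNA")
        g.add_node(triad.target, node_class="gene")
        for a, b in triad.edges():
            g.add_edge(a, b)
    return g


_EDGE_COLUMNS = ["regulator", "target", "regulator_class", "target_class", "evidence"]


def write_edges_tsv(edges: Iterable[RegulatoryEdge], path) -> None:
    pd.DataFrame(
        [
            {
                "regulator": e.regulator,
                "target": e.target,
                "regulator_class": e.regulator_class,
                "target_class": e.target_class,
                "evidence": e.evidence,
            }
            for e in edges
        ],
        columns=_EDGE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> list[RegulatoryEdge]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        RegulatoryEdge(
            regulator=r.regulator,
            regulator_class=r.regulator_class,
            target=r.target,
            target_class=r.target_class,
            evidence=str(r.evidence),
        )
        for r in df.itertuples()
    ]


def write_triads_tsv(triads: Iterable[FFLTriad], path) -> None:
    pd.DataFrame(
        [
            {"tf": t.tf, "mirna": t.mirna, "target": t.target, "ffl_type": t.ffl_type}
            for t in triads
        ]
    ).to_csv(path, sep="\t", index=False)
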