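"""Expression/score - drug-response association screens.

Features (gene expression or the per-patient hazard-weighted score) are
correlated with drug response (AUC or imputed response; lower values mean
greater sensitivity) by Spearman correlation, with Benjamini-Hochberg
adjustment across all tested (feature, drug) pairs of one screen call.
Associations passing |Rs| > threshold and FDR < threshold are labelled
**sensitive** when Rs < 0 (high expression, low AUC) and **resistant**
when Rs > 0.  Default thresholds: |Rs| > 0.25 for per-gene screens on cell
lines and |Rs| > 0.3 for score-level screens, both at FDR < 0.05.

Multi-layer bias of clinically actionable genes (CAGs) between high- and
low-score patient groups is assessed per layer: continuous layers (mRNA,
protein, methylation) by the Wilcoxon rank-sum test with log fold change,
binary layers (mutation, SCNA events) by Fisher's exact test on 2x2
counts; each layer forms its own BH family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .grn_ffl import FFLTriad, RefinedNetwork, triads_to_graph
from .stats_core import bh_adjust, rank_sum_logfc

__all__ = [
    "DrugAssociation",
    "CagBiasRecord",
    "ScreenResult",
    "gene_drug_screen",
    "score_drug_screen",
    "cag_bias",
    "ffl_drug_network",
]


@dataclass(frozen=True)
class DrugAssociation:
    """A retained (feature, drug) correlation with its label."""

    feature: str
    drug: str
    rho: float
    p_value: float
    fdr: float
    label: str  # "sensitive" (Rs < 0) or "resistant" (Rs > 0)

    def __post_init__(self) -> None:
        expected = "sensitive" if self.rho < 0 else "resistant"
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with Rs={self.rho}")


@dataclass(frozen=True)
class CagBiasRecord:
    """Per-gene, per-layer bias between high- and low-score groups."""

    gene: str
    layer: str
    statistic: float  # logFC (continuous) or frequency difference (binary)
    p_value: float
    fdr: float
    biased_group: str  # "high" or "low"


@dataclass(frozen=True)
class ScreenResult:
    """All tested pairs plus the retained, labelled associations."""

    associations: tuple[DrugAssociation, ...]
    tested: pd.DataFrame  # feature, drug, rho, p, fdr
    skipped: tuple[tuple[str, str, str], ...] = ()  # (feature, drug, reason)


def _spearman_grid(
    feat: pd.DataFrame, resp: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, str]]]:
    """Spearman rho and two-sided t-approximation p for every pair.

    ``feat`` is features x samples, ``resp`` samples x drugs, fully
    aligned.  Missing response values fall back to per-pair computation on
    pairwise-complete observations.  Degenerate pairs (constant vector or
    < 3 shared samples) are reported in the skip list with NaN statistics.
    """
    n_feat, n = feat.shape
    n_drug = resp.shape[1]
    rho = np.full((n_feat, n_drug), np.nan)
    pval = np.full((n_feat, n_drug), np.nan)
    skipped: list[tuple[int, int, str]] = []

    fvals = feat.to_numpy(dtype=float)
    rvals = resp.to_numpy(dtype=float)
    feat_const = np.ptp(fvals, axis=1) == 0
    resp_nan = np.isnan(rvals).any(axis=0)

    def t_pvalue(r: np.ndarray, m: int) -> np.ndarray:
        r = np.clip(r, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((m - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
        return np.where(np.abs(r) >= 1.0, 0.0, p)

    clean_cols = np.nonzero(~resp_nan)[0]
    if clean_cols.size and n >= 3:
        fr = stats.rankdata(fvals, axis=1)
        rr = stats.rankdata(rvals[:, clean_cols], axis=0)
        fr = (fr - fr.mean(axis=1, keepdims=True)) / np.where(
            fr.std(axis=1) == 0, 1.0, fr.std(axis=1)
        )[:, None]
        rsd = rr.std(axis=0)
        resp_const = rsd == 0
        rr = (rr - rr.mean(axis=0, keepdims=True)) / np.where(resp_const, 1.0, rsd)[None, :]
        r = fr @ rr / n
        r[feat_const, :] = np.nan
        r[:, resp_const] = np.nan
        rho[:, clean_cols] = r
        pval[:, clean_cols] = t_pvalue(r, n)

    for j in np.nonzero(resp_nan)[0]:
        y = rvals[:, j]
        ok = ~np.isnan(y)
        for i in range(n_feat):
            x = fvals[i, ok]
            if ok.sum() < 3:
                skipped.append((i, j, "fewer_than_3_shared_samples"))
                continue
            if np.ptp(x) == 0 or np.ptp(y[ok]) == 0:
                continue  # picked up as constant below
            r, p = stats.spearmanr(x, y[ok])
            rho[i, j], pval[i, j] = r, p

    return rho, pval, skipped


def gene_drug_screen(
    expr: pd.DataFrame,
    drugs: pd.DataFrame,
    rs_threshold: float = 0.25,
    fdr_threshold: float = 0.05,
) -> ScreenResult:
    """Per-gene Spearman screen against drug response.

    ``expr`` is genes x samples, ``drugs`` samples x drugs; shared samples
    are intersected.  BH adjustment runs across all testable pairs of this
    call (one FDR family per screen).  Retention requires strictly
    |Rs| > ``rs_threshold`` and FDR < ``fdr_threshold``; the label follows
    the correlation sign (negative = sensitive).
    """
    shared = expr.columns.intersection(drugs.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    feat = expr[shared]
    resp = drugs.loc[shared]
    rho, pval, idx_skips = _spearman_grid(feat, resp)

    features = list(map(str, feat.index))
    drug_ids = list(map(str, resp.columns))
    ok = ~np.isnan(rho)
    rows = [
        (features[i], drug_ids[j], rho[i, j], pval[i, j])
        for i, j in zip(*np.nonzero(ok))
    ]
    skipped = [(features[i], drug_ids[j], reason) for i, j, reason in idx_skips]
    skipped += [
        (features[i], drug_ids[j], "degenerate_feature_or_response")
        for i, j in zip(*np.nonzero(~ok))
        if (features[i], drug_ids[j]) not in {(a, b) for a, b, _ in skipped}
    ]
    if not rows:
        return ScreenResult(
            associations=(),
            tested=pd.DataFrame(columns=["feature", "drug", "rho", "p", "fdr"]),
            skipped=tuple(skipped),
        )
    table = pd.DataFrame(rows, columns=["feature", "drug", "rho", "p"])
    table["fdr"] = bh_adjust(table["p"].to_numpy()).adjusted
    keep = (table["rho"].abs() > rs_threshold) & (table["fdr"] < fdr_threshold)
    assocs = tuple(
        DrugAssociation(
            feature=r.feature,
            drug=r.drug,
            rho=float(r.rho),
            p_value=float(r.p),
            fdr=float(r.fdr),
            label="sensitive" if r.rho < 0 else "resistant",
        )
        for r in table[keep].itertuples()
    )
    return ScreenResult(associations=assocs, tested=table, skipped=tuple(skipped))


def score_drug_screen(
    score: pd.Series,
    drugs: pd.DataFrame,
    rs_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
) -> ScreenResult:
    """Screen a single per-sample score against every drug."""
    expr = score.to_frame(score.name or "score").T
    return gene_drug_screen(expr, drugs, rs_threshold, fdr_threshold)


def cag_bias(
    high: Sequence[str],
    low: Sequence[str],
    layers: Mapping[str, pd.DataFrame],
    genes: Sequence[str] | None = None,
) -> tuple[list[CagBiasRecord], list[tuple[str, str]]]:
    """Multi-layer alteration bias between high- and low-score groups.

    Each layer is a genes x samples matrix; layers whose values are all
    0/1 are treated as binary alteration calls (Fisher exact on the 2x2
    altered-by-group table, statistic = frequency difference high - low),
    the rest as continuous (Wilcoxon rank-sum, statistic = logFC
    high - low).  BH adjustment runs within each layer.

    Returns
    -------
    (records, untested) with one record per (gene, layer) tested and a
    list of (gene, layer) pairs missing from a layer.
    """
    high, low = list(high), list(low)
    if genes is None:
        genes = sorted({g for m in layers.values() for g in map(str, m.index)})
    records: list[CagBiasRecord] = []
    untested: list[tuple[str, str]] = []
    for layer_name in sorted(layers):
        mat = layers[layer_name]
        h = [s for s in high if s in mat.columns]
        l = [s for s in low if s in mat.columns]
        vals = mat.to_numpy()
        binary = np.isin(vals[~np.isnan(vals.astype(float))], (0, 1)).all()
        layer_rows = []
        for gene in genes:
            if gene not in mat.index:
                untested.append((gene, layer_name))
                continue
            a = mat.loc[gene, h].to_numpy(dtype=float)
            b = mat.loc[gene, l].to_numpy(dtype=float)
            if binary:
                table = [
                    [int(a.sum()), int(len(a) - a.sum())],
                    [int(b.sum()), int(len(b) - b.sum())],
                ]
                _, p = stats.fisher_exact(table)
                statistic = float(a.mean() - b.mean())
            else:
                p, statistic = rank_sum_logfc(a, b)
            layer_rows.append((gene, statistic, p))
        if not layer_rows:
            continue
        fdr = bh_adjust([p for _, _, p in layer_rows]).adjusted
        for (gene, statistic, p), q in zip(layer_rows, fdr):
            records.append(
                CagBiasRecord(
                    gene=gene,
                    layer=layer_name,
                    statistic=statistic,
                    p_value=float(p),
                    fdr=float(q),
                    biased_group="high" if statistic > 0 else "low",
                )
            )
    return records, untested


def ffl_drug_network(
    refined: RefinedNetwork | Iterable[FFLTriad],
    *association_lists: Iterable[DrugAssociation],
) -> nx.Graph:
    """Integrate refined triads with feature-drug associations.

    Nodes are the TFs, miRNAs and target genes of the refined network plus
    one node per associated drug (``node_class="drug"``); edges are the
    triad regulator-target pairs plus one labelled association edge per
    (feature, drug) whose feature appears in the network.
    """
    triads = refined.triads if isinstance(refined, RefinedNetwork) else tuple(refined)
    g = triads_to_graph(triads)
    for assocs in association_lists:
        for a in assocs:
            if a.feature not in g:
                continue
            g.add_node(a.drug, node_class="drug")
            g.add_edge(a.feature, a.drug, label=a.label, rho=a.rho, fdr=a.fdr)
    return g
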