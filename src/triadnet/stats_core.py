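"""Shared statistical primitives.

Every screen in the pipeline reduces to a handful of operations: Spearman
rank correlation with a two-sided p-value, Benjamini-Hochberg adjustment,
per-gene z-normalization, the Wilcoxon rank-sum test with a log-fold-change,
and per-group alteration frequencies.  They are centralised here so that the
conventions (mid-ranks for ties, t-approximation for the Spearman p, sample
standard deviation for z-scores) are fixed in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "AdjustedPVector",
    "spearman",
    "bh_adjust",
    "z_normalize",
    "alteration_frequency",
    "rank_sum_logfc",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation (Rs) with its two-sided p-value.

    ``ok`` is False when the correlation is undefined (a constant input
    vector); in that case ``rho`` and ``p_value`` are NaN rather than a
    silent zero.
    """

    rho: float
    p_value: float
    n: int
    ok: bool = True

    def __post_init__(self) -> None:
        if self.ok and not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho out of range: {self.rho}")


@dataclass(frozen=True)
class AdjustedPVector:
    """Raw p-values and their BH-adjusted counterparts, index aligned."""

    raw: np.ndarray
    adjusted: np.ndarray

    def __post_init__(self) -> None:
        if self.raw.shape != self.adjusted.shape:
            raise ValueError("raw and adjusted must be index-aligned")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation of two equal-length vectors.

    Rho is the Pearson correlation of mid-ranks (average ranks on ties) and
    the p-value uses the two-sided t-distribution approximation, matching
    the classical formula 1 - 6*sum(d^2)/(n*(n^2-1)) exactly when there are
    no ties.  A constant vector makes the correlation undefined; this is
    reported through ``ok=False``, never coerced to zero.

    Parameters
    ----------
    x, y : array-like of float, length >= 3, finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n, ok=False)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=n)


def bh_adjust(p) -> AdjustedPVector:
    """Benjamini-Hochberg step-up adjusted p-values (FDR).

    Input order is preserved; ties receive identical adjusted values.
    """
    raw = np.asarray(p, dtype=float)
    if raw.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if raw.size == 0:
        return AdjustedPVector(raw=raw, adjusted=raw.copy())
    if np.any((raw < 0) | (raw > 1)) or not np.isfinite(raw).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
    return AdjustedPVector(raw=raw, adjusted=adjusted)


def z_normalize(expr: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """z-normalize a genes x samples matrix per gene (row).

    Uses the sample standard deviation (ddof=1).  Constant rows cannot be
    scaled; they are set to all-zero and reported in the returned flag list.

    Returns
    -------
    (normalized, constant_genes)
    """
    if expr.size == 0:
        raise ValueError("empty expression matrix")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    sd_safe = np.where(sd == 0, 1.0, sd)
    out = (values - mean) / sd_safe
    out[constant, :] = 0.0
    flagged = [str(g) for g in expr.index[constant]]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns), flagged


def alteration_frequency(
    alterations: pd.DataFrame, groups: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-group, per-gene alteration frequency.

    Parameters
    ----------
    alterations : binary sample x gene matrix (0/1).
    groups : map sample -> group label; only mapped samples are counted.

    Returns
    -------
    group x gene DataFrame of frequencies in [0, 1]
    (altered count / group size).
    """
    groups = pd.Series(groups)
    vals = alterations.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("alteration matrix must be binary 0/1")
    common = alterations.index.intersection(groups.index)
    sub = alterations.loc[common]
    return sub.groupby(groups.loc[common]).mean()


def rank_sum_logfc(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p-value and log fold change.

    The inputs are log2-scale values; logFC is defined as
    ``mean(a) - mean(b)`` so that a +1 shift of ``a`` in log2 units gives
    logFC = 1.  The p-value is the exact permutation distribution of the
    rank-sum statistic for small tie-free samples and the tie-corrected
    normal approximation otherwise (scipy ``mannwhitneyu`` with
    ``method="auto"``; the two-sided Mann-Whitney U test is equivalent to
    the Wilcoxon rank-sum test).

    Returns
    -------
    (p_value, logFC)
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    stat = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    logfc = float(a.mean() - b.mean())
    return float(stat.pvalue), logfc
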