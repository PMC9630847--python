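"""Hazard-weighted gene-set scoring and survival stratification.

The clinical arm of the pipeline: each family gene is screened with a
univariate Cox proportional-hazards model on z-normalized log2 expression,
genes with a significant hazard ratio (Wald p < 0.05) form the score
roster, and each patient receives the score

    score(s) = (1 / n_genes) * sum_over_roster( e_{g,s} * HR_g )

— the mean of the patient's z-normalized expression over the significant
genes, weighted by each gene's hazard ratio.  Patients are then split at
the score cut-point maximising the two-group log-rank statistic (maximally
selected rank statistic, survminer-style) and compared with Kaplan-Meier
curves and the log-rank test.

The univariate Cox solver is a Newton-Raphson maximiser of the partial
likelihood with Breslow tie handling by default (Efron available); it is
cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

__all__ = [
    "NoEventsError",
    "SurvivalTable",
    "HazardEstimate",
    "PTPScoreResult",
    "CutpointResult",
    "LogrankResult",
    "cox_univariate",
    "select_significant",
    "ptp_score",
    "logrank_chisq",
    "km_logrank",
    "optimal_cutpoint",
]


class NoEventsError(ValueError):
    """Raised when a survival fit is attempted with no observed events."""


@dataclass(frozen=True)
class SurvivalTable:
    """Aligned survival vectors: sample ids, positive times, 0/1 events."""

    samples: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be aligned 1-D vectors")
        if (time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("events must be 0/1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalTable":
        return cls(
            samples=tuple(df["sample"].astype(str)),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.samples, "time": self.time, "event": self.event}
        )


@dataclass(frozen=True)
class HazardEstimate:
    """Univariate proportional-hazards output for one gene."""

    gene: str
    hr: float
    coef: float
    se: float
    wald_p: float
    n_events: int
    ok: bool = True  # False on non-convergence or a degenerate covariate


@dataclass(frozen=True)
class PTPScoreResult:
    """Per-sample hazard-weighted score with its roster and weights."""

    scores: pd.Series
    roster: tuple[str, ...]
    weights: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CutpointResult:
    """Maximally selected log-rank cut-point.

    The reported p-value is not corrected for the cut-point search and is
    therefore selection-biased; treat it as descriptive.
    """

    cutpoint: float
    chi_sq: float
    p_value: float
    n_low: int
    n_high: int


@dataclass(frozen=True)
class LogrankResult:
    chi_sq: float
    p_value: float
    km_curves: Mapping[str, pd.DataFrame] = field(default_factory=dict)


def _partial_likelihood_terms(
    beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str
) -> tuple[float, float, float]:
    """(loglik, gradient, information) of the univariate Cox model at beta."""
    order = np.argsort(-time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    eta = beta * x
    w = np.exp(eta - eta.max())  # rescaled risk weights; constants cancel
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)

    loglik = grad = info = 0.0
    i = 0
    n = x.size
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        died = event[i:j] == 1
        d = int(died.sum())
        if d:
            xs = x[i:j][died]
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            if ties == "breslow" or d == 1:
                loglik += beta * xs.sum() - d * np.log(S0)
                grad += xs.sum() - d * S1 / S0
                info += d * (S2 / S0 - (S1 / S0) ** 2)
            elif ties == "efron":
                wd = np.exp(beta * xs - eta.max())
                D0, D1, D2 = wd.sum(), (wd * xs).sum(), (wd * xs * xs).sum()
                loglik += beta * xs.sum()
                for r in range(d):
                    f = r / d
                    a0 = S0 - f * D0
                    a1 = S1 - f * D1
                    a2 = S2 - f * D2
                    loglik -= np.log(a0)
                    grad += -a1 / a0
                    info += a2 / a0 - (a1 / a0) ** 2
                grad += xs.sum()
            else:
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return loglik, grad, info


def cox_univariate(
    gene_expr,
    survival: SurvivalTable,
    gene: str = "gene",
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> HazardEstimate:
    """Univariate Cox proportional-hazards fit for one covariate.

    Maximises the partial likelihood by Newton-Raphson (Breslow tie
    handling by default, Efron optional) and reports HR = exp(coef) with a
    two-sided Wald p-value.  The covariate is expected z-normalized so that
    HRs are per standard deviation of expression.

    Raises
    ------
    NoEventsError when no events are observed; ValueError for < 2 events.
    A constant covariate or a non-converged fit returns ``ok=False`` with
    NaN statistics rather than raising.
    """
    x = np.asarray(gene_expr, dtype=float)
    if x.shape != survival.time.shape:
        raise ValueError("expression and survival are not aligned")
    n_events = int(survival.event.sum())
    if n_events == 0:
        raise NoEventsError("no events observed; hazard ratio is not estimable")
    if n_events < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        return HazardEstimate(gene, np.nan, np.nan, np.nan, np.nan, n_events, ok=False)

    beta = 0.0
    converged = False
    for _ in range(max_iter):
        _, grad, info = _partial_likelihood_terms(
            beta, x, survival.time, survival.event, ties
        )
        if info <= 0:
            break
        step = grad / info
        step = np.clip(step, -2.0, 2.0)  # guard wild first steps
        beta += step
        if abs(step) < tol:
            converged = True
            break
    _, _, info = _partial_likelihood_terms(beta, x, survival.time, survival.event, ties)
    if not converged or info <= 0 or not np.isfinite(beta):
        return HazardEstimate(gene, np.nan, np.nan, np.nan, np.nan, n_events, ok=False)
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return HazardEstimate(
        gene=gene,
        hr=float(np.exp(beta)),
        coef=float(beta),
        se=float(se),
        wald_p=float(max(p, np.finfo(float).tiny)),
        n_events=n_events,
    )


def select_significant(
    estimates: Sequence[HazardEstimate], alpha: float = 0.05
) -> list[str]:
    """Genes with a significant hazard ratio (Wald p < alpha).

    An empty roster is signalled with a warning (downstream scoring then
    refuses to run) rather than passed through silently.
    """
    roster = [e.gene for e in estimates if e.ok and e.wald_p < alpha]
    if not roster:
        warnings.warn("no gene has a significant hazard ratio", stacklevel=2)
    return roster


def ptp_score(
    z_expr: pd.DataFrame,
    estimates: Mapping[str, HazardEstimate] | Mapping[str, float],
) -> PTPScoreResult:
    """Hazard-weighted mean score per sample.

    ``z_expr`` is the genes x samples matrix restricted to the significant
    roster and must already be z-normalized per gene (mean 0, sample-sd 1;
    all-zero rows from constant genes are tolerated).  The score of sample
    s is ``mean over genes of z_expr[g, s] * HR_g``.
    """
    if z_expr.shape[0] == 0:
        raise ValueError("empty roster: no significant genes to score")
    vals = z_expr.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd1 = vals.std(axis=1, ddof=1)
    sd0 = vals.std(axis=1, ddof=0)
    zeroed = (vals == 0).all(axis=1)
    # accept either sd convention (sample or population) as unit scale
    unit = (np.abs(sd1 - 1) <= 1e-6) | (np.abs(sd0 - 1) <= 1e-6)
    if (np.abs(mean) > 1e-6).any() or (~zeroed & ~unit).any():
        raise ValueError("expression must be z-normalized per gene before scoring")
    weights = np.array(
        [
            e.hr if isinstance(e := estimates[g], HazardEstimate) else float(e)
            for g in z_expr.index
        ]
    )
    scores = vals.T @ weights / len(z_expr.index)
    return PTPScoreResult(
        scores=pd.Series(scores, index=z_expr.columns, name="ptpscore"),
        roster=tuple(str(g) for g in z_expr.index),
        weights={str(g): float(w) for g, w in zip(z_expr.index, weights)},
    )


def logrank_chisq(
    time: np.ndarray, event: np.ndarray, in_group1: np.ndarray
) -> tuple[float, float]:
    """Two-group Mantel-Haenszel log-rank statistic and p-value.

    Vectorised over the event table; used both directly and inside the
    cut-point scan.  Identical groups give chi-square 0, p = 1.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], g1[order]
    n = t.size
    first = np.r_[True, t[1:] != t[:-1]]
    starts = np.nonzero(first)[0]
    at_risk = n - starts
    g_suffix = np.concatenate([np.cumsum(g[::-1])[::-1], [0]])
    n1_at_risk = g_suffix[starts]
    d = np.add.reduceat(e, starts)
    d1 = np.add.reduceat(e * g, starts)

    use = (d > 0) & (at_risk > 1)
    frac = n1_at_risk[use] / at_risk[use]
    o_minus_e = (d1[use] - d[use] * frac).sum()
    var = (
        d[use]
        * frac
        * (1 - frac)
        * (at_risk[use] - d[use])
        / (at_risk[use] - 1)
    ).sum()
    if var == 0:
        return 0.0, 1.0
    chi = o_minus_e**2 / var
    return float(chi), float(stats.chi2.sf(chi, df=1))


def km_logrank(
    groups: Mapping[str, str] | pd.Series | np.ndarray,
    survival: SurvivalTable,
) -> LogrankResult:
    """Two-group log-rank comparison with Kaplan-Meier curves.

    ``groups`` assigns each sample a binary label (aligned array or map by
    sample id).  The returned ``km_curves`` hold one KM survival-function
    table per group label, ready for plotting.
    """
    if isinstance(groups, (dict, pd.Series)):
        labels = np.array([groups[s] for s in survival.samples])
    else:
        labels = np.asarray(groups)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    mask = labels == uniq[1]
    chi, p = logrank_chisq(survival.time, survival.event, mask)
    curves = {}
    for label in uniq:
        sel = labels == label
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[sel], survival.event[sel], label=str(label))
        curves[str(label)] = kmf.survival_function_
    return LogrankResult(chi_sq=chi, p_value=p, km_curves=curves)


def optimal_cutpoint(
    score,
    survival: SurvivalTable,
    minprop: float = 0.1,
) -> CutpointResult:
    """Cut-point maximising the two-group log-rank statistic.

    Candidate cut-points are the observed score values whose low (<= cut)
    and high (> cut) groups both contain at least ``minprop`` of the
    samples (survminer's maximally selected rank statistic, without the
    Hothorn-Lausen p-value correction).  Ties in the statistic break toward
    the lower cut-point.  The associated p-value is selection-biased; see
    CutpointResult.
    """
    score = np.asarray(score, dtype=float)
    if score.shape != survival.time.shape:
        raise ValueError("score and survival are not aligned")
    if np.ptp(score) == 0:
        raise ValueError("all scores are equal; no cut-point exists")
    if not 0 < minprop <= 0.5:
        raise ValueError("minprop must be in (0, 0.5]")
    n = score.size
    min_group = int(np.ceil(minprop * n))
    candidates = np.unique(score)[:-1]  # score > max gives an empty high group
    best: CutpointResult | None = None
    for c in candidates:
        high = score > c
        n_high = int(high.sum())
        if n_high < min_group or n - n_high < min_group:
            continue
        chi, p = logrank_chisq(survival.time, survival.event, high)
        if best is None or chi > best.chi_sq:
            best = CutpointResult(
                cutpoint=float(c),
                chi_sq=chi,
                p_value=p,
                n_low=n - n_high,
                n_high=n_high,
            )
    if best is None:
        raise ValueError("no candidate cut-point satisfies the minprop constraint")
    return best
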