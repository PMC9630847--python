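"""Synthetic cohorts with planted regulatory ground truth.

Every downstream stage of the pipeline is testable without downloads
because this module emulates its inputs with known structure:

* a regulatory ground truth — TF->gene / TF->miRNA edges with positive
  linear coefficients (activation) and miRNA->gene / miRNA->TF edges with
  negative coefficients (repression), from which the planted feed-forward
  loops are exactly recoverable by brute-force enumeration;
* log2-scale expression: regulator rows i.i.d. Gaussian, target rows the
  planted linear combination of their regulators plus Gaussian noise;
* miRNA->target prior sources with controlled recall and false-positive
  rate per source, emulating multi-database target predictions;
* survival times exponential with log-hazard linear in z-normalized
  expression, under independent exponential censoring calibrated to the
  requested censoring fraction;
* drug response (AUC-like) linear in the expression of selected genes;
* promoter sequences with PWM-distributed motif instances planted at
  recorded positions.

Determinism: one integer master seed; each component draws from a child
generator ``default_rng(SeedSequence(seed, spawn_key=(k,)))`` with a fixed
per-component index k, so any stage can be regenerated independently and
identical configurations give identical outputs on every platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ptpscore_survival import SurvivalTable

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "child_rng",
    "generate_truth",
    "generate_prior_sources",
    "generate_expression",
    "generate_survival",
    "generate_drug_response",
    "generate_promoters",
    "simulate",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_survival_tsv",
    "read_survival_tsv",
    "write_fasta",
    "read_fasta",
]

#: fixed spawn-key index per component (documented seed derivation)
_COMPONENTS = {
    "truth": 0,
    "priors": 1,
    "expression": 2,
    "survival": 3,
    "drugs": 4,
    "promoters": 5,
}

_PRIOR_SOURCE_NAMES = ("miRDB", "miRTarBase", "PITA", "TargetScan")


def child_rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component child generator of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_COMPONENTS[component],))
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    The defaults are the simulation conditions the package's validation
    runs under: a modest gene family (20 targets) regulated by 5 TFs and
    5 miRNAs at edge density 0.3, 200 samples, regulatory effect size 1.0
    on log2 expression against noise sd 0.3, 20% censoring, and 4 prior
    sources at recall 0.9 / false-positive rate 0.05.
    """

    seed: int = 0
    n_tf: int = 5
    n_mirna: int = 5
    n_target: int = 20
    n_samples: int = 200
    edge_density: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 0.3
    censor_rate: float = 0.2
    prior_recall: float = 0.9
    prior_fpr: float = 0.05
    n_sources: int = 4
    n_drugs: int = 8
    survival_frac: float = 0.3
    survival_beta: float = math.log(2)
    drug_frac: float = 0.25
    drug_effect: float = 1.0
    drug_noise_sd: float = 0.3
    baseline_hazard: float = 0.05
    expr_mean: float = 8.0

    def __post_init__(self) -> None:
        for name in ("n_tf", "n_mirna", "n_target", "n_samples", "n_sources", "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("edge_density", "censor_rate", "prior_recall", "prior_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.noise_sd <= 0 or self.drug_noise_sd <= 0:
            raise ValueError("noise sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth regulatory structure of a synthetic cohort.

    Edge maps go (regulator, target) -> signed linear coefficient; TF-source
    edges are positive, miRNA-source edges negative.  ``survival_betas``
    maps genes to their planted log-hazard coefficients and
    ``drug_effects`` maps (gene, drug) to response coefficients.
    """

    tfs: tuple[str, ...]
    mirnas: tuple[str, ...]
    targets: tuple[str, ...]
    drugs: tuple[str, ...]
    tf_gene_edges: dict[tuple[str, str], float]
    mirna_gene_edges: dict[tuple[str, str], float]
    tf_mirna_edges: dict[tuple[str, str], float]
    mirna_tf_edges: dict[tuple[str, str], float]
    survival_betas: dict[str, float] = field(default_factory=dict)
    drug_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.tf_gene_edges.values()) or any(
            c <= 0 for c in self.tf_mirna_edges.values()
        ):
            raise ValueError("TF-source coefficients must be positive")
        if any(c >= 0 for c in self.mirna_gene_edges.values()) or any(
            c >= 0 for c in self.mirna_tf_edges.values()
        ):
            raise ValueError("miRNA-source coefficients must be negative")


def _bernoulli_edges(rng, sources, targets, p, coef):
    out = {}
    for a in sources:
        for b in targets:
            if rng.random() < p:
                out[(a, b)] = coef
    return out


def generate_truth(config: SimConfig) -> PlantedTruth:
    """Sample the planted regulatory structure.

    Each potential edge of each class is drawn independently with
    probability ``edge_density``; coefficients are +/- ``effect_size`` by
    regulator class.  When at least two nodes of every class exist and the
    density is >= 0.5, one triad of each FFL type (TF-FFL, miRNA-FFL,
    composite-FFL) is additionally planted deterministically so that every
    motif class is exercised.
    """
    rng = child_rng(config.seed, "truth")
    tfs = tuple(f"TF{i + 1:02d}" for i in range(config.n_tf))
    mirnas = tuple(f"miR{i + 1:02d}" for i in range(config.n_mirna))
    targets = tuple(f"G{i + 1:03d}" for i in range(config.n_target))
    drugs = tuple(f"drug{i + 1:02d}" for i in range(config.n_drugs))

    d, eff = config.edge_density, config.effect_size
    tf_gene = _bernoulli_edges(rng, tfs, targets, d, eff)
    mirna_gene = _bernoulli_edges(rng, mirnas, targets, d, -eff)
    tf_mirna = _bernoulli_edges(rng, tfs, mirnas, d, eff)
    mirna_tf = _bernoulli_edges(rng, mirnas, tfs, d, -eff)

    if d > 0:
        # guarantee every edge class is represented
        tf_gene.setdefault((tfs[0], targets[0]), eff)
        mirna_gene.setdefault((mirnas[0], targets[0]), -eff)
        tf_mirna.setdefault((tfs[0], mirnas[0]), eff)
        mirna_tf.setdefault((mirnas[-1], tfs[-1]), -eff)

    if (
        d >= 0.5
        and config.n_tf >= 2
        and config.n_mirna >= 2
        and config.n_target >= 2
    ):
        # one planted triad of each FFL type
        tf_gene.setdefault((tfs[0], targets[0]), eff)
        mirna_gene.setdefault((mirnas[0], targets[0]), -eff)
        tf_mirna.setdefault((tfs[0], mirnas[0]), eff)
        mirna_tf.pop((mirnas[0], tfs[0]), None)  # keep it a pure TF-FFL

        tf_gene.setdefault((tfs[1], targets[1]), eff)
        mirna_gene.setdefault((mirnas[1], targets[1]), -eff)
        mirna_tf.setdefault((mirnas[1], tfs[1]), -eff)
        tf_mirna.pop((tfs[1], mirnas[1]), None)  # pure miRNA-FFL

        tf_gene.setdefault((tfs[0], targets[1]), eff)
        mirna_gene.setdefault((mirnas[1], targets[1]), -eff)
        tf_mirna.setdefault((tfs[0], mirnas[1]), eff)
        mirna_tf.setdefault((mirnas[1], tfs[0]), -eff)  # composite-FFL

    surv_genes = sorted(
        rng.choice(
            targets,
            size=max(1, round(config.survival_frac * config.n_target)),
            replace=False,
        )
    )
    survival_betas = {
        g: float(config.survival_beta * rng.choice([-1.0, 1.0])) for g in surv_genes
    }
    drug_effects: dict[tuple[str, str], float] = {}
    n_hit = max(1, round(config.drug_frac * config.n_target))
    for drug in drugs:
        for g in sorted(rng.choice(targets, size=n_hit, replace=False)):
            drug_effects[(g, drug)] = float(
                config.drug_effect * rng.choice([-1.0, 1.0])
            )
    return PlantedTruth(
        tfs=tfs,
        mirnas=mirnas,
        targets=targets,
        drugs=drugs,
        tf_gene_edges=tf_gene,
        mirna_gene_edges=mirna_gene,
        tf_mirna_edges=tf_mirna,
        mirna_tf_edges=mirna_tf,
        survival_betas=survival_betas,
        drug_effects=drug_effects,
    )


def generate_prior_sources(
    truth: PlantedTruth,
    n_sources: int,
    recall: float,
    fpr: float,
    seed: int,
) -> dict[str, set[tuple[str, str]]]:
    """Emulate miRNA-target prediction databases of varying quality.

    Each source contains each true miRNA->gene edge independently with
    probability ``recall`` and each non-edge (decoy) pair with probability
    ``fpr``.  Sources are named after common prediction databases.
    """
    if n_sources < 2:
        raise ValueError("need at least 2 prior sources")
    rng = child_rng(seed, "priors")
    true_pairs = sorted(truth.mirna_gene_edges)
    decoys = sorted(
        (m, g)
        for m in truth.mirnas
        for g in truth.targets
        if (m, g) not in truth.mirna_gene_edges
    )
    names = [
        _PRIOR_SOURCE_NAMES[i] if i < len(_PRIOR_SOURCE_NAMES) else f"source{i + 1}"
        for i in range(n_sources)
    ]
    out: dict[str, set[tuple[str, str]]] = {}
    for name in names:
        kept = {p for p in true_pairs if rng.random() < recall}
        kept |= {p for p in decoys if rng.random() < fpr}
        out[name] = kept
    return out


def generate_expression(
    truth: PlantedTruth, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2-scale expression for genes (TFs + targets) and miRNAs.

    Regulator rows (TFs, miRNAs) are i.i.d. standard Gaussian deviations
    around ``expr_mean``; each target row is the planted linear combination
    of its regulators' deviations plus Gaussian noise of sd ``noise_sd``,
    again around ``expr_mean``.

    Returns
    -------
    (gene_expr, mirna_expr) : genes x samples and miRNAs x samples frames.
    """
    rng = child_rng(config.seed, "expression")
    samples = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    tf_dev = {t: rng.standard_normal(config.n_samples) for t in truth.tfs}
    mirna_dev = {m: rng.standard_normal(config.n_samples) for m in truth.mirnas}
    target_dev = {}
    for g in truth.targets:
        signal = np.zeros(config.n_samples)
        for (t, tg), coef in truth.tf_gene_edges.items():
            if tg == g:
                signal += coef * tf_dev[t]
        for (m, mg), coef in truth.mirna_gene_edges.items():
            if mg == g:
                signal += coef * mirna_dev[m]
        target_dev[g] = signal + rng.normal(0.0, config.noise_sd, config.n_samples)

    mu = config.expr_mean
    gene_expr = pd.DataFrame(
        {**{t: mu + v for t, v in tf_dev.items()}, **{g: mu + v for g, v in target_dev.items()}},
        index=samples,
    ).T
    mirna_expr = pd.DataFrame(
        {m: mu + v for m, v in mirna_dev.items()}, index=samples
    ).T
    gene_expr.index.name = "gene"
    mirna_expr.index.name = "mirna"
    return gene_expr, mirna_expr


def generate_survival(
    expr: pd.DataFrame,
    betas: dict[str, float],
    baseline_hazard: float,
    censor_rate: float,
    seed: int,
) -> SurvivalTable:
    """Exponential survival times with log-hazard linear in expression.

    Sample s has hazard ``baseline_hazard * exp(sum betas_g * z_{g,s})``
    with z the per-gene z-normalized expression.  Censoring is an
    independent exponential time whose rate is calibrated so the expected
    censored fraction matches ``censor_rate`` at the mean hazard
    (``censor_rate`` 1 censors everything, 0 nothing).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    from .stats_core import z_normalize

    rng = child_rng(seed, "survival")
    samples = list(expr.columns)
    eta = np.zeros(len(samples))
    if betas:
        sub = expr.loc[sorted(betas)]
        z, _ = z_normalize(sub)
        for g, beta in betas.items():
            eta += beta * z.loc[g].to_numpy()
    hazard = baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate >= 1.0:
        return SurvivalTable(
            samples=tuple(samples), time=event_time, event=np.zeros(len(samples), int)
        )
    if censor_rate <= 0.0:
        return SurvivalTable(
            samples=tuple(samples), time=event_time, event=np.ones(len(samples), int)
        )
    # with censor hazard mu, P(censored | lambda_s) = mu / (mu + lambda_s);
    # solve mean_s of that = censor_rate so the expectation holds under
    # hazard heterogeneity
    from scipy.optimize import brentq

    censor_hazard = brentq(
        lambda mu: (mu / (mu + hazard)).mean() - censor_rate,
        1e-12 * hazard.mean(),
        1e12 * hazard.mean(),
    )
    censor_time = rng.exponential(1.0 / censor_hazard, size=len(samples))
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return SurvivalTable(samples=tuple(samples), time=time, event=event)


def generate_drug_response(
    expr: pd.DataFrame,
    drug_effects: dict[tuple[str, str], float],
    noise_sd: float,
    seed: int,
    drugs: tuple[str, ...] | None = None,
    intercept: float = 0.5,
) -> pd.DataFrame:
    """Sample x drug response matrix (AUC-like; lower = more sensitive).

    ``AUC(s, d) = intercept + sum_g effect(g, d) * centred_expr(g, s) +
    Gaussian(0, noise_sd)``; expression is centred per gene so the
    intercept sets the response scale.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    rng = child_rng(seed, "drugs")
    if drugs is None:
        drugs = tuple(sorted({d for _, d in drug_effects}))
    samples = list(expr.columns)
    centred = expr.sub(expr.mean(axis=1), axis=0)
    out = pd.DataFrame(
        rng.normal(intercept, noise_sd, size=(len(samples), len(drugs))),
        index=samples,
        columns=list(drugs),
    )
    for (g, d), coef in drug_effects.items():
        if g in centred.index and d in out.columns:
            out[d] += coef * centred.loc[g].to_numpy()
    out.index.name = "sample"
    return out


def generate_promoters(
    pwm,
    n_seq: int,
    length: int,
    plant_rate: float,
    seed: int,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Uniform-background promoter sequences with planted PWM sites.

    Each sequence independently carries, with probability ``plant_rate``,
    one site sampled from the PWM's per-position base distributions at a
    uniformly random position on the forward strand.  The manifest records
    the ground-truth (seq_id, start, strand) of every planted site.

    Returns
    -------
    (records, manifest) : list of (id, sequence) and the site manifest.
    """
    from .motif_scan import BASES

    rng = child_rng(seed, "promoters")
    freqs = pwm.raw_frequencies()  # true motif distribution, no pseudocount
    w = freqs.shape[0]
    records = []
    rows = []
    for i in range(n_seq):
        seq_id = f"promoter{i + 1:04d}"
        seq = rng.choice(list(BASES), size=length, p=[0.25] * 4)
        if length >= w and rng.random() < plant_rate:
            start = int(rng.integers(0, length - w + 1))
            site = [BASES[rng.choice(4, p=freqs[j])] for j in range(w)]
            seq[start : start + w] = site
            rows.append({"seq_id": seq_id, "start": start, "strand": "+"})
        records.append((seq_id, "".join(seq)))
    manifest = pd.DataFrame(rows, columns=["seq_id", "start", "strand"])
    return records, manifest


# ---------------------------------------------------------------------------
# file IO (all plain text; round-trips bit-exactly through these readers)


def write_expression_tsv(expr: pd.DataFrame, path) -> None:
    # %.17g keeps float64 round-trippable so readers recover identical bits
    expr.to_csv(path, sep="\t", index_label=expr.index.name or "gene",
                float_format="%.17g")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_survival_tsv(table: SurvivalTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_survival_tsv(path) -> SurvivalTable:
    return SurvivalTable.from_frame(
        pd.read_csv(path, sep="\t", float_precision="round_trip")
    )


def write_fasta(records, path, descriptions=None) -> None:
    """Write (id, seq) pairs as FASTA; descriptions are key=value strings."""
    with open(path, "w") as fh:
        for seq_id, seq in records:
            desc = f" {descriptions[seq_id]}" if descriptions else ""
            fh.write(f">{seq_id}{desc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def simulate(config: SimConfig, outdir=None) -> dict:
    """Run every generator under one master seed; optionally write files.

    Returns a dict with the truth, prior sources, expression matrices,
    survival table and drug-response matrix.  With ``outdir`` set, writes
    the standard TSV/JSON artefacts (expression, miRNA expression, edge
    lists, priors, survival, drug response, truth manifest).
    """
    truth = generate_truth(config)
    priors = generate_prior_sources(
        truth, config.n_sources, config.prior_recall, config.prior_fpr, config.seed
    )
    expr, mirna_expr = generate_expression(truth, config)
    survival = generate_survival(
        expr, truth.survival_betas, config.baseline_hazard, config.censor_rate, config.seed
    )
    drugs = generate_drug_response(
        expr, truth.drug_effects, config.drug_noise_sd, config.seed, drugs=truth.drugs
    )
    result = {
        "config": config,
        "truth": truth,
        "priors": priors,
        "expr": expr,
        "mirna_expr": mirna_expr,
        "survival": survival,
        "drug_response": drugs,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_expression_tsv(expr, outdir / "expression.tsv")
        write_expression_tsv(mirna_expr, outdir / "mirna_expression.tsv")
        write_survival_tsv(survival, outdir / "survival.tsv")
        drugs.to_csv(outdir / "drug_response.tsv", sep="\t")
        edge_rows = []
        for cls, edges in (
            ("TF", truth.tf_gene_edges),
            ("miRNA", truth.mirna_gene_edges),
            ("TF", truth.tf_mirna_edges),
            ("miRNA", truth.mirna_tf_edges),
        ):
            for (a, b), coef in sorted(edges.items()):
                edge_rows.append(
                    {"regulator": a, "target": b, "regulator_class": cls, "coef": coef}
                )
        pd.DataFrame(edge_rows).to_csv(outdir / "true_edges.tsv", sep="\t", index=False)
        prior_rows = [
            {"regulator": m, "target": g, "regulator_class": "miRNA", "source": name}
            for name, pairs in priors.items()
            for m, g in sorted(pairs)
        ]
        pd.DataFrame(prior_rows).to_csv(outdir / "prior_edges.tsv", sep="\t", index=False)
        manifest = asdict(truth)
        manifest["tf_gene_edges"] = {f"{a}->{b}": c for (a, b), c in truth.tf_gene_edges.items()}
        manifest["mirna_gene_edges"] = {
            f"{a}->{b}": c for (a, b), c in truth.mirna_gene_edges.items()
        }
        manifest["tf_mirna_edges"] = {
            f"{a}->{b}": c for (a, b), c in truth.tf_mirna_edges.items()
        }
        manifest["mirna_tf_edges"] = {
            f"{a}->{b}": c for (a, b), c in truth.mirna_tf_edges.items()
        }
        manifest["drug_effects"] = {f"{g}|{d}": c for (g, d), c in truth.drug_effects.items()}
        (outdir / "truth.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return result
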