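# triadnet

Pan-cancer co-regulatory network analysis for gene families, built around
miRNA–TF **feed-forward loops (FFLs)**: a transcription factor (TF) and a
miRNA that both regulate a common target gene while also regulating one
another. `triadnet` implements the full analytical chain as a tested,
reusable Python library:

1. **Prior integration** — miRNA→target interaction pairs from multiple
   prediction databases are kept when supported by at least two sources.
2. **Promoter motif scanning** — TF→gene edges are called by scanning
   promoter windows (−1000 to +200 bp around the TSS, coding strand) with
   JASPAR-format PWMs on both strands; a hit's p-value is the exact
   background tail probability of its log-odds score, computed by dynamic
   programming, retained at p < 1e−5.
3. **FFL construction and refinement** — triads (t, m, g) with t→g, m→g
   and a TF–miRNA cross edge are enumerated and classified (TF-FFL /
   miRNA-FFL / composite-FFL), then refined per sample group with signed
   Spearman filters on expression: miRNA→gene edges need Rs < 0 with
   p < 0.05, TF→gene edges Rs > 0 with p < 0.05.
4. **Network topology** — Maximal Clique Centrality,
   MCC(v) = Σ_{C ∋ v} (|C|−1)! over maximal cliques, defines hub genes and
   the top-k core subnetwork; Markov clustering (MCL) extracts modules;
   degree and exact betweenness label hubs and bottlenecks.
5. **Hazard-weighted scoring** — each family gene is screened by
   univariate Cox regression on z-normalized log2 expression; the
   per-patient score is

       score(s) = (1/n) Σ_{g ∈ significant genes} e_{g,s} · HR_g

   the HR-weighted mean of z-normalized expression over genes with a
   significant hazard ratio. Patients are stratified at the maximally
   selected log-rank cut-point and compared by Kaplan–Meier / log-rank.
6. **Drug association** — expression or score is screened against drug
   response (AUC; lower = more sensitive) with Spearman correlation and
   BH FDR: |Rs| > 0.25 (genes) or |Rs| > 0.3 (score) at FDR < 0.05, with
   negative correlations labelled *sensitive* and positive *resistant*;
   multi-layer (mRNA / protein / methylation / mutation / SCNA) bias
   between score groups is tested by rank-sum or Fisher exact tests.

Because the real cohorts behind such analyses (TCGA, GDSC, …) require
large downloads, `triadnet` ships a first-class synthetic-data module that
generates every pipeline input with planted ground truth — regulatory
edges with signed linear effects, multi-source priors with controlled
recall/false-positive rates, exponential survival with expression-linked
hazards, linearly coupled drug response, and promoters with planted PWM
sites — so every stage is validated end-to-end against known structure.

## Worked example

```python
from triadnet.synthetic_data import SimConfig, simulate
from triadnet.grn_ffl import enumerate_ffls, refine_ffls
from triadnet.stats_core import z_normalize
from triadnet.ptpscore_survival import (
    cox_univariate, select_significant, ptp_score, optimal_cutpoint, km_logrank,
)
from triadnet.drug_assoc import gene_drug_screen

sim = simulate(SimConfig(seed=1))          # 200 samples, planted truth
truth = sim["truth"]

triads = enumerate_ffls(truth.tf_gene_edges, truth.mirna_gene_edges,
                        truth.tf_mirna_edges, truth.mirna_tf_edges)
refined = refine_ffls(triads, sim["expr"], sim["mirna_expr"])
print(f"{len(triads)} raw FFL triads -> {len(refined.triads)} refined")

z, _ = z_normalize(sim["expr"].loc[list(truth.targets)])
estimates = [cox_univariate(z.loc[g].to_numpy(), sim["survival"], gene=g)
             for g in z.index]
roster = select_significant(estimates)
scores = ptp_score(z.loc[roster], {e.gene: e for e in estimates})
cut = optimal_cutpoint(scores.scores.to_numpy(), sim["survival"])
lr = km_logrank((scores.scores.to_numpy() > cut.cutpoint).astype(int),
                sim["survival"])
print(f"{len(roster)} genes with significant HR; cut-point {cut.cutpoint:.3f} "
      f"(high n={cut.n_high}); log-rank chi2={lr.chi_sq:.1f}, p={lr.p_value:.2e}")

screen = gene_drug_screen(sim["expr"], sim["drug_response"])
n_sens = sum(a.label == "sensitive" for a in screen.associations)
print(f"{len(screen.tested)} gene-drug pairs tested; {len(screen.associations)} "
      f"associations ({n_sens} sensitive)")
```

Output:

```
34 raw FFL triads -> 34 refined
14 genes with significant HR; cut-point 0.011 (high n=90); log-rank chi2=45.9, p=1.25e-11
200 gene-drug pairs tested; 120 associations (72 sensitive)
```

All 34 planted triads carry real regulatory effects and survive the signed
correlation filters; 14 of the 20 family genes have a significant hazard
ratio (6 of the 20 carry a planted log-hazard effect of ±log 2, and genes
downstream of them inherit risk through shared regulators); the score
split separates survival sharply (log-rank p ≈ 1e−11); the drug screen
recovers the planted expression–response couplings with the expected
sensitive/resistant signs.

There is also a CLI mirroring the library stages:

```bash
triadnet simulate --seed 1 --outdir sim/
triadnet scan --pwm motifs.jaspar --fasta promoters.fa --pvalue 1e-5 --out hits.tsv
triadnet ffl --edges sim/edges --expr sim/expression.tsv \
    --mirna-expr sim/mirna_expression.tsv --out triads.tsv
triadnet score --expr sim/expression.tsv --clinical sim/survival.tsv --out scores.tsv
triadnet drugs --expr sim/expression.tsv --response sim/drug_response.tsv --out assoc.tsv
```

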