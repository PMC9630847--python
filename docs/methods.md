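# Methods

This note documents the models, conventions and design choices behind
`triadnet`, in the spirit of a statistical software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Regulatory model and FFL taxonomy

The pipeline models a gene family regulated by transcription factors
(activation, positive linear effect on log2 expression) and miRNAs
(repression, negative effect). A feed-forward loop (FFL) is a triad
(TF t, miRNA m, gene g) with t→g, m→g and at least one TF–miRNA cross
edge; the cross-edge direction defines the type:

| type          | cross edges        |
|---------------|--------------------|
| TF-FFL        | t→m only           |
| miRNA-FFL     | m→t only           |
| composite-FFL | both t→m and m→t   |

The three types partition the triad set. Enumeration is exact (indexed
join over target-sharing regulator pairs) and is property-tested against
brute-force triple-loop enumeration.

### Prior integration

miRNA→target pairs from k ≥ 2 prediction sources are retained when
present in at least `min_sources` (default 2) distinct sources — the
standard at-least-two-databases rule. With per-source recall r the
retention probability of a true pair is 1 − (1−r)^k − k·r·(1−r)^(k−1);
the synthetic sources are calibrated so this closed form is testable.

### Expression-based refinement

Within each sample group, every triad edge is tested by Spearman
correlation: miRNA→gene edges must show Rs < 0 with p < 0.05, TF→gene
edges Rs > 0 with p < 0.05, and a triad survives only if all filtered
edges pass (strict AND; configurable). **By default only the two
target-incident edges are filtered.** Applying the sign rules to the
cross edges of a composite triad is unsatisfiable — the single
corr(t, m) value cannot be simultaneously positive (for t→m) and negative
(for m→t) — so composite FFLs could never survive; cross-edge filtering
is therefore opt-in (`filter_cross_edges=True`), and cross-edge
correlations are always recorded in the triad statistics. Under null
expression each filtered edge passes with probability ≈ 0.025 (one-sided
sign × significance), so a triad survives with probability ≈ 6e−4; this
calibration is checked by simulation.

Degenerate inputs (missing features, constant expression rows) skip the
triad with a reason code instead of raising.

## Promoter scanning

Promoter windows are [TSS−1000, TSS+200) on the coding strand (0-based,
half-open; minus-strand genes use the reverse complement of the mirrored
window), truncated with a flag at contig ends. PWM columns are
regularised with a total pseudocount (default 0.8) split across bases in
proportion to the background (default uniform 0.25), then scored as
log2(frequency/background).

Score p-values are exact on a discretized scale: matrix entries are
rounded to integer multiples of 1e−3 (log2-odds units) and the full score
distribution under the background is obtained by dynamic programming over
positions; P(score ≥ s) is then an exact tail sum. For widths ≤ 6 the DP
is verified against exhaustive enumeration of all 4^w words. A threshold
above the maximum attainable score yields p = 0.0 exactly (documented
convention). Scanning scores every window on both strands (reverse-strand
scores via the reverse-complemented matrix) and retains hits with
p strictly below the threshold (default 1e−5). Edge calling collapses
hits to one TF→gene edge per promoter with the best hit p-value as
evidence; it is idempotent and order-independent.

Synthetic promoters sample planted sites from the *raw* motif frequencies
(no pseudocount): the pseudocount is a scanning regularisation, not part
of the ground-truth motif.

## Network topology

FFL triads are projected to an undirected simple graph (one edge per
regulator–target pair; the projection is a documented choice, and the
directed triad lists remain available). Maximal cliques come from
Bron–Kerbosch with pivoting; MCC(v) = Σ(|C|−1)! over maximal cliques
containing v, with isolated nodes scored 0. The top-k core is the induced
subgraph of the k highest-MCC nodes, ties broken lexicographically.

MCL adds unit self-loops, column-normalises, and alternates expansion
(matrix squaring) with inflation (entrywise power, default 2.0, plus
renormalisation) until the max entry change falls below 1e−6 or 100
iterations (non-convergence returns the current clustering with a flag).
Clusters are read from attractor rows; each node joins the attractor
receiving most of its column flow, and attractors sharing flow merge, so
the result is always a partition. Higher inflation produces finer
clusterings.

Hubs and bottlenecks are nodes strictly above configurable quantiles
(default 0.9) of degree and exact Brandes betweenness respectively.

## Hazard-weighted scoring and stratification

Expression is log2-scale, z-normalized per gene with the **sample**
standard deviation (ddof = 1); constant genes become all-zero rows and
are flagged. Each gene is screened with a univariate Cox
proportional-hazards model — a Newton–Raphson maximiser of the partial
likelihood with **Breslow** tie handling by default (Efron available),
reporting HR = exp(β) and a two-sided Wald p. The solver is cross-checked
against lifelines in the test suite. Zero observed events raise an
explicit error; constant covariates and non-converged fits are flagged,
never silently zeroed.

Genes with Wald p < 0.05 form the score roster (an empty roster is
signalled). The per-patient score is the mean over roster genes of
z-normalized expression times the gene's HR — i.e. *n* in the 1/n
prefactor is the number of significant genes, giving a per-patient
average over the gene roster (the only reading that yields a per-patient
quantity). Scoring enforces that its input is z-normalized (unit sample
or population sd per row) rather than trusting the caller.

The cut-point is the score value maximising the two-group log-rank
statistic among splits leaving at least `minprop` (default 0.1) of
samples on each side — the maximally selected rank statistic, as in
survminer, without the Hothorn–Lausen correction; the associated p-value
is therefore selection-biased and flagged as descriptive. Ties break
toward the lower cut-point; `minprop=0.5` forces the median split. The
log-rank statistic is a vectorised Mantel–Haenszel computation, verified
against lifelines and a hand-worked six-sample event table; Kaplan–Meier
curves for plotting come from lifelines.

## Drug-response screens

Spearman correlations between features (genes or the score) and response
(AUC-like; lower = more sensitive) use a rank-matrix formulation with the
two-sided t-approximation, falling back to pairwise-complete per-pair
computation when response values are missing. BH adjustment spans all
tested pairs of one screen invocation (one FDR family per call).
Retention requires |Rs| strictly above the threshold (0.25 per-gene,
0.3 for the score) and FDR < 0.05; Rs < 0 is labelled *sensitive*,
Rs > 0 *resistant* — negating the response flips every label. Multi-layer
bias between high/low score groups uses the Wilcoxon rank-sum test (logFC
= difference of log2 group means; exact permutation p for small tie-free
groups) for continuous layers and Fisher's exact test for binary layers,
with BH within each layer; the high/low split defaults to the median.

## Synthetic cohorts: what they emulate and what they do not

Defaults encode the validation conditions: 5 TFs, 5 miRNAs, 20 family
genes, edge density 0.3, 200 samples, effect size 1.0 (log2 units) vs
noise sd 0.3, 20% censoring, 4 prior sources at recall 0.9 / FPR 0.05,
8 drugs, 30% of genes with survival effects of ±log 2, drug effects ±1.0
with noise sd 0.3, baseline hazard 0.05, baseline expression 8 (log2
scale). One integer master seed drives everything; each component uses a
child generator `default_rng(SeedSequence(seed, spawn_key=(k,)))` with a
fixed component index k, so stages regenerate independently and outputs
are identical across platforms.

Regulator expression is i.i.d. Gaussian; targets are exact linear
combinations of their regulators plus Gaussian noise. Survival times are
exponential with log-hazard linear in z-normalized expression; censoring
is an independent exponential whose rate is solved (Brent root-finding)
so the expected censored fraction equals the requested rate under the
realised hazard distribution. Drug response is linear in centred
expression. When all node classes have ≥ 2 members and density ≥ 0.5,
one triad of each FFL type is planted deterministically on top of the
Bernoulli edges so every motif class is always exercised.

Deliberately **not** modelled: read-level RNA-seq counts and library-size
effects, miRNA biogenesis, copy-number segments, cyclic feedback in
expression (cross-regulatory TF–miRNA edges do not propagate into the
expression model; their correlations are null unless induced by shared
targets), non-proportional hazards, and dose–response curve shapes.
Passing tests therefore demonstrate correctness of the statistical
machinery and calibrated recovery under the stated generative model, not
robustness to the full messiness of real tumor cohorts.

## Numerical conventions

- Spearman: mid-ranks for ties, t-approximation p (exact classical
  formula recovered on tie-free input); constant vectors flagged, never
  coerced to Rs = 0.
- BH: statsmodels step-up; input order preserved.
- Wilcoxon: exact permutation p for small tie-free samples, tie-corrected
  normal approximation otherwise (`mannwhitneyu` auto).
- All files are plain text; expression/survival TSVs round-trip
  bit-exactly (`%.17g` writing, round-trip float parsing).
- Problem sizes in the validation scripts (e.g. 60-cohort refinement
  sweeps, 50-seed hazard recovery, 150-rep null screens) are chosen to
  make the binomial error of every reported rate small relative to its
  pass band while keeping a full run in the tens of seconds.
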