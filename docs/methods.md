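# Methods

## Scope and shape

`exomir` implements a biomarker-discovery workflow for stage-associated
exosomal miRNAs as a set of composable stages: expression preprocessing and
differential testing (`exprde`), stage-common/stage-specific partitioning
(`stagesets`), multi-database target-evidence consensus (`targetdb`),
bipartite network decomposition and vulnerability scoring (`tpoma`),
evaluation statistics (`evalstats`), ceRNA triangle inference (`cerna`), a
synthetic cohort generator with planted truth (`synthdata`), and an
orchestrator plus CLI (`pipeline`, `cli`). All artifacts are plain text
(TSV/SIF/JSON), so every intermediate is diffable.

## Differential expression

Input matrices are assumed background-corrected and normalised; preprocessing
masks negative and missing intensities, drops all-missing features, imputes
the rest from the k = 5 nearest feature profiles (Euclidean distance over
shared samples, mean of neighbour values, feature-median fallback), and
applies log2(x + 1) unless the data are already on log2 scale. k-nearest
imputation was chosen as a concrete, well-understood realisation of generic
"interpolation" for microarray intensities.

Each stage is contrasted against healthy with a moderated t. Per feature, the
pooled two-group variance s² with d = n₁ + n₀ − 2 residual df is shrunk
toward a scaled inverse-chi-square prior (d₀, s₀²) fitted by method of
moments on z = log s²: with e = z − ψ(d/2) + log(d/2), the excess of
Var(e) over ψ′(d/2) determines d₀ via trigamma inversion (Newton iteration),
and s₀² follows from the mean of e. The moderated statistic uses the
posterior variance (d₀s₀² + ds²)/(d₀ + d) with d₀ + d df. When the observed
log-variances show no excess dispersion the prior df is infinite and s₀² is
the geometric mean of s², which makes the degenerate identical-variance case
collapse exactly onto the ordinary pooled t (a deliberate convention, tested).
Zero-variance features are handled by the shrinkage itself — the posterior
variance never vanishes while s₀² > 0.

The differential filter is **raw** p < 0.05 (strict) and |log₂FC| > 1
(strict), with log₂FC oriented case − control and healthy always the control.
Raw p is the workflow's stated operating point; Benjamini–Hochberg adjustment
is available behind a flag (`use_adjusted`). Two-group stage comparisons use
the Wilcoxon rank-sum with midranks and tie-corrected normal approximation;
more than two groups use Kruskal–Wallis.

## SC/SS partitioning

Membership is by miRNA identity across the five stage-vs-healthy threshold
sets: SC = intersection of all five, SS(s) = present in stage s only. miRNAs
differential in 2–4 stages are reported as *intermediate* and belong to
neither — the Venn reading of the five-way comparison. Direction is ignored
by default; a strict mode additionally requires a consistent sign across all
five contrasts before granting SC status.

## Target-evidence consensus

Evidence records are one claim per (database, miRNA, gene). The confidence
filter keeps, within each prediction database, records at or below that
database's top-20 % score quantile (ties at the boundary included). The cut
is per database, not pooled, because confidence scales are not comparable
across sources; a pooled variant exists behind `--global-top-frac`.
Conserved-only databases additionally require the conserved-site flag.
Validation-type records carry no score and bypass the confidence filter. The
vote keeps a pair supported by ≥ 4 distinct prediction databases **or** ≥ 2
distinct validation databases; duplicate (pair, database) records count once.

## Network decomposition and scoring

The miRNA → gene network is a duplicate-free edge set restricted to the
miRNA set of interest; gene indegree is counted **within that restriction**.
Genes split into single-line (indegree 1) and hotspot (indegree ≥ 2) classes
— disjoint and jointly covering all targeted genes. Per-miRNA scores:

- NGM — all targets;
- NGSM — single-line targets;
- NCGSM — disease-relevant single-line targets;
- NCGSM-TF — disease-relevant single-line targets in the TF catalog.

The chain NCGSM-TF ≤ NCGSM ≤ NGSM ≤ NGM holds by construction and is
property-tested on random graphs, as is the conservation identity
Σ NGSM = #(indegree-1 genes). Candidate miRNAs are ranked by descending
(NCGSM-TF, NCGSM, NGSM) with alphabetical tie-break — the NGSM tie-break is
what reproduces the published top-26 table's printed row order exactly.
Candidate hotspot genes are the disease-relevant hotspot genes with
indegree ≥ 5, where indegree is counted in the relevance-filtered hotspot
network of the SC miRNAs (not the global network). Relevance filtering is
applied after decomposition. Stage subnetworks connect each stage's SS
miRNAs to the disease-relevant targets exclusive to that stage (targeted by
no other stage's SS set).

## Evaluation statistics

- **AUC** via the Mann–Whitney midrank identity U/(n₁n₂); auto-direction
  reports max(AUC, 1 − AUC) with the favoured direction recorded, matching
  common ROC tooling. Stage-AUC is one-vs-rest among tumor samples only.
- **Combined models**: logistic regression with a small L2 penalty
  (λ = 10⁻⁶, i.e. C = 10⁶) so the fit exists under complete separation;
  scored in-sample by rank AUC.
- **Survival**: Kaplan–Meier product-limit curves and the two-group log-rank
  chi-square (Σ(O − E))²/ΣV on 1 df, with a mean expression split for miRNAs
  (median for genes/cell lines; both rules exposed).
- **Drug response**: Welch two-sided t-test of IC50 between median-split
  expression groups (Welch is the safer default for 11-per-arm cell-line
  panels; Student's is available). Direction reports the more resistant group.
- **Spearman** with midranks and the t approximation on n − 2 df; constant
  vectors raise a degeneracy error rather than returning NaN.
- **Over-representation**: upper-tail hypergeometric per user-supplied gene
  set with BH adjustment across sets (a generic stand-in for annotation-based
  enrichment, which needs external releases).

ceRNA triangles require all three edges: consensus target (m, G), validated
interaction (m, L), and positive co-expression ρ(L, G) > 0 at raw p < 0.05
(unadjusted, per the screening convention; BH can be applied downstream).
Correlations are computed on the tumor-sample panel.

## Synthetic cohort: what it emulates

Defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| group sizes | healthy 11, I 20, II 20, IIIA 20, IIIB 16, IV 12 | serum-cohort composition of the workflow's reference dataset |
| n_mirnas | 300 | array-scale panel, small enough for fast tests |
| effect_log2fc / sigma | 2.0 / 0.7 | clearly detectable shift at these group sizes |
| sc_frac / ss_frac | 0.10 / 0.10 | tens of planted markers per class |
| n_pred_dbs / n_valid_dbs | 8 / 3 (3 conserved-only) | the 11-database voting layout |
| db_sensitivity / db_fpr | 0.8 / 0.01 | good-but-imperfect per-database detection |
| relevance_frac / tf_frac | 0.3 / 0.2 | minority of genes disease-relevant / TFs |
| hazard_beta / censor_rate | 1.0 / 0.3 | marked prognostic signal, realistic censoring |
| n_cell_lines / ic50_delta | 22 / 1.0 | small cell-line panel with a detectable response shift |
| n_cerna_samples / n_triples | 100 / 15 | enough samples for stable rank correlations |

Expression is Gaussian on the log2 scale with per-miRNA baselines; SC miRNAs
are shifted by ±effect in all five stage groups, each SS miRNA in exactly
one, signs random and recorded in the truth ledger. True target pairs give
each gene indegree 1 with probability 0.35, else 2–6 uniform; single-line
genes are ledgered per regulator. Evidence scores are p-value-like: true
pairs Uniform(0, 0.2), false pairs Uniform(0, 1), so the top-20 % cut is
meaningful. Planted relevant genes score in (5, 20] with the direct flag and
all other genes fail the (score > 5 AND direct) predicate, so the filter
recovers the planted set exactly. Survival times are exponential with hazard
h₀·exp(β·x) on standardised marker expression (h₀ = 1/730 d⁻¹) with
independent exponential censoring calibrated to the target censoring
fraction. IC50 shifts by ic50_delta between high/low expression halves of the
designated gene. ceRNA triangles share a latent factor between lncRNA and
mRNA (correlation ≈ 0.67 at the default noise), drawn from SC miRNAs' pairs
to mirror the key-miRNA focus of the downstream analysis. The
sensitivity/false-positive parameterisation of database evidence is this
package's own construction — no noise model for database claims exists to
copy. All randomness derives from `default_rng([seed, op_index])`, so
identical config + seed is byte-reproducible.

Not emulated: microarray batch effects and probe cross-hybridisation,
empirical inter-miRNA correlation, database-specific score distributions,
cohort-level confounding. Passing tests therefore demonstrate correctness of
the algorithms and calibration of the statistics under the stated generative
model — not performance on real serum cohorts.

## Problem sizes and numerical choices

The default configuration (300 miRNAs × 99 samples, 800 genes, ~2,400 true
pairs) runs the full pipeline in a few seconds; recovery checks use 5–10
fixed seeds and calibration checks 200 simulations / 10,000 null features —
sizes chosen to make Monte-Carlo error small relative to the acceptance
bands while keeping the suite quick. Trigamma inversion runs Newton to
1e-8 relative tolerance. Quantile ties at the confidence boundary are kept.
All ranking ties break alphabetically for determinism. Degenerate inputs
(constant vectors, all-identical splits, empty classes) raise typed errors
(`DegenerateStatisticError`, `InputError`) rather than propagating NaN.

## Known limitations

- The vulnerability-score acronym semantics are operational definitions
  reverse-engineered from the published top-26 table's monotone structure;
  they reproduce its printed order but are not an authoritative expansion.
- Replication against the original GEO/TCGA/CCLE cohorts requires external
  downloads and version-pinned database snapshots and is documented, not
  automated; the published headline counts (89 SC / 94 SS, 7,306 pairs,
  96.8 % AUC, …) are not desk-reproducible from this repository.
- At the default scaled-down network size, few hotspot genes reach
  indegree ≥ 5, so the pipeline's gene candidate list is usually empty; the
  hotspot ranking is validated on the printed-table fixture instead.
- In-sample AUC only; no cross-validation, Cox regression, or time-dependent
  ROC. The "survival after 3 years" landmark analysis is not implemented
  beyond a configurable time-window filter.
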