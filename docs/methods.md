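# Methods

This note describes the statistical model behind each stage of `ocsubtypes`,
the default parameters and why they were chosen, the numerical decisions
that matter for reproducibility, and known limitations.

Notation: expression values are log2-scale throughout unless stated
otherwise; matrices are genes × samples.

## 1. Synthetic data with planted structure

`generate_bulk` simulates a multi-cohort bulk expression study in which
every downstream claim can be checked against ground truth.

**Model.** Each gene g has a baseline level `base_g ~ N(baseline_mean,
baseline_sd²)` (defaults 7, 1 — typical log2 microarray intensities). The
stromal profile is the baseline perturbed at the gene level,
`stroma_g = base_g + N(0, compartment_sd²)` with `compartment_sd = 0.5`:
cancer and stroma share most of their transcriptome and differ by well under
one baseline SD per gene, as real compartments do. Each subtype s gets a
cancer profile `cancer_{s,g} = base_g + effect_size·1[g ∈ sig_s]`, where the
signature blocks (default 40 genes per subtype, `effect_size = 1.5`) are
disjoint. A separate 15-gene stromal block is elevated in the stroma
profile. A tumor sample i of subtype s with purity `p_i ~ U(0.4, 0.9)` is

```
x_ig = p_i · cancer_{s,g} + (1 − p_i) · stroma_g + batch_{c(i)},g + ε_ig
```

with per-cohort batch shifts `N(0, batch_sd²)` (default 0.5) and noise
`N(0, noise_sd²)` (default 0.5). Normal samples carry no cancer
compartment: their profile is `stroma_g + N(0, (compartment_sd/2)²)` plus
sample noise. Consequently the expected tumor-vs-normal log-fold-change of
a planted gene is mean-purity × effect_size — the attenuation any purity
mixture imposes — which the differential-gene tests account for.

**Why these defaults.** Signature blocks must carry enough aggregate signal
for a 200-sample cohort to dominate the purity axis of variation (purity is
itself a strong, biologically real expression gradient): 40 genes at effect
1.5 against 300 genes at noise 0.5 puts consensus clustering in a regime
where the planted k wins clearly but not trivially. Purity below 0.4 makes
samples mostly stroma and subtype recovery ill-posed, matching the common
practice of excluding low-purity samples.

**Survival.** Event times are exponential with per-subtype hazard
multipliers (defaults 3.0, 0.5, 1.0, 1.5 — one clearly poor and one clearly
good prognosis subtype). Censoring times are `U(0, M)` with M solved by
Brent's method so the expected censoring fraction matches
`censoring_rate = 0.3`.

**Single cells.** `generate_singlecell` draws malignant and non-malignant
cells per disease stage (primary/relapse/metastasis); each malignant cell
gets a latent subtype from a stage-specific mixture and a
`signature_shift` (default +1 log2) on that subtype's signature genes over
a `N(2, 0.5²)` baseline with cell noise 0.5 — single-cell scale values with
realistic per-cell dispersion.

## 2. Cohort integration

`merge_cohorts` intersects gene sets (lexicographic order) and concatenates
samples. `adjust_batch` is a deliberately simple, transparent stand-in for
ComBat: per gene, each cohort's values are centered at the cohort mean,
rescaled from the within-cohort SD to the **pooled within-cohort SD**
`sqrt(Σ_c (n_c − 1) s_c² / (N − C))`, and re-centered at the pooled mean.
Targeting the pooled within-cohort SD (rather than the overall SD) makes
the map a fixed point, so the adjustment is exactly idempotent — applying
it twice changes nothing beyond floating-point error. It removes cohort
location/scale structure, which is what downstream clustering relies on,
but performs no empirical-Bayes shrinkage; with the default cohort sizes
(≥ ~30) the shrinkage ComBat would add is minor. Cohorts under
`min_cohort_size = 3` samples are rejected because a within-cohort SD from
fewer samples is meaningless.

`select_variable_genes` ranks genes by the unscaled median absolute
deviation (the 1.4826 consistency constant is omitted — ranking is
scale-invariant) with lexicographic tie-breaking for determinism.

## 3. Consensus NMF subtyping

For each k in 2..6 (`n_runs` restarts, default 30; the pipeline uses 10 for
speed):

1. **Nonnegativity prep** (`prep="split"`, the default): each gene is
   centered and its positive and negative parts become separate rows
   (`g+`, `g−`). This preserves below-baseline signal that a simple
   per-gene min-shift (`prep="shift"`, also available) compresses, and it
   removes the shared baseline component that otherwise dominates the
   first NMF factor.
2. Each run resamples 80% of genes without replacement
   (`gene_subsample = 0.8`). All samples are always retained, so the
   consensus matrix definition is unchanged; resampling decorrelates runs
   so the cophenetic coefficient discriminates between k values instead of
   saturating at 1 for several k.
3. NMF (scikit-learn, multiplicative updates, `tol = 1e-5`,
   `max_iter = 500`); samples are hard-assigned to their argmax component;
   the consensus matrix entry (i, j) is the fraction of runs co-assigning
   samples i and j.
4. The cophenetic coefficient correlates consensus distances (1 −
   consensus) with the cophenetic distances of their average-linkage
   hierarchical clustering (scipy). The chosen k maximizes it; ties prefer
   smaller k.
5. Hard labels come from cutting the dendrogram at k clusters, renamed
   C1..Ck by decreasing size. Silhouette widths on the consensus-distance
   matrix (singletons get width 0) define the retention filter
   (`threshold = 0`: any sample closer to another cluster than its own is
   dropped).

## 4. Differential and signature genes

`differential_genes` uses a moderated two-sample t statistic: the pooled
per-gene variance is shrunk 50/50 toward the genewise-median variance
(`shrink_weight = 0.5`), stabilizing small-sample estimates in the spirit
of limma without its full empirical-Bayes machinery; p-values are
Benjamini–Hochberg adjusted (statsmodels). A gene is "up" when logFC > 1
and FDR < 0.05 — the conventional twofold/5% thresholds.

Per subtype, **TT** = genes up versus the union of the other subtypes and
**TN** = genes up versus normals. `f_scores` is a vectorized one-way ANOVA
F per gene (constant genes get F = 0; degenerate infinite F is reported as
the largest finite F + 1 so rankings stay well-defined).

`subtype_signatures` intersects four sets per subtype: TT, TN, the top
`top_n` genes by cancer-compartment fold-change versus the mean of the
other subtypes' cancer compartments, and the top `top_n` by
cancer-compartment fold-change versus the normal profile (default
`top_n = 200`, the conventional signature-list scale at genome-wide gene
counts; use smaller values for small simulated universes).

**ssModules.** Module *detection* is treated as a pluggable upstream step;
any named gene lists with an optional parent-child hierarchy can be
screened. `module_overlap_test` is the exact hypergeometric upper tail
`P(X ≥ |module ∩ target|)` (scipy). A module qualifies when both its TT and
TN p-values are below `alpha = 0.05`; within a connected hierarchy chain
only the member with the smallest `p_TT · p_TN` survives (ties to the
smaller module), preventing nested modules from being reported twice.

## 5. Compartment deconvolution

Under the two-compartment model, `E[x_ig] = p_i·e^cancer_g +
(1 − p_i)·e^stroma_g` is linear in purity: a per-gene OLS of expression on
purity gives `e^stroma_g` as the intercept and `e^cancer_g` as intercept +
slope, computed in closed form for all genes at once. Guards: at least
`min_samples = 10` samples per subtype and purity SD ≥ 0.05, below which
the regression is ill-conditioned. Negative estimates are clipped at 0 (log
expression is nonnegative) and flagged per gene. On noiseless mixtures the
recovery is exact to machine precision; this is an acceptance criterion.

## 6. Relative crosstalk (RC)

Expression enters on the linear scale (`2^x − 1`, clipped at 0). For a
ligand L and receptor R in subtype s, the four direction products
`e^L_C·e^R_C, e^L_C·e^R_S, e^L_S·e^R_C, e^L_S·e^R_S` are normalized by
their sum, so the four RC scores sum to 1 exactly; a pair with all four
products zero is emitted with null scores rather than dropped silently,
and pairs missing from the profiles are counted in a `skipped` attribute.
`comprehensive_rc` averages directions across subtypes per pair;
`celltype_rc` applies the same construction to cell-type linear mean
expression in single-cell data (requiring ≥ 10 cells per type).

## 7. Single-cell subtype scoring

Genes are sorted by mean expression across cells (lexicographic
pre-sorting for determinism) and divided into `n_bins = 30` bins of
`floor(G/30)` genes, remainder in the last bin. For each signature,
`per_bin = 100` control genes are drawn from every bin containing a
signature gene — with replacement only when a bin is smaller than 100, and
flagged when so. The SC score of a cell is mean(signature) − mean(control),
which cancels cell depth and bin-level baseline; with `per_bin` equal to
the bin size and replacement off, the control is exactly the whole bin.

Cells are assigned to their argmax subtype. A cell is a **hybrid** (and
excluded from stage summaries) when all three hold: second-best score > 1,
second − third > 0.3, and second > 0.1 × first. Ties at the top are
assigned to the first subtype in order and flagged. `stage_proportions`
tabulates non-hybrid subtype fractions per disease stage;
`stage_de` reports genes up in relapse versus both primary and metastasis.

## 8. Risk modelling

The published ten-gene OSS model ships verbatim
(`published_model()`): MFAP4 0.0166, FBLN2 0.1858, IGF2 0.0227,
NME5 −0.0034, MGLL −0.1435, COLEC11 −0.0101, AGR2 −0.0415, TFF3 −0.0453,
PAEP −0.0199, DEFB1 −0.0275. OSS = Σ coefficient × expression; higher is
higher risk.

`fit_lasso_cox` re-derives such models: genes are z-scaled internally
(coefficients are reported back on the original scale), the penalty path
comes from a full-data Coxnet fit (scikit-survival, L1, 50 alphas), and the
penalty is chosen by K-fold (default 10) cross-validated partial-likelihood
deviance. The deviance is −2 × the Breslow log partial likelihood,
evaluated by hand with a log-sum-exp shift for numerical stability (the
scikit-survival scorer targets a different estimand). Per fold the solver
may truncate the path; only alphas fitted in every fold compete. The
default `rule="1se"` takes the largest alpha within one SE of the minimum
(parsimony); `rule="min"` takes the minimum, and the pipeline falls back to
it when the 1-SE choice zeroes every coefficient. Fits require ≥ 30 samples
and ≥ 10 events. The training cutpoint is the median OSS; `stratify`
labels OSS > cutpoint as high-risk, and `logrank_test` (lifelines)
compares the groups, validated against hand risk-set tabulation.

## 9. Pipeline and determinism

`run_pipeline` chains all stages, writing plain-text artifacts (TSV, GMT,
MTX triplet, CSV, JSON; floats at `%.10g`) and a `manifest.json` of SHA-256
hashes. Stage seeds are derived from the master seed via
`np.random.SeedSequence` reduced mod 2³¹ − 1. The manifest omits the output
directory so reruns of the same seed anywhere are byte-identical — an
acceptance criterion. A stage failure raises `RuntimeError` naming the
stage, with partial outputs retained.

## Limitations

- The batch adjuster removes location/scale effects only; no
  empirical-Bayes shrinkage, no covariate preservation.
- Coexpression module *detection* is out of scope; only the
  overlap-screening of supplied candidate modules is implemented.
- The simulators are Gaussian on the log scale — no count-level noise,
  dropout, or cohort-specific platform effects beyond location/scale.
- Deconvolution assumes purity is known and the two-compartment model
  holds per subtype; compartment profiles are subtype-level means, not
  per-sample estimates.
- The moderated t variance shrinkage uses a fixed 50/50 weight rather than
  an estimated prior.
- `fit_lasso_cox` assumes proportional hazards and right censoring;
  survival times must be positive and events binary.
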