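# Methods

## Cohort model

A cohort is a set of omic layers aligned by TCGA-style barcode. The
patient identifier is the first three dash-delimited barcode fields;
the fourth field's leading two digits encode the sample type (01–09
tumor, 10–19 normal; codes ≥ 20 denote control material and are
rejected rather than silently grouped). "Paired" means a patient
contributes both a tumor and a normal sample within one cancer type,
and paired analyses admit only cancers whose pair count is *strictly*
greater than 20 (default `paired_min_pairs=20`).

Layers are aligned lazily: each analysis intersects the sample
identifiers it needs, so partial cohorts (say, expression plus TMB
only) are legal. Missing clinical values are carried as explicit
missing markers, never imputed; every grouped analysis reports how many
samples it dropped and why.

### Ingest rules

* Duplicated samples within a (patient, group, cancer) class are
  reduced to one by a seeded uniform draw over the lexicographically
  sorted duplicates, so ingest is reproducible given the seed recorded
  in the bundle manifest. The last sample of a class is never removed.
* Genes with zero TPM in every sample are excluded, then values are
  stored as log2(TPM+1).
* Promoter methylation keeps only probes annotated TSS1500 *and*
  CpG-island; the per-gene promoter beta is the unweighted mean over
  kept probes, ignoring missing values (median available via the `how`
  option). Genes with no kept probe are absent from the layer.
* Protein-coding filtering is delegated to an optional user-supplied
  gene whitelist, since annotation versions vary.

## Statistical core

Every statistic is computed from its defining formula; scipy supplies
only distribution functions (normal, t, chi-square).

* **Mann–Whitney U** uses midranks. When min(n₁, n₂) ≤ 8 and no ties
  exist, the two-sided p comes from the exact rank-sum null obtained by
  dynamic-programming enumeration; otherwise from a normal
  approximation with tie and continuity corrections. At n₁ = n₂ = 8 the
  approximation sits within ~0.011 of the exact value at worst
  (typically far closer); exactness below that size is what the exact
  branch is for.
* **Wilcoxon signed-rank** drops zero differences, is exact (sign-
  pattern enumeration) for n ≤ 12 without ties in |d|, else normally
  approximated with tie correction.
* **Kruskal–Wallis** applies the standard tie correction and a
  chi-square reference with k−1 df.
* **Correlation**: Pearson, or Spearman as Pearson on midranks; p from
  t = r·√((n−2)/(1−r²)) with n−2 df. Constant input is an error, not a
  NaN.
* **BH** is the step-up procedure, applied within exactly one result
  family at a time (one pan-cancer table, one DEG table, one ORA
  table).
* **Cox regression** maximizes the Efron-corrected partial likelihood
  by Newton–Raphson with step-halving, stopping when the log-likelihood
  changes by < 1e-9 (at most 50 iterations). |β| > 15 is reported as a
  monotone-likelihood (perfect separation) diagnostic. The hazard ratio
  always concerns the gene covariate; age adjustment adds age as a
  second continuous covariate. In the pan-cancer forest, expression is
  standardized within each cancer's tumor samples, so HRs are per
  standard deviation and comparable across cancers (this deliberately
  differs from per-unit-expression HRs).
* **Kaplan–Meier** is the product-limit estimator; the **log-rank**
  test uses the observed-minus-expected statistic with hypergeometric
  variance per distinct event time.
* **ROC** enumerates all distinct thresholds, draws diagonal segments
  through ties, and integrates by trapezoid, which makes the AUC equal
  the midrank U/(n₁n₀) identity to machine precision.
* **ssGSEA** orders genes by decreasing expression with a deterministic
  tie-break (value, then symbol), weights in-set positions by
  (N − position)^α with α = 0.25, and sums the running difference of
  the in-set and out-of-set cumulative distributions over all
  positions. Only the ranking matters (monotone-transform invariant).
  The Stromal and Immune infiltration scores are ssGSEA scores of two
  signature gene sets; ESTIMATE is defined as their sum.
* **Preranked GSEA** uses the weighted Kolmogorov–Smirnov running
  statistic (weight exponent 1 on |metric|), signed maximum deviation
  as ES, and a seeded gene-label permutation null (phenotype
  permutation is impossible for preranked input). p is computed within
  the matching-sign null pool with the +1 correction,
  (1 + #extreme)/(#same-sign + 1): conditioning only the count, not
  the pool, on sign would compress null p into (0, ½) and break
  calibration. NES divides ES by the mean |null ES| of matching sign;
  FDR is BH across sets; the leading edge collects in-set genes up to
  the ES extremum.
* **ORA** computes the upper hypergeometric tail with exact integer
  binomial arithmetic. The background for co-expression panels is the
  set of genes actually tested, not the genome, to keep the null
  honest.
* **DEG analysis** splits samples at the median of the index (ties to
  the low group), reports log2FC as the difference of group means on
  the stored log2 scale (the log2 fold change of geometric means of
  TPM+1), with Mann–Whitney p and BH q. Rank tests are the default for
  all boxplot-style group comparisons.

## Analysis conventions

Group tests require ≥ 3 samples per group per cancer; correlations
require ≥ 5 overlapping tumor samples; Cox fits require ≥ 10 events
(all logged in the output metadata). Correlation analyses use tumor
samples only — normals would confound tumor-microenvironment questions.
The two-group age split is at 65 years and the three-group split uses
age tertiles (both overridable); AJCC sub-stages collapse to I–IV and
"Stage X" becomes missing. KM and DEG median splits assign ties to the
low group, so split labels are a deterministic function of the values.
The GSEA ranking metric is the DEG log2FC. All stochastic procedures
take an explicit seed; there is no hidden global randomness.

## Synthetic cohort generator

The generator emulates the layer inventory of a real pan-cancer bundle
so the whole stack is testable offline.

* Per-gene baseline means on the log2(TPM+1) scale are drawn once from
  N(4.0, 1.5²), clipped below at 0.5; samples add N(0, 1²) noise, and
  values are clipped at 0 (negative log2 expression does not exist).
* Differential expression is a mean shift in the tumor samples of one
  cancer. Co-expression couples a gene's latent noise to an index
  gene's at a target correlation.
* TMB and MSI are nonnegative near-linear transforms of latents coupled
  to planted genes through a Gaussian copula, so the Pearson target is
  approached closely (the fixture realizes r = 0.56 for a 0.6 target at
  n = 400).
* Survival is exponential with per-patient log-hazard equal to the
  planted log HR times the standardized gene expression; censoring is
  independent uniform administrative censoring with a window solved for
  ≈ 30 % censoring at the baseline hazard (rescaled approximately for
  other rates).
* Promoter betas pass a logistic transform of the coupled latent, which
  attenuates the linear correlation slightly; plants are specified by
  target sign and magnitude.
* Immune cell ratios are Dirichlet draws; immune scores are computed by
  the real ssGSEA code path from two signature sets, so the ESTIMATE
  additivity invariant holds by construction, not by assignment.
* Barcodes use a `SYNT-` project field so they can never collide with
  real TCGA identifiers.

The reference fixture (seed 20240917, fixed in code) has four cancers —
BRCA 400T/60N with 30 pairs, COAD 60T/40N with 25, CHOL 35T/12N with 8,
LUAD 50T/10N with 3 — 500 genes including five immune gene families,
two ssGSEA signatures and three toy catalogs. Planted: log2FC 2 in COAD
(differential expression recovery), log2FC 3 in CHOL (a strong
diagnostic gene: at exactly 2 SD the expected AUC of 0.92 is too close
to the 0.9 acceptance line for a finite sample, so the diagnostic plant
is deliberately stronger), TMB r = 0.6 and MSI r = 0.5 in BRCA, log
HR 0.7 in BRCA, promoter-methylation r = −0.5 in BRCA, a 10-gene
co-expression module around G0050 in COAD (also a GO catalog set, for
GSEA/ORA recovery), one co-expressed pair in BRCA, and coupling of
G0080 to part of the immune signature (immune-score sign recovery).

What the generator does *not* emulate: realistic TPM marginal
distributions, gene–gene correlation structure beyond the planted
couplings, copy-number or mutational-signature effects, batch effects,
or non-proportional hazards. Passing tests therefore demonstrate that
the analysis stack recovers known effects under its own model
assumptions — not that those assumptions hold in real TCGA data.

## Numerical choices and problem sizes

Figures annotate only numbers carried in the analysis payload; nothing
is recomputed at render time. TSV outputs use fixed formatting so runs
are byte-reproducible. Test-suite simulations are sized for laptop-scale
runs: Cox calibration uses 100 fits of n = 120, GSEA calibration 200
seeds at 199 permutations on a 200-gene ranking, the ROC identity 1000
random fixtures, and exhaustive ssGSEA placement checks G = 12 with set
sizes 2 and 3.

## Known limitations

Efron is the only tie convention offered; time-dependent covariates and
multivariate signatures beyond age adjustment are out of scope, as are
moderated (limma/DESeq2-style) differential tests, optimal-cutpoint
survival scans, and pathway-topology methods. The heatmap/triangle and
radar renderings are functional approximations of the journal styles,
not pixel-faithful reproductions.
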