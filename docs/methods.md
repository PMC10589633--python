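# Methods

This note records the statistical models implemented in `raremics`, the
defaults and conventions that matter, what the bundled simulator does and
does not emulate, and the design choices made where the design was
genuinely open.

## Outlier calling

Each omic signal arrives as a features × individuals matrix per exam:
log2(TPM+2) expression, methylation beta values in (0,1) (transformed to
m-values m = log2(β/(1−β)) before correction), and natural-log normalized
protein fluorescence. Expression features are pre-filtered to those with
≥ 6 reads and TPM > 0.1 in ≥ 20% of individuals (boundaries inclusive for
reads and the fraction).

Residualization is a single per-feature OLS of the values on: k latent
technical factors (default k = 30, computed as the top right singular
vectors of the feature-centered matrix — the role hidden-factor methods
such as PEER play, here by a deterministic truncated SVD), genotype PCs
(11 by convention), age, sex, and optionally the strongest cis-QTL
genotype for that feature. Residuals are centered and scaled to Z within
each exam using the sample (ddof = 1) standard deviation. Missing values
are excluded pairwise; a feature needs ≥ 30 non-missing individuals and
non-zero residual variance to be scored; a singular design raises with
the collinear columns named. We make no attempt to pre-center before the
QTL term — it is one joint OLS per feature.

Joint calls across the two exams: over/under outlier requires |Z| above
the threshold (default 3) in *both* exams with consistent sign; controls
require |Z| < 1 in both; everything else is neither. Per signal,
individuals whose outlier count exceeds Q3 + 1.5·IQR of the
per-individual count distribution are removed entirely ("global
outliers"); quartiles use linear interpolation (type-7), the numpy
default, fixed here because the convention changes the fence on small
cohorts. Replication of exam-1 outliers is assessed at |Z| > 2 in exam 5,
sign-consistent when a direction is requested. Cross-omics sharing uses
the mean-across-exam Z in the second signal at a relaxed |Z| > 2
threshold plus a one-sided Wilcoxon rank-sum shift test.

Gene-level methylation aggregates CpG Z-scores by the median over CpGs
within 1.5 kb upstream of the gene's TSS, strand-aware (distance 0–1500 bp
inclusive on the upstream side). Coordinates are 0-based half-open
internally; 1-based inputs must be converted at the boundary. Probe
masking for variant-overlapping methylation probes is accepted as a
precomputed mask, not recomputed.

## Splicing outliers

Per junction cluster (individuals × junctions counts), junctions are
dropped when no sample reaches 15 reads or fewer than 40% of samples have
more than 3 reads; clusters reduced below two junctions are dropped.

A Dirichlet-Multinomial is fit by maximum likelihood with Minka's
fixed-point iteration on the concentration vector α (moment-matched
initialization, damping on overshoot, convergence at relative
log-likelihood change < 1e-8, cap 500 iterations; ≥ 2 junctions and ≥ 10
individuals with positive depth required). Each individual's deviation is
the Mahalanobis distance of their junction-proportion vector from the DM
mean μ = α/Σα under the DM proportion covariance *at that individual's
depth n*, Cov = (diag μ − μμᵀ)(n + A)/(n(1 + A)); the last junction
coordinate is dropped because proportions live on a simplex. The MD null
depends on depth and on cluster dimensionality, so p-values are empirical:
for each depth class present, 10,000 DM count vectors are drawn at that
depth and p = (1 + #{null MD ≥ observed}) / (n_draws + 1). The add-one
rule bounds p away from zero at 1/(n_draws+1). Drawing per depth class
(rather than one shared pool) is our choice; it keeps the null exact per
individual at modest extra cost. At 2,000 draws the discreteness of tied
MD values makes the uniformity of null p-values marginally detectable;
at the 10,000-draw default it is not, which is why the calibration checks
use 10,000.

Cluster p-values map to genes by p_m = min over the gene's c clusters and
P_gene = 1 − (1 − p_m)^c, the probability of a minimum that small among c
independent uniforms. Gene p-values convert to Z = max(0, Φ⁻¹(1 − p)):
splicing outliers carry no direction, so we adopt the one-sided
upper-tail mapping and report non-negative Z.

## Rare-variant enrichment

Variants are retained as rare when the cohort allele frequency, the
external (reference-panel) overall frequency, and every listed
subpopulation frequency are all < 1%; missing external frequencies are
read as 0 (absent from the panel) with a log note. Carrier indicators per
(gene, individual) use the gene body ± 10 kb (half-open windows);
methylation analyses use windows around the CpG site instead.

Relative risk from the 2×2 table (a,b = outliers with/without a rare
variant; c,d = controls): RR = [a/(a+b)]/[c/(c+d)], SE of log RR
= sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)), 95% Wald interval on the log
scale, and a one-sided t test of log RR/SE against RR = 1 at
df = (a+b+c+d) − 2. The df convention for the single-enrichment test is
not uniquely determined by the workflow we follow; we reuse the
two-enrichment comparison's convention (total instances − 2) and note
that at these sample sizes the t and normal references are
indistinguishable. Zero a or c yields an explicitly flagged result with
undefined CI — no silent continuity correction. Two enrichments are
compared by t = (log RR₁ − log RR₂)/sqrt(SE₁² + SE₂²), two-sided, df =
summed instances − 2. The one-sided test is mildly anticonservative in
finite tables (measured level ≈ 0.052–0.055 at nominal 0.05 over the
table sizes we simulate), a known property of the Wald log-RR
approximation.

Ancestry-matched controls: each outlier is paired with the control
nearest in Euclidean distance over the top genotype PCs (11 by default);
exact ties break to the lexicographically smaller control ID; controls
may be reused.

## The Watershed CRF

Structure and notation are in the README. Conventions that matter:

* **Latent Z is binary per signal**; direction (under/over) lives only in
  the emission categories. This keeps exact 2^K inference and matches the
  architecture we implement.
* **Categories**: 3-level (none/under/over) for expression, methylation,
  protein; 2-level (none/outlier) for splicing. Status codes: 0 none, 1
  under (or outlier), 2 over, −1 missing. Missing E_k contributes no
  evidence and is marginalized; posteriors are always produced for all K
  signals.
* **Binarization**: outlier status from per-signal p-values at the 0.05
  threshold, direction from the sign of the median-across-exam Z (the
  `--pvalue_threshold` flag). Evaluation labels may instead use the
  per-signal empirical 2% p-value quantile (`--pvalue_fraction`), our
  reading of "top 2% of Z-scores".
* **Training filters**, in order: per signal, drop measurements
  inconsistent across exams (one exam |Z| ≥ 3, the other |Z| ≤ 1); remove
  per-signal global outliers (Q3 + 1.5 IQR fence on outlier counts); keep
  instances with ≥ 2 observed signals; keep genes with at least one
  outlier individual in ≥ 2 signals. Median-across-exam Z is the model
  input.
* **Annotations**: aggregated across a gene's rare variants by max per
  feature (binary flags stay binary, continuous scores take the
  strongest variant), then mean-centered and scaled to unit population
  (ddof = 0) sd; constant columns are dropped with a warning. The
  annotation list is data: the package imposes no fixed count.
* **Objective**: penalized marginal log-likelihood, λ(‖β‖² + ‖θ‖²) with θ
  counted once per unordered pair and intercepts included in ‖β‖²,
  exactly as written. Default λ = 1.0 on standardized features; an
  optional grid search on held-out marginal likelihood can replace it.
* **EM**: E-step enumerates all 16 state posteriors. M-step updates φ by
  posterior-weighted category counts with Dirichlet pseudocount 1
  (MAP under Dirichlet(2) — this is what guarantees φ never has zero
  mass on an observed category), then maximizes the expected CRF
  log-likelihood over (β, θ) to convergence with L-BFGS (gradient =
  expected minus model sufficient statistics, gtol 1e-8). Running the
  inner optimizer to convergence (rather than partial steps) is our
  choice; it makes each EM iteration a proper MAP-EM step. The monitored
  objective (penalized marginal log-likelihood + φ log-prior) is then
  provably non-decreasing, and a decrease beyond 1e-8 relative raises an
  error rather than being tolerated — it can only mean an inference bug.
* **Initialization** is deterministic: β from per-signal GAM fits
  (labels: any outlier category vs none), θ = 0, φ from label-conditional
  category frequencies with pseudocount 1. A consequence worth knowing:
  with weakly informative annotations the likelihood is nearly flat
  between "Z tracks the binarized E" and the generating configuration,
  and EM stays near the warm start. Parameter recovery is therefore only
  expected when annotations carry real signal — which is the premise of
  the method.
* **GAM** is scikit-learn logistic regression with C = 1/(2λ), intercept
  unpenalized. **RIVER** is literally the K = 1 model; no separate code
  path exists, so its equivalence checks are structural.

**N2 evaluation.** Pairs are (gene, individual₁, individual₂) with
identical rare-variant sets near the gene; groups larger than two keep the
two lexicographically smallest IDs (held-out = second), a deterministic
rule. Pair members are excluded from training. The held-out individual is
scored by P(Z_k = 1 | G, E_held-in) and labeled by their own binarized
status; AUC-PR (average precision) per signal, for Watershed and GAM, with
100 half-subsample bootstrap replicates drawn pairwise (the same
subsample indices score both models). Signals with fewer than 10 labeled
pairs are skipped. Per-variant posteriors take the maximum over carriers,
with thresholding utilities at 0.5 and 0.9.

## Trait scoring

Effect sizes are compared as percentile-normalized (rank/n, average ranks
on ties) absolute values — the sign of a rare-allele effect is arbitrary.
Prioritized sets (posterior ≥ 0.5 or 0.9) are compared to the background
by medians and a one-sided rank-sum test. The gene-level association test
labels individuals by residual trait Z (outlier |Z| > 2, control
|Z| < 0.2; the residualization covariates are accepted as a precomputed
residual column), collapses rare variants within 10 kb of each gene, and
rank-sum-tests the posterior distributions between the two groups per
signal plus a combined max-across-signals posterior, BH-adjusted across
genes. Gene restriction lists (e.g. phenotype-ontology genes) are
optional user inputs, not bundled resources.

## The simulator

`raremics.simulate` generates cohorts with the statistical structure the
pipeline assumes, with known truth. Defaults are the package's study
conditions:

* **Annotations**: half binary (Bernoulli 0.25), half standard normal;
  three informative features per signal with weights ≈ 2.2 and intercept
  −2.5, giving latent effect rates around 10–15%. The strong weights
  reflect that the informative annotations in this problem (stop,
  frameshift, splice-site flags, conservation) are strongly predictive.
* **Couplings**: θ = 0.8 between expression–methylation and
  expression–splicing, 0.3 elsewhere — information sharing strongest
  along the transcription-coupled edges.
* **Emissions**: φ(outlier | Z=1) ≈ 0.70 split over directions,
  φ(outlier | Z=0) = 0.05 — matching the p < 0.05 binarization rate under
  the null.
* **Exams**: per-feature cross-exam correlation defaults per signal to
  0.24 / 0.16 / 0.05 / 0.67 (expression / methylation / splicing /
  protein), the median correlations reported for these data types in
  longitudinal blood multi-omics; injected outliers appear in both exams
  at |Z| = 5.
* **Latent states** are sampled exactly from the CRF by enumerating the
  16 state probabilities per instance. Missingness is independent per
  signal (default 10%).
* **N2 structure**: within each gene a configurable fraction of
  individuals (default 10%) is paired; the partner inherits the variant
  set and annotation vector, and — because the shared variant is the
  putative cause — the same latent Z draw. Observed statuses stay
  independent draws given Z. Without the shared Z, the held-in evidence
  would be independent of the held-out label and the N2 evaluation would
  measure nothing.
* **Junction clusters** are DM draws at known α (default (10, 5, 5)) and
  fixed depth 100.
* One master seed; submodule streams are spawned deterministically, so
  identical configs give bit-identical cohorts.

What the simulator does *not* emulate: linkage disequilibrium, realistic
allele-frequency spectra, sequence-level genotypes, array probe
chemistry, batch structure, or any dependence of annotations on genomic
position. Passing tests on simulated cohorts therefore demonstrate the
statistical machinery (inference exactness, calibration, recovery,
ranking behaviour) under the model's own assumptions — not performance on
real cohort data, whose annotation informativeness and outlier rates are
far less favorable.

## Problem sizes and numerical choices

The test and acceptance runs use cohorts of 8,000–18,000 instances
(e.g. 250 individuals × 40 genes for parameter recovery, 300 × 60 with
900 N2 pairs for evaluation), 2,000 individuals per splicing-calibration
cluster, and 200–2,000 replicates for the statistical calibration
checks — sizes chosen so every property is measured with comfortable
Monte-Carlo margin while a full run stays in the minutes range on one
CPU. EM uses tol 1e-6 relative and at most 80 iterations in the recovery
study (the objective is long flat by then); DM fitting uses tol 1e-8.
Degenerate inputs (zero depth, constant annotation columns, zero-variance
residuals, empty groups, zero contingency cells) are either flagged
explicitly or excluded with warnings, never silently patched.

## Known limitations

* The latent-variable model is only weakly identified when annotations
  are uninformative; fitted emissions then drift toward the GAM-anchored
  warm start (see Initialization above).
* The Wald log-RR test is mildly anticonservative for small tables; exact
  alternatives (e.g. conditional tests) are deliberately out of scope to
  keep the estimator the standard two-way-table one.
* Exact inference scales as 2^K; the implementation is generic in K but
  intended for the K = 4 setting (K ≲ 15 remains practical).
* The splicing Z conversion discards direction by construction; analyses
  that need signed splicing effects must work from cluster-level
  proportions directly.
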