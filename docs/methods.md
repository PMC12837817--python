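# Methods

This note documents the statistical models, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions that affect results.

## Metabolomics arm

**Normalization.** "Total ion signal" normalization divides each
non-blank sample by its summed intensity. The rescaling constant is the
mean of the sample totals, so post-normalization all totals are equal and
intensities stay on the original order of magnitude. Blank samples are
instrument controls and are carried through I/O untouched and excluded
from every statistic.

**QC CV filter.** Features whose coefficient of variation across
pooled-QC injections exceeds 30% are removed. CV uses the sample (n−1)
standard deviation over QC injections divided by their mean; a zero QC
mean removes the feature with a warning. At least two QC injections are
required.

**Univariate testing.** Two-sided Welch (unequal-variance) t-tests are
used. The unequal-variance form is the safer default when no variance
assumption is stated, and at n = 6 per group the cost in power is small.
Tests run on log₂(x+1)-transformed normalized intensities (multiplicative
noise becomes approximately additive); fold changes are computed on the
normalized group means and oriented treatment/control (BRC/ddH₂O), the
same orientation used by the single-nucleus DE arm. BH adjustment is the
standard step-up procedure (statsmodels), cross-checked in the test suite
against an independent literal step-up enumeration.

**Differential rule.** up: VIP > 1 and q < 0.05 and log₂FC ≥ 0.8;
down: the same with log₂FC ≤ −0.8; everything else ns. The log₂FC bound
is inclusive, the other two strict, exactly as the thresholds are
written.

**qPCR (2^−ΔΔCt).** ΔCt = Ct_target − Ct_reference per sample;
ΔΔCt subtracts the control-group mean ΔCt; the reported fold change is
2^−ΔΔCt. The group comparison is a Welch test on ΔCt values rather than
on the exponentiated folds: ΔCt is closer to normal and variance-stable,
while the fold changes remain what is reported.

## OPLS-DA

The model is the standard single-y orthogonal signal correction: features
are mean-centred and unit-variance scaled (the metabolomics convention;
it also makes the model equivariant to per-feature rescaling), the class
variable is encoded 0/1 and centred. Each orthogonal round computes the
PLS weight w ∝ Xᵀy, the loading p of the resulting score, splits off
w_ortho = p − (wᵀp)w, and deflates X by the orthogonal component; one
predictive PLS component is then fitted on the filtered matrix. Defaults:
one predictive + one orthogonal component (the usual two-axis score-plot
layout); `n_orthogonal` is configurable and must stay below rank(X).

Conventions chosen where the field's software differs:

- **Sign**: predictive scores are sign-fixed to correlate positively with
  the treatment class, so outputs are deterministic.
- **VIP** is computed over the predictive component only:
  VIP_j = √p·|w_j| with ‖w‖ = 1, hence mean(VIP²) = 1 exactly. (Whether
  orthogonal components enter VIP is version-dependent across
  implementations; the predictive-only form is pinned and tested.)
- **Q²Y** = 1 − PRESS/TSS over stratified k-fold cross-validation with
  every fold refitting scaling, deflation and the predictive component.
  Default 7 folds, the chemometrics-ecosystem convention; when the
  minority class is smaller than the fold count (e.g. 6+6 samples) the
  fold count is clamped to the minority class size with a warning, since
  a stratified fold must not exhaust a class. `n_folds = n_samples`
  gives leave-one-out, which the test suite checks against an independent
  refit oracle.
- **Permutation test**: class labels permuted (200 iterations by
  default), the full model refitted, and the statistic — Q²Y by default,
  R²Y optionally — recomputed. The empirical p uses the add-one
  (permutations + 1 in both numerator and denominator) convention, so the
  smallest attainable p with 200 permutations is 1/201 ≈ 0.005 and p = 0
  is impossible; ties count against the model. R²Y is a poor permutation
  statistic when features ≫ samples (it saturates near 1 for any
  labels), which is why the cross-validated statistic is the default.

## Single-nucleus arm

**QC metrics.** n_count (total UMIs), n_feature (genes detected),
log₁₀GenesPerUMI = log₁₀(n_feature)/log₁₀(n_count) (library complexity),
and percent.mt (% of counts from mitochondrial-flagged genes).
Mitochondrial genes are identified by an explicit flag column in
`features.tsv`, not by name prefix — honeybee gene naming makes prefix
matching unreliable. Nuclei with n_count ≤ 1 have an undefined complexity
metric (log₁₀(1) = 0 denominator); they are reported as 0 and flagged.

**Filter.** Keep iff log₁₀GenesPerUMI > 0.85 and 200 < n_feature < 5000
and percent.mt < 5, with all bounds strict as printed (200, 5000 and 5
themselves excluded). The filter report counts failures per criterion and
notes that doublet detection is not performed, so survivor counts are not
comparable to pipelines that remove doublets.

**Normalization.** Counts per nucleus divided by the nucleus total,
scaled to 10,000, then log(1+x) with the natural log — the default of the
standard single-cell toolkits. (Descriptions of this step sometimes say
"log10-transformed according to the package defaults" although the named
package's default is the natural log; the package default is followed
here and a `log10` flag is exposed.)

**Gene-set curation.** Detectability is summarized per gene as the
maximum over annotated cell types of (i) the percent of nuclei expressing
the gene and (ii) its mean normalized expression, zeros included; max_avg
uses normalized (not raw) expression since that is the scale scoring runs
on. Within each set, thresholds are the 70th percentile of max_pct
(floored at 5%) and the 70th percentile of max_avg — quantiles use the
linear-interpolation convention, stated explicitly because quantile
definitions differ across ecosystems — and genes must strictly exceed
both. If fewer than five genes pass, the top five by the mean of
min-max-scaled max_pct and max_avg are retained (lexicographic gene-id
tie-break); sets smaller than five are kept whole with a warning.

**JASMINE scoring.** Per nucleus and gene set: (a) the mean rank of the
expressed signature genes among all genes the nucleus expresses,
ascending in expression with average ranks for ties, divided by the
number of expressed genes — the exact mean rank rather than any
subsampled approximation; (b) the odds ratio
(sig-expressed · nonsig-unexpressed)/(sig-unexpressed · nonsig-expressed)
with +0.5 on all four cells (the enrichment variant chosen from the
published algorithm's odds-ratio/likelihood pair; a Haldane correction
guards zero cells). A nucleus expressing no signature gene gets both raw
components 0. Components are min-max scaled across nuclei (a constant
component scales to all-zero) and averaged. Both components depend only
on within-nucleus ranks and the expressed/unexpressed dichotomy, so
scores are invariant to per-nucleus rescaling — depth normalization
matters only through which entries are nonzero.

**Lineage comparison.** Composite scores pooled over the glial types
(SG, AST, CG, EG) versus the neuronal types (KCs, OLCs, OPNs) and
compared per gene set with a two-sided Wilcoxon rank-sum test.

**Composition testing.** The per-type statistic is the log₂ fold
difference of proportions, treatment/control. When any type count is
zero, proportions switch to (count + 0.5)/(total + 0.5·K) with K the
number of types, keeping the statistic finite. The null distribution
permutes condition labels across nuclei (1000 draws by default) with the
two-sided statistic |log₂FD| and the add-one p; BH is applied across cell
types. An exact mode enumerates all condition-label assignments for small
datasets. Bootstrap CIs resample nuclei with replacement within each
condition and take percentile intervals. Note the permutation p is
super-uniform (conservative) when nucleus counts are small, because the
count statistic lives on a coarse integer lattice and ties count as
extreme; at the scale the test is meant for (thousands of nuclei) the
rejection rate is nominal, and the test suite checks both regimes.

**Differential expression.** Within each cell type (requiring ≥ 3 nuclei
per condition), a two-sided Wilcoxon rank-sum per gene on normalized
expression; genes with no variation across both groups carry no evidence
and get p = 1. BH is applied within the cell type (matching the scope of
the usual single-cell DE frameworks, while the proportion test adjusts
across cell types). log₂FC follows the single-cell convention
log₂((mean(expm1 x_t)+1)/(mean(expm1 x_c)+1)), configurable to plain
means of the log values; pct_treatment/pct_control are fractions of
nuclei with nonzero expression. Gene selection for enrichment uses
q < 0.05, |logFC| > 1.5, and max(pct) > 0.1 (the max-over-groups reading
of a min.pct filter).

## Synthetic data

**Metabolomics generator.** Intensities are lognormal around per-feature
baselines (multiplicative noise is the standard LC–MS error model;
baselines span 10⁴–10⁶ arbitrary units). Defaults are the study design:
six biological replicates per condition, five pooled-QC injections, 200
features with 20 planted at log₂FC = 1.5 in the treatment group, and 15%
biological CV. QC samples are the pooled all-sample mean times lognormal
technical noise — 10% CV for stable features and 60% for a planted set of
"unstable" features that the 30% CV filter should remove. The unstable
set is drawn disjoint from the planted differential set so filter
behaviour and recovery can be assessed independently. σ is derived from
the requested CV via σ = √log(1+CV²), so the generated CV is exact in
expectation.

**Single-nucleus generator.** Counts are negative-binomial with
variance μ + φμ² and a shared dispersion φ = 0.5; per-gene means are
lognormal around a base mean of 0.5 with mild per-cell-type modulation,
giving realistic libraries (~1–2 k UMIs, several hundred genes per
nucleus, complexity comfortably above the 0.85 QC bound). The default
populations are the seven honeybee-brain types (KCs, OLCs, OPNs
neuronal; SG, AST, CG, EG glial, ~1 030 nuclei per condition), five
metabolic gene sets (glycolysis, gluconeogenesis, PPP, IIS, TCA; disjoint
memberships drawn from the non-mitochondrial pool), and a +1 log₂
activity shift planted for glycolysis and PPP genes in the glial types
under treatment — the direction of the glial metabolic response the
pipeline is designed to detect. Cell-type counts per condition are
multinomial around the configured proportions (optionally shifted between
conditions); 5% extra low-quality nuclei (libraries shrunk ×0.03,
mitochondrial means ×30) are spiked in for QC testing. 1% of genes are
flagged mitochondrial.

The generators do **not** model raw spectra, chromatography, retention
drift, read-level sequencing, ambient RNA, doublets, batch effects, or
gene–gene correlation beyond cell-type structure. Passing recovery tests
therefore demonstrates that the statistics are implemented correctly and
behave as designed under their own assumptions — not that the pipeline is
robust to the artefacts of real LC–MS or droplet data. Effect sizes and
dispersions were chosen for testability (clear planted signal at desk
scale), since no generative parameters are available for the real data.

## Numerical choices and degenerate inputs

- Welch test with zero variance in both groups and equal means returns
  (t = 0, p = 1) instead of NaN.
- Zero-variance features get correlation 0 (with a warning) in the
  OPLS-DA correlation output; unit-variance scaling maps zero-sd columns
  to sd 1 to avoid division by zero.
- The single global seed is expanded into per-stage seeds through
  `SeedSequence([seed, crc32(stage)])`, so each stage is individually
  reproducible and stages do not share streams.
- Problem sizes in the test suite (e.g. 12-sample OPLS-DA toys, 100-draw
  brute-force sweeps, 200-simulation calibration runs, 1 000
  nuclei/condition for proportion-test calibration) are chosen so the
  whole suite runs in about a minute on one CPU while keeping Monte Carlo
  error well inside the asserted bounds.

## Known limitations

- Single predictive component only (two-class OPLS-DA); no O2PLS,
  S-plots, or automatic component selection.
- The moderated (empirical-Bayes) linear-model fit used by some targeted
  metabolomics workflows is not implemented; plain Welch tests stand in.
- No doublet detection, integration, clustering, or annotation: nuclei
  must arrive labeled.
- Pathway enrichment of differential metabolites, classifier-based
  perturbation prioritization, and mixed-effects transcriptional
  distances are out of scope.
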