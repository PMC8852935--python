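# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices and the known limitations of twaskit.

## Study design being modelled

The pipeline reproduces the structure of a two-reference-panel TWAS of
a binary disease: two biobanks provide genotypes plus multi-tissue
expression (panel A larger, panel B smaller but sharing the same true
genetic regulation), several case-control GWAS cohorts provide
genotypes and disease status, and follow-up analyses interrogate the
significant genes (colocalization with eQTL signals, rare damaging
variants, regional lipid-trait association, co-expression and gene-set
enrichment).

## Genotype and expression QC

Variants are removed when call rate < 0.95, MAF < 0.01 or the exact
Hardy–Weinberg test P < 1e-6; a variant failing several rules is
counted under each but removed once. The HWE test is the exact
conditional (permutation) test on the heterozygote count given the
allele counts, two-sided by summing all heterozygote-count
probabilities not exceeding the observed one. The exact test is used
rather than the χ² approximation because a 1e-6 threshold operates far
in the tail where χ² is unreliable; the implementation is validated
exhaustively against an exact-rational enumeration for all genotype
tables with n ≤ 50.

Expression is normalised in two steps: sample-level quantile
normalisation (each sample mapped onto the across-sample mean of sorted
vectors; ties get the mean of spanned targets, making the map
idempotent) and gene-level inverse-normal transformation
Φ⁻¹((rank − 0.5)/n) with average ranks for ties. The (rank − 0.5)/n
offset is symmetric and keeps the transform finite.

Missing dosages are mean-imputed per variant after QC and before model
training: elastic-net solvers need complete matrices, and the ≥ 0.95
call-rate filter bounds the distortion.

## Annotation-informed SNP priors

The full hierarchical Bayesian treatment of epigenomic annotations is
deliberately out of scope; the prior here is a transparent
enrichment estimate. Variants whose best cis |z| exceeds the 95th
percentile form the "top" set; γ̂ is the Haldane-corrected log odds
ratio of annotation presence in the top set versus the rest, and
prior_j = σ(μ̂ + γ̂·a_j) with μ̂ solved (Brent) so the mean prior equals
a configurable baseline (default 0.5). Priors map to penalty factors
v_j = clamp(1 − prior_j, 0.1, 1): monotone decreasing, with the 0.1
floor preventing any variant from becoming effectively unpenalised.
On simulated panels with a generating enrichment odds ratio of 4, γ̂
recovers log 4 within two Woolf standard errors; LD partners of causal
variants dilute the estimate slightly, which is visible but small at
the default LD level (AR(1) ρ = 0.6).

## Weighted elastic net

Per gene, over cis variants (±1 Mb of the TSS):

    argmin_β (1/2n)‖y − Xβ − b‖² + λ Σ_j v_j (α|β_j| + (1−α)β_j²/2)

Columns are standardised internally and weights returned on the dosage
scale. The solver is cyclic coordinate descent on the Gram matrix
(covariance updates), numba-compiled, with warm starts along a
100-point log-spaced λ path (λ_min/λ_max = 1e-3) from the smallest λ
that zeroes all coefficients. λ is chosen by minimum tenfold
cross-validated MSE; the one-standard-error rule is not applied. Fold
assignment is a seeded permutation of a round-robin labelling —
reproducibility over statistical nicety. Mixing defaults to α = 0.5.

Two performance metrics are reported: cv-R² as the squared Pearson
correlation between out-of-fold predictions and observed expression
(this is what the > 0.01 retention filter uses, strict inequality) and
the 1 − MSE/Var variant. The solution satisfies the KKT conditions of
the stated objective at 1e-6 on test problems, and with all penalty
factors equal it matches scikit-learn's ElasticNet coefficient-for-
coefficient, which serves as the independent solver cross-check.

## TWAS association

GReX(i) = Σ_j w_j·dosage_ij on each model's alt allele; cohort variants
with swapped ref/alt are flipped (2 − d), and model variants missing
from a cohort contribute zero with the coverage fraction logged
(models under 50% coverage are skipped). GReX is standardised per
cohort before logistic regression so betas are per SD of imputed
expression; covariates (sex, PCs) are optional. Non-converged or
separated fits are dropped with a recorded reason rather than patched.

Cohorts combine by fixed-effect inverse-variance meta-analysis (the
per-cohort model and the combination rule are both design choices:
the source design prints neither), with Cochran's Q, its χ² P and
I² = max(0, (Q − (k−1))/Q) always reported; a Stouffer
sample-size-weighted z is available as an option. Two panels'
association tables merge by keeping, per gene-tissue pair, the record
with the smaller P (winning panel recorded); per gene the minimum P
across tissues defines the gene-level row. Significance is declared on
the merged min-P at α/m without cross-panel multiplicity correction,
mirroring the integration rule of the design being modelled. Genes are
"known" when their TSS lies within ±1 Mb of any catalog locus on the
same chromosome (boundary inclusive), "novel" otherwise, and
"unclassified" without a position.

## Colocalization

Single-causal-variant Bayesian colocalization: per variant and trait,
log ABF = ½[log(1−r) + r·z²] with r = W/(V+W), V = se², and prior
effect SD 0.15 for quantitative traits, 0.2 for case-control log-odds.
Hypothesis masses use priors p1 = p2 = 1e-4, p12 = 1e-5; the H3
(distinct causal variants) mass needs the off-diagonal sum
Σ_{i≠j} ABF1_i·ABF2_j, computed exactly by log-sum-exp over pairs for
loci up to 500 variants and by the algebraic identity
S1·S2 − S12 above that (the identity loses precision to cancellation
exactly when H3 is negligible, so the switch is safe). Posteriors match
a brute-force enumeration over all single-causal configurations to
1e-10 in log space for small loci. The decision rule is PP4 > 0.55
(strict), configurable. When only z, MAF and n are available the
standard error is approximated as 1/√(2·maf·(1−maf)·n), divided by
s(1−s) for case fraction s, and flagged.

## Rare-variant burden and regional association

Damaging ⇔ MAF < 0.01 (strict) AND (LoF ∨ ClinVar-pathogenic ∨
missense with ≥ 1 of 5 prediction algorithms calling it damaging).
Annotation labels are inputs; no annotation pipeline is run. Carriers
are samples with dosage > 0 at any damaging variant of the gene
(missing → non-carrier). Binary traits use the two-sided Fisher exact
test (point-probability rule); the odds ratio gets a Haldane 0.5
correction when a cell is zero and a Woolf 95% CI on the corrected
table. Quantitative traits use OLS of trait on carrier status with
covariate adjustment; two covariate presets exist (sex + 5 PCs +
lipid medication, with or without age) because the two association
designs being modelled differ in exactly that term, and neither is
hard-coded.

Regional association filters variants to MAF > 0.01 and imputation
info > 0.4 (info defaults to 1 for directly generated genotypes) and
corrects α by M_eff × n_traits, where
M_eff = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)] over eigenvalues of the
regional variant correlation matrix (eigenvalues rounded at 1e-10
because the floor rule is discontinuous at integers). An externally
computed M_eff is accepted as a direct input. Rows carry both the
Bonferroni flag and a genome-wide (P < 5e-8) flag.

## Co-expression and enrichment

Edges connect lncRNA to protein-coding genes with |Pearson r|
strictly > 0.4, by default restricted to cis neighbourhoods (same
chromosome, TSS distance ≤ 1 Mb) since the motivating analyses look at
lncRNAs co-expressed with surrounding genes; `cis_only=False` removes
the restriction. Enrichment is the right-tailed hypergeometric test of
a query set against named gene sets intersected with an explicit
universe (the universe is a required input because the appropriate
choice — all genes vs all TWAS-testable genes — is analysis-dependent),
with Benjamini–Hochberg FDR across sets.

## Synthetic-data generator

Genotypes: one latent AR(1) standard-normal vector per sample per LD
block (ρ = 0.6 by default), thresholded at each variant's
Hardy–Weinberg genotype quantiles for its MAF (drawn uniform on
0.05–0.5). Blocks sit 3 Mb apart on one synthetic chromosome, so they
are independent and each gene's cis window contains exactly its own
block; by default two genes share a block (so cis neighbours and
LD-mediated co-expression exist). Coordinates are 1-based.

Expression: per gene, 2 causal cis-SNPs with standard-normal effects,
noise scaled so the genetic fraction of variance equals the gene's
drawn h²_cis (uniform 0.05–0.4 by default); causal variant identities
and effects are shared across tissues and across the two panels, with
independent samples and noise per tissue and panel. Causal variants
carry an epigenomic annotation at the rate implied by a baseline of
0.2 and an enrichment odds ratio of 4.

Disease: liability ℓ_i = Σ_g α_g·GReX_true(i,g) + ε_i, ε ~ N(0,1),
cases above the (1 − prevalence) quantile (prevalence 0.1), sampled to
the requested case/control counts by repeated pool draws. Liability
coefficients have fixed magnitude `liability_effect_sd` and random
sign: the generator's power studies condition on h²_cis only, so causal
genes must carry comparable liability effects for power to be a
function of heritability rather than of an incidental effect-size draw.

Rare variants: independent binomial dosages at MAFs drawn in
(0.0005, 0.009) — LD is negligible at these frequencies — with class
labels (20% LoF, 10% ClinVar-pathogenic, 40% missense-damaging, 30%
benign) and additive carrier shifts on designated quantitative traits.

What the generator does **not** emulate: recombination maps, population
structure and admixture, imputation uncertainty, sex chromosomes,
post-mortem expression artefacts, trans-regulation, and co-expression
beyond shared cis genetics. Passing calibration and recovery checks on
this substrate therefore demonstrates the statistical machinery is
correct and calibrated under the stated model, not that real-data
confounders (stratification, cross-cell-type heterogeneity) are
handled.

## Scaled-down study sizes

The self-checks in `twaskit.benchmarks` (also run by
`scripts/acceptance.py`) use: 2,000 null genes × 1,000 samples for null
calibration of the association step; 1,000 replicates at n = 100 for
the linear-model type-I error; 100 shared-causal and 100
distinct-causal loci of 50 variants (causal z ≈ 8) for colocalization
discrimination; 200 genes at n = 500 for the cv-R²–h² slope and the
prior log-OR recovery; and a 200-gene, 4,000-sample (two cohorts of
1,000/1,000) end-to-end power study with 5% causal genes and liability
effect magnitude 1.0. These sizes give stable operating characteristics
while keeping the full suite to a couple of minutes.

## Known limitations

* The per-cohort association model and meta-analysis rule are
  conventions chosen here (logistic + fixed-effect IVW); the toolkit
  reports heterogeneity so users can judge when a random-effects model
  would be more faithful.
* The annotation prior is a marginal enrichment estimate, not a joint
  hierarchical model; with many annotations or strong LD it will
  under-estimate the true enrichment.
* Colocalization assumes a single causal variant per trait per locus;
  multi-causal loci deflate PP4.
* The M_eff eigenvalue estimator is one of several conventions for the
  effective number of tests and tends to be conservative in strong-LD
  regions; externally computed values can be supplied.
* Firth correction is not attempted for separated logistic fits; such
  gene-cohort records are dropped with a logged reason, which slightly
  reduces power for very rare or very strong signals.
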