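# twaskit

A toolkit for transcriptome-wide association studies (TWAS) of
case-control traits, built around the two-reference-panel design used in
coronary-artery-disease genetics: expression prediction models are
trained on genotype + multi-tissue expression reference panels, used to
impute genetically regulated expression (GReX) into GWAS cohorts, and
the imputed expression is tested for association with disease. The
toolkit covers the full chain —

1. **QC & normalisation** — variant filters (call rate ≥ 0.95,
   MAF ≥ 0.01, exact Hardy–Weinberg P ≥ 1e-6), sample-level quantile
   normalisation and gene-level inverse-normal transformation of
   expression;
2. **Prediction models** — per-gene cis (±1 Mb) weighted elastic net
   with tenfold cross-validation, where each SNP carries a penalty
   factor derived from an epigenomic-annotation prior; models kept when
   cross-validated R² > 0.01;
3. **TWAS** — GReX imputation (allele-aware dosage weighting),
   per-cohort logistic association, fixed-effect inverse-variance
   meta-analysis with Cochran's Q / I², integration of two panels by
   lowest P per gene-tissue pair, Bonferroni significance, and
   known/novel annotation against a GWAS locus catalog (±1 Mb);
4. **Colocalization** — Wakefield approximate Bayes factors and
   posterior probabilities PP0…PP4 of the five sharing hypotheses,
   with the decision rule PP4 > 0.55;
5. **Rare-variant burden** — damaging-variant definition (MAF < 0.01
   and LoF / ClinVar-pathogenic / missense predicted damaging),
   per-gene carrier collapse, Fisher's exact test for binary traits and
   covariate-adjusted linear regression for quantitative traits, plus
   regional SNP association corrected by the effective number of
   independent tests (eigenvalue estimator);
6. **Co-expression & enrichment** — lncRNA–coding edges at
   |Pearson r| > 0.4 and right-tailed hypergeometric gene-set
   enrichment with Benjamini–Hochberg FDR;
7. **Simulation** — a seeded generator producing reference panels
   (Gaussian-copula LD, sparse cis-eQTLs, annotation enrichment),
   liability-threshold case-control cohorts, a second panel sharing the
   first's eQTL effects, and rare damaging variants with carrier
   effects — the substrate for every calibration and recovery check.

## The model at the core

For gene *g* with expression *y* and cis dosage matrix *X*, the
prediction model solves

    argmin_β  (1/2n)‖y − Xβ − b‖²  +  λ Σ_j v_j ( α|β_j| + (1−α)β_j²/2 )

with mixing α = 0.5 and per-SNP penalty factors
v_j = clamp(1 − prior_j, 0.1, 1), prior_j = σ(μ̂ + γ̂·a_j) from the
annotation indicator a_j; λ is chosen by tenfold cross-validated MSE.
GReX for sample *i* is Σ_j w_j·dosage_ij, tested by logistic regression
per cohort and combined by inverse-variance meta-analysis. At a locus,
colocalization scores each variant with
log ABF = ½[log(1−r) + r·z²], r = W/(V+W), and normalises the five
hypothesis masses to PP0…PP4.

## Worked example

```python
from twaskit import (SimulationConfig, bonferroni_threshold, filter_models,
                     train_weighted_elastic_net, impute_grex, associate_grex,
                     meta_analyze)
from twaskit.simulate import (simulate_genotypes, simulate_reference_panel,
                              simulate_gwas_cohorts)

cfg = SimulationConfig(
    n_genes=60, n_ref_a=300, n_tissues=1,
    cohort_sizes=[(800, 800), (800, 800)],
    causal_gene_fraction=0.1, liability_effect_sd=1.0, seed=3,
)
geno = simulate_genotypes(cfg, cfg.n_ref_a)
expr, annotations, truth = simulate_reference_panel(cfg, geno)
models = filter_models(train_weighted_elastic_net(geno, expr["T0"], seed=3),
                       r2_min=0.01)
print(f"{len(models)} prediction models retained (cv-R2 > 0.01)")

tables = []
for cohort_geno, pheno in simulate_gwas_cohorts(cfg, truth):
    grex = impute_grex(cohort_geno, models)
    tables.append(associate_grex(grex, pheno["status"].to_numpy()))
meta = meta_analyze(tables)
thr = bonferroni_threshold(0.05, len(meta))
print(f"Bonferroni threshold: {thr:.3g} ({len(meta)} gene-tissue tests)")
print(meta[meta["p"] < thr].sort_values("p")[["gene", "tissue", "z", "p"]]
      .to_string(index=False))
print("true causal genes:", sorted(truth.causal_genes))
```

prints

```
60 prediction models retained (cv-R2 > 0.01)
Bonferroni threshold: 0.000833 (60 gene-tissue tests)
 gene tissue          z             p
G0004     T0 -22.628107 2.292363e-113
G0031     T0 -20.445675  6.564433e-93
G0023     T0 -20.087804  9.434415e-90
G0013     T0  17.637437  1.270966e-69
G0027     T0  13.615045  3.259445e-42
G0005     T0  -9.756915  1.723176e-22
G0022     T0   6.963386  3.321902e-12
G0047     T0   6.431272  1.265409e-10
G0012     T0  -3.522873  4.268962e-04
G0030     T0   3.352662  8.003838e-04
true causal genes: ['G0004', 'G0013', 'G0023', 'G0027', 'G0031', 'G0047']
```

All six genes whose expression truly drives disease liability reach
transcriptome-wide significance with the correct effect direction. The
extra hits (G0005, G0012, G0022, G0030) are each the cis neighbour
sharing an LD block with a causal gene — the familiar TWAS phenomenon
that co-regulated neighbours of a causal gene light up too, which is
why the toolkit carries a colocalization stage.

## Command line

`twaskit` exposes `simulate`, `qc`, `train`, `twas`, `coloc`, `burden`,
`network`, `enrich` and `run` (the full seeded pipeline with a
provenance manifest):

```
twaskit run --config cfg.yaml --out runs/demo --seed 7
```

A rerun with the same config and seed reproduces every output
bit-identically (hashes recorded in `manifest.json`).

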