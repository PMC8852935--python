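"""Calibration, discrimination and recovery studies on synthetic data.

These are the package's standard self-checks: each function generates
data with the synthetic module under stated conditions, runs the
corresponding pipeline stage, and returns the measured operating
characteristics — null P-value uniformity of the TWAS association step,
type-I error of the covariate-adjusted quantitative association,
colocalization discrimination between shared- and distinct-causal loci,
cross-validated R² tracking of true cis heritability, recovery of the
annotation-enrichment log odds ratio, and end-to-end power on a
scaled-down case-control study.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .coloc import posteriors_from_log_abf
from .burden import quantitative_assoc
from .datatypes import ModelEntry, PredictionModelSet
from .models import estimate_snp_priors, filter_models, train_weighted_elastic_net
from .simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_gwas_cohorts,
    simulate_reference_panel,
)
from .twas import associate_grex, bonferroni_threshold, impute_grex, meta_analyze


def null_twas_calibration(
    n_genes: int = 2000, n_samples: int = 1000, seed: int = 0
) -> dict:
    """Null calibration of GReX imputation + case-control association.

    Genes get arbitrary nonzero prediction weights over their cis
    variants, but the phenotype is drawn independently of genotype, so
    every gene is null; per-gene P-values should be uniform.
    Returns the Kolmogorov–Smirnov P against the uniform and the
    empirical type-I error at 0.05.
    """
    cfg = SimulationConfig(
        n_genes=n_genes, snps_per_gene=4, genes_per_block=1, n_tissues=1, seed=seed
    )
    rng = np.random.default_rng(seed + 1)
    g = simulate_genotypes(cfg, n_samples, rng=rng)
    models = PredictionModelSet()
    vids = g.variants["variant_id"].to_numpy()
    for gi in range(n_genes):
        idx = slice(gi * 4, gi * 4 + 4)
        w = rng.normal(size=4)
        models.add(
            ModelEntry(
                gene=f"G{gi:04d}", tissue="T0", panel="A",
                variant_ids=list(vids[idx]), weights=w,
                ref=["A"] * 4, alt=["G"] * 4, intercept=0.0,
                cv_r2=0.2, cv_r2_var=0.2, n_train=n_samples,
            )
        )
    grex = impute_grex(g, models)
    y = (rng.random(n_samples) < 0.5).astype(float)
    tab = associate_grex(grex, y)
    p = tab["p"].to_numpy()
    return {
        "n_tests": len(p),
        "ks_p": float(kstest(p, "uniform").pvalue),
        "type_i_at_05": float((p < 0.05).mean()),
    }


def quantitative_type_i_error(
    n_reps: int = 1000, n: int = 100, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Type-I error of the covariate-adjusted linear association under the null."""
    rng = np.random.default_rng(seed)
    hits = 0
    ps = np.empty(n_reps)
    for r in range(n_reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        _, _, p = quantitative_assoc(x, y, covariates=cov)
        ps[r] = p
        hits += p < alpha
    return {
        "n_reps": n_reps,
        "type_i": hits / n_reps,
        "ks_p": float(kstest(ps, "uniform").pvalue),
    }


def coloc_discrimination(
    n_loci: int = 100, n_variants: int = 50, z_causal: float = 8.0, seed: int = 0
) -> dict:
    """Shared- vs distinct-causal discrimination of the colocalization step.

    Shared loci put a z ≈ 8 signal at the same variant in both traits;
    distinct loci put it at different (uncorrelated) variants. Reports
    the fraction of shared loci called colocalized (pp4 > 0.55) and the
    fraction of distinct loci with pp3 > pp4.
    """
    rng = np.random.default_rng(seed)
    se = 0.05
    prior_sd = 0.15
    r = prior_sd**2 / (se**2 + prior_sd**2)

    def locus(causal_idx, z0):
        z = rng.normal(size=n_variants)
        z[causal_idx] = z0 + rng.normal(0, 0.5)
        return 0.5 * (np.log1p(-r) + r * z**2)

    shared_hits = 0
    distinct_hits = 0
    for _ in range(n_loci):
        l1 = locus(0, z_causal)
        l2 = locus(0, z_causal)
        pp = posteriors_from_log_abf(l1, l2)
        shared_hits += pp[4] > 0.55
    for _ in range(n_loci):
        l1 = locus(0, z_causal)
        l2 = locus(1, z_causal)
        pp = posteriors_from_log_abf(l1, l2)
        distinct_hits += pp[3] > pp[4]
    return {
        "shared_pp4_rate": shared_hits / n_loci,
        "distinct_pp3_rate": distinct_hits / n_loci,
    }


def cv_r2_h2_slope(n_genes: int = 200, n_ref: int = 500, seed: int = 0) -> dict:
    """Regression slope of cross-validated R² on true cis heritability."""
    cfg = SimulationConfig(
        n_genes=n_genes, n_ref_a=n_ref, n_tissues=1,
        h2_cis_range=(0.05, 0.4), seed=seed,
    )
    g = simulate_genotypes(cfg, n_ref)
    expr, _, truth = simulate_reference_panel(cfg, g)
    models = train_weighted_elastic_net(g, expr["T0"], seed=seed)
    h2 = np.array([truth.h2_cis[e.gene] for e in models])
    r2 = np.array([e.cv_r2 for e in models])
    slope, _, _ = quantitative_assoc(h2, r2)
    return {"slope": float(slope), "n_genes": len(h2)}


def prior_log_or_recovery(n_genes: int = 200, n_ref: int = 500, seed: int = 0) -> dict:
    """Recovery of the annotation-enrichment log odds ratio (generating OR = 4)."""
    cfg = SimulationConfig(
        n_genes=n_genes, n_ref_a=n_ref, n_tissues=1,
        annotation_enrichment_or=4.0, seed=seed,
    )
    g = simulate_genotypes(cfg, n_ref)
    expr, ann, truth = simulate_reference_panel(cfg, g)
    z = _best_cis_z(g, expr["T0"])
    flags = (
        ann.set_index("variant_id")["annotated"]
        .reindex(g.variants["variant_id"])
        .to_numpy(dtype=int)
    )
    pt = estimate_snp_priors(z, flags, list(g.variants["variant_id"]))
    # Woolf SE from the same 2x2 split used by the estimator
    cut = np.quantile(np.abs(z), 0.95)
    top = np.abs(z) > cut
    n11 = (top & (flags == 1)).sum() + 0.5
    n10 = (top & (flags == 0)).sum() + 0.5
    n01 = (~top & (flags == 1)).sum() + 0.5
    n00 = (~top & (flags == 0)).sum() + 0.5
    se = float(np.sqrt(1 / n11 + 1 / n10 + 1 / n01 + 1 / n00))
    return {
        "gamma_hat": float(pt.gamma_hat),
        "se": se,
        "generating_log_or": float(np.log(4.0)),
        "abs_error_in_se": abs(pt.gamma_hat - np.log(4.0)) / se,
    }


def _best_cis_z(g, e) -> np.ndarray:
    d = g.mean_impute().dosages
    sd = d.std(axis=0)
    ok = sd > 1e-12
    ds = np.zeros_like(d)
    ds[:, ok] = (d[:, ok] - d[:, ok].mean(axis=0)) / sd[ok]
    v = e.values
    vs = (v - v.mean(axis=1, keepdims=True)) / np.maximum(v.std(axis=1, keepdims=True), 1e-12)
    r = np.clip((vs @ ds) / g.n_samples, -0.999999, 0.999999)
    return np.abs(r * np.sqrt(g.n_samples - 3)).max(axis=0)


def end_to_end_power(
    n_genes: int = 200,
    n_ref: int = 500,
    cohort_sizes=((1000, 1000), (1000, 1000)),
    seed: int = 0,
) -> dict:
    """Scaled-down end-to-end study: power for causal genes with h² ≥ 0.1.

    Simulates a reference panel, trains and filters prediction models,
    imputes GReX into liability-threshold case-control cohorts, runs the
    per-cohort association and fixed-effect meta-analysis, and measures
    power at the Bonferroni threshold among causal genes with true cis
    heritability ≥ 0.1, plus the false-positive count among null genes.
    """
    cfg = SimulationConfig(
        n_genes=n_genes,
        n_ref_a=n_ref,
        n_tissues=1,
        cohort_sizes=[tuple(c) for c in cohort_sizes],
        n_cohorts=len(cohort_sizes),
        causal_gene_fraction=0.05,
        liability_effect_sd=1.0,
        seed=seed,
    )
    g = simulate_genotypes(cfg, n_ref)
    expr, _, truth = simulate_reference_panel(cfg, g)
    models = filter_models(train_weighted_elastic_net(g, expr["T0"], seed=seed), 0.01)
    cohorts = simulate_gwas_cohorts(cfg, truth)
    tables = []
    for geno, pheno in cohorts:
        grex = impute_grex(geno, models)
        tables.append(associate_grex(grex, pheno["status"].to_numpy()))
    meta = meta_analyze(tables)
    m = len(meta)
    thr = bonferroni_threshold(0.05, m)
    sig = set(meta.loc[meta["p"] < thr, "gene"])
    causal_h2 = {
        gid for gid in truth.causal_genes if truth.h2_cis[gid] >= 0.1
    }
    tested = set(meta["gene"])
    causal_tested = causal_h2 & tested
    null_tested = tested - set(truth.causal_genes)
    power = len(sig & causal_tested) / len(causal_tested) if causal_tested else float("nan")
    return {
        "n_tested": m,
        "threshold": thr,
        "n_causal_h2_ge_0.1": len(causal_h2),
        "n_causal_tested": len(causal_tested),
        "power": power,
        "false_positives": len(sig & null_tested),
        "n_null_tested": len(null_tested),
        "expected_false_positives": 0.05 * len(null_tested) / max(m, 1),
    }
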