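"""Rare damaging-variant burden tests and regional trait association.

A variant qualifies as damaging when its MAF is below 0.01 (strict) and
it is loss-of-function, ClinVar-pathogenic, or missense predicted
damaging by at least one of five in-silico algorithms. Samples collapse
to per-gene carrier indicators (carrier ⇔ nonzero dosage at any
damaging variant of the gene). Binary traits use Fisher's exact test on
the carrier × case 2×2 table; quantitative traits use linear regression
of the trait on carrier status with covariate adjustment. Regional
association applies the common-variant filters (MAF > 0.01, imputation
info > 0.4) and corrects for the effective number of independent tests
estimated from the eigenvalues of the variant correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import fisher_exact, norm

from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)

DAMAGING_CLASSES = ("LoF", "clinvar_pathogenic", "missense_damaging")
DEFAULT_DAMAGING_MAF_MAX = 0.01
DEFAULT_REGIONAL_MAF_MIN = 0.01
DEFAULT_INFO_MIN = 0.4
GENOME_WIDE_P = 5e-8

# Covariate presets mirroring the two association designs: the burden
# regressions adjust for sex, five PCs and lipid medication; the
# regional lipid-locus analysis additionally adjusts for age.
COVARIATE_PRESETS = {
    "burden": ["sex", "PC1", "PC2", "PC3", "PC4", "PC5", "lipid_medication"],
    "regional": ["sex", "age", "PC1", "PC2", "PC3", "PC4", "PC5", "lipid_medication"],
}


def classify_damaging(
    ann: pd.DataFrame, maf_max: float = DEFAULT_DAMAGING_MAF_MAX
) -> set[str]:
    """Variant ids qualifying as rare damaging.

    Requires columns variant_id, maf, class, n_damaging_algorithms.
    Included ⇔ maf < maf_max AND (LoF OR clinvar_pathogenic OR
    (missense_damaging AND n_damaging_algorithms ≥ 1)).
    """
    if not 0.0 < maf_max <= 0.5:
        raise ValueError("maf_max must lie in (0, 0.5]")
    bad = set(ann["class"]) - set(DAMAGING_CLASSES) - {"benign"}
    if bad:
        raise ValueError(f"unknown variant classes: {sorted(bad)}")
    rare = ann["maf"] < maf_max
    damaging = (
        (ann["class"] == "LoF")
        | (ann["class"] == "clinvar_pathogenic")
        | ((ann["class"] == "missense_damaging") & (ann["n_damaging_algorithms"] >= 1))
    )
    return set(ann.loc[rare & damaging, "variant_id"])


def carrier_status(
    genotypes: GenotypeMatrix, damaging: set[str], gene_map: dict
) -> pd.DataFrame:
    """Per-sample, per-gene carrier indicator (any-of rule).

    carrier(i, g) = 1 ⇔ dosage > 0 at any damaging variant mapped to g;
    missing dosages count as non-carrier. Genes with no damaging
    variants are omitted.
    """
    missing = damaging - set(gene_map)
    if missing:
        raise ValueError(f"gene_map does not cover {len(missing)} damaging variants")
    vids = genotypes.variants["variant_id"].to_numpy()
    cols = {}
    for j, vid in enumerate(vids):
        if vid in damaging:
            cols.setdefault(gene_map[vid], []).append(j)
    out = {}
    d = np.nan_to_num(genotypes.dosages, nan=0.0)
    for gene, idx in sorted(cols.items()):
        out[gene] = (d[:, idx] > 0).any(axis=1).astype(int)
    return pd.DataFrame(out, index=list(genotypes.sample_ids))


@dataclass
class BurdenResult:
    gene: str
    trait: str
    kind: str  # "binary" or "quantitative"
    n_carriers: int
    n_noncarriers: int
    p: float
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    beta: float | None = None
    se: float | None = None


def fisher_burden(
    carrier: np.ndarray, case: np.ndarray, gene: str = "", trait: str = ""
) -> BurdenResult:
    """Fisher's exact test of carrier status against a binary trait.

    Two-sided exact P by the point-probability rule; sample odds ratio
    with Haldane 0.5 correction when any cell is zero, and a Woolf
    (log-OR normal) 95% CI on the corrected table. A zero carrier
    margin returns P = 1 with the OR missing.
    """
    carrier = np.asarray(carrier, dtype=int)
    case = np.asarray(case, dtype=int)
    if carrier.shape != case.shape or carrier.size == 0:
        raise ValueError("carrier and case must be aligned, non-empty")
    a = int(np.sum((carrier == 1) & (case == 1)))
    b = int(np.sum((carrier == 1) & (case == 0)))
    c = int(np.sum((carrier == 0) & (case == 1)))
    d = int(np.sum((carrier == 0) & (case == 0)))
    n_car, n_non = a + b, c + d
    if n_car == 0 or n_non == 0 or (a + c) == 0 or (b + d) == 0:
        return BurdenResult(gene, trait, "binary", n_car, n_non, p=1.0)
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    orr = (a2 * d2) / (b2 * c2)
    se_log = np.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
    zc = norm.ppf(0.975)
    return BurdenResult(
        gene, trait, "binary", n_car, n_non, p=float(p),
        odds_ratio=float(orr),
        ci_low=float(np.exp(np.log(orr) - zc * se_log)),
        ci_high=float(np.exp(np.log(orr) + zc * se_log)),
    )


def quantitative_assoc(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float, float]:
    """OLS of a trait on a predictor with covariate adjustment.

    Returns (beta, se, two-sided t-based P) for x. Covariate columns
    that are collinear are dropped with a warning; x collinear with the
    covariates (or constant) is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    base = [np.ones_like(x)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        for j in range(cov.shape[1]):
            trial = np.column_stack(base + [cov[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                base.append(cov[:, j])
            else:
                logger.warning("dropping collinear covariate column %d", j)
    # the predictor must add rank beyond intercept + covariates
    basis = np.column_stack(base)
    if np.linalg.matrix_rank(np.column_stack([basis, x])) == basis.shape[1]:
        raise ValueError("predictor is constant or collinear with the covariates")
    X = np.column_stack([base[0], x] + base[1:])
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("too few samples for the requested model")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def burden_scan(
    carriers: pd.DataFrame,
    phenotypes: pd.DataFrame,
    binary_traits: list[str],
    quantitative_traits: list[str],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """All gene × trait burden tests; one row per test."""
    rows = []
    cov = phenotypes[covariates].to_numpy(dtype=float) if covariates else None
    for gene in carriers.columns:
        car = carriers[gene].to_numpy()
        for trait in binary_traits:
            r = fisher_burden(car, phenotypes[trait].to_numpy(), gene, trait)
            rows.append(r.__dict__)
        for trait in quantitative_traits:
            if car.std() == 0:
                logger.info("gene %s: constant carrier status, skipped", gene)
                continue
            beta, se, p = quantitative_assoc(car, phenotypes[trait].to_numpy(), cov)
            rows.append(
                BurdenResult(
                    gene, trait, "quantitative",
                    int(car.sum()), int(len(car) - car.sum()),
                    p=p, beta=beta, se=se,
                ).__dict__
            )
    return pd.DataFrame(rows)


def effective_tests(genotypes: GenotypeMatrix, min_samples: int = 30) -> float:
    """Effective number of independent tests in a correlated variant set.

    Eigenvalue-based estimator on the variant correlation matrix:
    M_eff = Σ_i [1(λ_i ≥ 1) + (λ_i − ⌊λ_i⌋)], bounded in [1, M].
    Constant variant columns are dropped before the correlation.
    """
    d = genotypes.mean_impute().dosages
    keep = d.std(axis=0) > 1e-12
    d = d[:, keep]
    m = d.shape[1]
    if m < 2:
        raise ValueError("need at least 2 non-constant variants")
    if d.shape[0] < min_samples:
        raise ValueError(f"need at least {min_samples} samples")
    corr = np.corrcoef(d, rowvar=False)
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    # the floor rule is discontinuous at integers; round off eigenvalue
    # noise so exact-degeneracy cases (duplicated variants) land cleanly
    lam = np.round(lam, 10)
    m_eff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return float(np.clip(m_eff, 1.0, m))


def regional_association(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    maf_min: float = DEFAULT_REGIONAL_MAF_MIN,
    info_min: float = DEFAULT_INFO_MIN,
    info: np.ndarray | None = None,
    n_traits: int = 1,
    alpha: float = 0.05,
    m_eff: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Per-variant trait association in a region with M_eff correction.

    Variants are filtered by MAF > maf_min (strict) and imputation info
    score > info_min (info defaults to 1 for directly generated data);
    each passing variant is tested by covariate-adjusted OLS. The
    Bonferroni threshold is alpha / (M_eff × n_traits), with M_eff
    either supplied (e.g. from an external estimator) or computed from
    the regional correlation matrix. Rows carry both the Bonferroni and
    genome-wide (P < 5e-8) significance flags.
    """
    maf = genotypes.maf()
    if info is None:
        info = np.ones(genotypes.n_variants)
    keep = (maf > maf_min) & (np.asarray(info) > info_min)
    g = genotypes.take_variants(keep).mean_impute()
    if g.n_variants == 0:
        raise ValueError("no variants pass the regional filters")
    if m_eff is None:
        m_eff = effective_tests(g) if g.n_variants > 1 else 1.0
    threshold = alpha / (m_eff * n_traits)
    rows = []
    for j in range(g.n_variants):
        x = g.dosages[:, j]
        if x.std() <= 1e-12:
            continue
        beta, se, p = quantitative_assoc(x, trait, covariates)
        rows.append(
            {
                "variant_id": g.variants.loc[j, "variant_id"],
                "chrom": g.variants.loc[j, "chrom"],
                "pos": int(g.variants.loc[j, "pos"]),
                "beta": beta,
                "se": se,
                "p": p,
                "bonferroni_sig": p < threshold,
                "genome_wide_sig": p < GENOME_WIDE_P,
            }
        )
    return pd.DataFrame(rows), float(m_eff)
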