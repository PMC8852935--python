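"""Synthetic reference panels, GWAS cohorts and rare-variant data.

The generator emulates the statistical structure a TWAS pipeline
assumes:

* genotypes from a Gaussian copula — one latent AR(1) normal vector per
  sample per gene block, thresholded at each variant's Hardy–Weinberg
  genotype quantiles, giving cheap, seedable, controllable LD;
* multi-tissue expression where each gene has a sparse set of causal
  cis-eQTLs explaining a drawn cis heritability, with causal variants
  enriched in an epigenomic annotation class at a configurable odds
  ratio;
* case-control cohorts under a liability-threshold (probit) disease
  model whose liability loads on the true genetically regulated
  expression of designated causal genes;
* a second reference panel sharing the first panel's true eQTL effects
  but with independent samples and noise;
* rare (MAF < 0.01) damaging variants with additive carrier effects on
  quantitative traits.

Every draw flows through one `numpy.random.Generator` seeded from the
config, so identical config + seed reproduces outputs bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .datatypes import ExpressionMatrix, GenotypeMatrix

VARIANT_CLASSES = ("LoF", "clinvar_pathogenic", "missense_damaging", "benign")


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic data generator.

    Defaults are desk-scale stand-ins for the two-reference-panel,
    multi-cohort case-control design: a few hundred reference samples
    per panel, a handful of cohorts, ±1 Mb cis windows and sparse causal
    eQTL architecture.
    """

    n_ref_a: int = 300
    n_ref_b: int = 200
    n_cohorts: int = 2
    cohort_sizes: list = field(default_factory=lambda: [(500, 500), (500, 500)])
    n_genes: int = 100
    n_tissues: int = 2
    cis_window_bp: int = 1_000_000
    snps_per_gene: int = 20
    ld_rho: float = 0.6
    maf_range: tuple = (0.05, 0.5)
    h2_cis_range: tuple = (0.05, 0.4)
    n_causal_snps_per_gene: int = 2
    annotation_enrichment_or: float = 4.0
    annotation_baseline_rate: float = 0.2
    causal_gene_fraction: float = 0.05
    liability_effect_sd: float = 0.15
    prevalence: float = 0.1
    rare_maf_range: tuple = (0.0005, 0.009)
    lncRNA_fraction: float = 0.15
    genes_per_block: int = 2
    dosage_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_ref_a": self.n_ref_a,
            "n_ref_b": self.n_ref_b,
            "n_cohorts": self.n_cohorts,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "cis_window_bp": self.cis_window_bp,
            "snps_per_gene": self.snps_per_gene,
            "n_causal_snps_per_gene": self.n_causal_snps_per_gene,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if len(self.cohort_sizes) != self.n_cohorts:
            raise ConfigurationError("cohort_sizes length must equal n_cohorts")
        if any(nc <= 0 or nt <= 0 for nc, nt in self.cohort_sizes):
            raise ConfigurationError("cohort case/control counts must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        lo, hi = self.h2_cis_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("h2_cis_range must lie within [0, 1]")
        if self.annotation_enrichment_or < 1.0:
            raise ConfigurationError("annotation_enrichment_or must be >= 1")
        if not 0.0 < self.annotation_baseline_rate < 1.0:
            raise ConfigurationError("annotation_baseline_rate must lie in (0, 1)")
        if not 0.0 <= self.causal_gene_fraction <= 1.0:
            raise ConfigurationError("causal_gene_fraction must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigurationError("prevalence must lie in (0, 1)")
        lo, hi = self.rare_maf_range
        if not (0.0 < lo <= hi < 0.01):
            raise ConfigurationError("rare_maf_range must lie within (0, 0.01)")
        if self.n_causal_snps_per_gene > self.snps_per_gene:
            raise ConfigurationError("n_causal_snps_per_gene exceeds snps_per_gene")
        if self.genes_per_block <= 0:
            raise ConfigurationError("genes_per_block must be positive")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["cohort_sizes"] = [list(x) for x in self.cohort_sizes]
        d["maf_range"] = list(self.maf_range)
        d["h2_cis_range"] = list(self.h2_cis_range)
        d["rare_maf_range"] = list(self.rare_maf_range)
        return d


@dataclass
class SimulationTruth:
    """Ground truth for recovery tests.

    eqtl_effects: tissue -> gene -> list of (variant_id, effect);
    causal_genes: gene -> liability coefficient (nonzero exactly for
    causal genes); rare_effects: gene -> list of (trait, effect);
    annotation_flags: variant_id -> 0/1 epigenomic annotation;
    h2_cis / maf / panel layout kept for diagnostics.
    """

    eqtl_effects: dict = field(default_factory=dict)
    causal_genes: dict = field(default_factory=dict)
    rare_effects: dict = field(default_factory=dict)
    annotation_flags: dict = field(default_factory=dict)
    h2_cis: dict = field(default_factory=dict)
    variant_maf: dict = field(default_factory=dict)
    gene_block: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "eqtl_effects": {
                t: {g: [[v, float(b)] for v, b in lst] for g, lst in genes.items()}
                for t, genes in self.eqtl_effects.items()
            },
            "causal_genes": {g: float(a) for g, a in self.causal_genes.items()},
            "rare_effects": {
                g: [[t, float(b)] for t, b in lst] for g, lst in self.rare_effects.items()
            },
            "annotation_flags": {v: int(a) for v, a in self.annotation_flags.items()},
            "h2_cis": {g: float(h) for g, h in self.h2_cis.items()},
            "variant_maf": {v: float(m) for v, m in self.variant_maf.items()},
            "gene_block": {g: list(map(int, b)) for g, b in self.gene_block.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            eqtl_effects={
                t: {g: [(v, float(b)) for v, b in lst] for g, lst in genes.items()}
                for t, genes in d.get("eqtl_effects", {}).items()
            },
            causal_genes={g: float(a) for g, a in d.get("causal_genes", {}).items()},
            rare_effects={
                g: [(t, float(b)) for t, b in lst]
                for g, lst in d.get("rare_effects", {}).items()
            },
            annotation_flags={v: int(a) for v, a in d.get("annotation_flags", {}).items()},
            h2_cis={g: float(h) for g, h in d.get("h2_cis", {}).items()},
            variant_maf={v: float(m) for v, m in d.get("variant_maf", {}).items()},
            gene_block={g: tuple(map(int, b)) for g, b in d.get("gene_block", {}).items()},
        )


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

BLOCK_SPACING_BP = 3_000_000  # LD blocks far enough apart to be independent
SNP_SPACING_BP = 5_000


def _n_blocks(config: SimulationConfig) -> int:
    return -(-config.n_genes // config.genes_per_block)


def _gene_block_of(config: SimulationConfig, g: int) -> int:
    return g // config.genes_per_block


def _variant_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic positions on a single synthetic chromosome.

    Each LD block carries snps_per_gene variants per resident gene
    (genes_per_block genes share a block, so cis neighbours exist);
    blocks are separated beyond the cis window and hence independent.
    """
    rows = []
    snps_per_block = config.snps_per_gene * config.genes_per_block
    for b in range(_n_blocks(config)):
        start = 1 + b * BLOCK_SPACING_BP
        for j in range(snps_per_block):
            rows.append(
                {
                    "variant_id": f"chr1_{start + j * SNP_SPACING_BP}_A_G",
                    "chrom": "chr1",
                    "pos": start + j * SNP_SPACING_BP,
                    "ref": "A",
                    "alt": "G",
                    "block": b,
                }
            )
    return pd.DataFrame(rows)


def _gene_layout(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_lnc = int(round(config.lncRNA_fraction * config.n_genes))
    biotype = np.array(["coding"] * config.n_genes, dtype=object)
    if n_lnc > 0:
        biotype[rng.choice(config.n_genes, size=n_lnc, replace=False)] = "lncRNA"
    rows = []
    snps_per_block = config.snps_per_gene * config.genes_per_block
    for g in range(config.n_genes):
        b = _gene_block_of(config, g)
        start = 1 + b * BLOCK_SPACING_BP
        within = g % config.genes_per_block
        # TSSs of a block's genes are spread across the block
        tss = start + (within * config.snps_per_gene + config.snps_per_gene // 2) * SNP_SPACING_BP
        rows.append(
            {"gene_id": f"G{g:04d}", "chrom": "chr1", "tss_pos": tss, "biotype": biotype[g]}
        )
    return pd.DataFrame(rows)


def _draw_mafs(config: SimulationConfig, rng: np.random.Generator, m: int) -> np.ndarray:
    lo, hi = config.maf_range
    return rng.uniform(lo, hi, size=m)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _copula_dosages(
    rng: np.random.Generator,
    n: int,
    mafs: np.ndarray,
    blocks: np.ndarray,
    ld_rho: float,
    dosage_noise_sd: float = 0.0,
) -> np.ndarray:
    """Latent AR(1) normal per block, thresholded to HWE genotype frequencies.

    The alt allele is the minor allele (frequency = MAF). Per variant the
    latent standard normal is cut at Φ⁻¹((1−p)²) and Φ⁻¹(1−p²) so hard
    dosages follow Hardy–Weinberg proportions.
    """
    m = len(mafs)
    z = np.empty((n, m))
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        k = len(idx)
        e = rng.standard_normal((n, k))
        zb = np.empty((n, k))
        zb[:, 0] = e[:, 0]
        if ld_rho > 0:
            s = np.sqrt(1.0 - ld_rho**2)
            for j in range(1, k):
                zb[:, j] = ld_rho * zb[:, j - 1] + s * e[:, j]
        else:
            zb[:, 1:] = e[:, 1:]
        z[:, idx] = zb
    p = mafs
    t0 = ndtri((1.0 - p) ** 2)  # below: hom ref (dosage 0)
    t1 = ndtri(1.0 - p**2)  # above: hom alt (dosage 2)
    d = (z > t0).astype(float) + (z > t1).astype(float)
    if dosage_noise_sd > 0:
        d = np.clip(d + rng.normal(0.0, dosage_noise_sd, size=d.shape), 0.0, 2.0)
    return d


def simulate_genotypes(config: SimulationConfig, n: int, rng=None) -> GenotypeMatrix:
    """Draw n samples of genotype dosages for the config's variant layout."""
    if n <= 0:
        raise ConfigurationError(f"sample count must be positive, got {n}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layout = _variant_layout(config)
    # MAF draw depends only on config + the rng stream position
    maf_rng = np.random.default_rng(config.seed + 101)
    mafs = _draw_mafs(config, maf_rng, len(layout))
    d = _copula_dosages(
        rng, n, mafs, layout["block"].to_numpy(), config.ld_rho, config.dosage_noise_sd
    )
    variants = layout.drop(columns=["block"]).copy()
    variants["true_maf"] = mafs
    return GenotypeMatrix(
        sample_ids=[f"S{i:05d}" for i in range(n)], variants=variants, dosages=d
    )


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------


def simulate_reference_panel(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    truth: SimulationTruth | None = None,
    panel: str = "A",
) -> tuple[dict, pd.DataFrame, SimulationTruth]:
    """Expression per tissue + variant annotations + ground truth.

    If `truth` is given (panel B), its eQTL effects and annotations are
    reused so the second panel shares the first panel's genetic
    architecture; only samples and noise are independent.
    """
    rng = np.random.default_rng(config.seed + 7 + (0 if truth is None else 13))
    layout = _variant_layout(config)
    genes = _gene_layout(config, np.random.default_rng(config.seed + 3))
    blocks = layout["block"].to_numpy()
    vids = layout["variant_id"].to_numpy()

    fresh = truth is None
    if fresh:
        truth = SimulationTruth()
        lo, hi = config.h2_cis_range
        h2 = rng.uniform(lo, hi, size=config.n_genes)
        # causal variant choice and effect sizes shared across tissues
        for g in range(config.n_genes):
            gid = genes.loc[g, "gene_id"]
            truth.h2_cis[gid] = float(h2[g])
            b = _gene_block_of(config, g)
            truth.gene_block[gid] = (b,)
            in_block = np.flatnonzero(
                (blocks == b)
                & (np.abs(layout["pos"].to_numpy() - genes.loc[g, "tss_pos"]) <= config.cis_window_bp)
            )
            if len(in_block) < config.n_causal_snps_per_gene:
                raise ConfigurationError(
                    f"gene {gid}: fewer cis variants than n_causal_snps_per_gene"
                )
            causal = rng.choice(in_block, size=config.n_causal_snps_per_gene, replace=False)
            effects = rng.standard_normal(config.n_causal_snps_per_gene)
            for t in range(config.n_tissues):
                tissue = f"T{t}"
                truth.eqtl_effects.setdefault(tissue, {})[gid] = [
                    (vids[c], float(b)) for c, b in zip(causal, effects)
                ]
        # annotations: causal variants enriched at the configured odds ratio
        p_bg = config.annotation_baseline_rate
        odds_bg = p_bg / (1 - p_bg)
        p_causal = (config.annotation_enrichment_or * odds_bg) / (
            1 + config.annotation_enrichment_or * odds_bg
        )
        causal_ids = {
            v for genes_d in truth.eqtl_effects.values() for lst in genes_d.values() for v, _ in lst
        }
        for v in vids:
            rate = p_causal if v in causal_ids else p_bg
            truth.annotation_flags[v] = int(rng.random() < rate)
        for v, m in zip(vids, layout_mafs(config)):
            truth.variant_maf[v] = float(m)

    vid_to_col = {v: j for j, v in enumerate(genotypes.variants["variant_id"])}
    expr_by_tissue = {}
    for t in range(config.n_tissues):
        tissue = f"T{t}"
        values = np.empty((config.n_genes, genotypes.n_samples))
        for g in range(config.n_genes):
            gid = genes.loc[g, "gene_id"]
            h2g = truth.h2_cis[gid]
            genetic = np.zeros(genotypes.n_samples)
            for v, b in truth.eqtl_effects[tissue][gid]:
                genetic += b * genotypes.dosages[:, vid_to_col[v]]
            var_g = genetic.var()
            if h2g > 0 and var_g <= 0:
                raise ConfigurationError(
                    f"gene {gid}: positive h2 but causal dosages are constant"
                )
            if h2g >= 1.0:
                noise_sd = 0.0
            elif h2g > 0:
                noise_sd = float(np.sqrt(var_g * (1 - h2g) / h2g))
            else:
                genetic = np.zeros_like(genetic)
                noise_sd = 1.0
            values[g] = genetic + rng.normal(0.0, noise_sd, size=genotypes.n_samples)
        expr_by_tissue[tissue] = ExpressionMatrix(
            genes=genes.copy(), sample_ids=list(genotypes.sample_ids), values=values, tissue=tissue
        )

    annotations = pd.DataFrame(
        {"variant_id": vids, "annotated": [truth.annotation_flags[v] for v in vids]}
    )
    if fresh:
        # designate causal genes for the disease model
        n_causal = int(round(config.causal_gene_fraction * config.n_genes))
        rng2 = np.random.default_rng(config.seed + 23)
        causal_idx = (
            rng2.choice(config.n_genes, size=n_causal, replace=False) if n_causal else []
        )
        for g in range(config.n_genes):
            gid = genes.loc[g, "gene_id"]
            if g in set(np.atleast_1d(causal_idx)):
                # fixed magnitude, random sign: keeps detectability a
                # function of h2_cis alone across causal genes
                sign = 1.0 if rng2.random() < 0.5 else -1.0
                truth.causal_genes[gid] = float(sign * config.liability_effect_sd)
    return expr_by_tissue, annotations, truth


def layout_mafs(config: SimulationConfig) -> np.ndarray:
    """The per-variant population MAFs implied by config + seed."""
    layout = _variant_layout(config)
    maf_rng = np.random.default_rng(config.seed + 101)
    return _draw_mafs(config, maf_rng, len(layout))


# ---------------------------------------------------------------------------
# GWAS cohorts
# ---------------------------------------------------------------------------


def _true_grex(
    config: SimulationConfig, genotypes: GenotypeMatrix, truth: SimulationTruth, tissue: str = "T0"
) -> dict:
    vid_to_col = {v: j for j, v in enumerate(genotypes.variants["variant_id"])}
    out = {}
    for gid in truth.causal_genes:
        g = np.zeros(genotypes.n_samples)
        for v, b in truth.eqtl_effects[tissue][gid]:
            g += b * genotypes.dosages[:, vid_to_col[v]]
        out[gid] = g
    return out


def simulate_gwas_cohorts(
    config: SimulationConfig,
    truth: SimulationTruth,
    with_covariates: bool = True,
    max_oversample: int = 40,
) -> list[tuple[GenotypeMatrix, pd.DataFrame]]:
    """Case-control cohorts under the liability-threshold model.

    Liability ℓ_i = Σ_g α_g·GReX_true(i, g) + ε_i with ε ~ N(0, 1);
    cases are draws with ℓ above the (1 − prevalence) quantile of the
    liability distribution, sampled down to the requested counts.
    Optional covariates (sex, five PCs) are generated independent of
    disease status so both adjusted and unadjusted association models
    are testable.
    """
    cohorts = []
    alpha = truth.causal_genes
    for c, (n_case, n_control) in enumerate(config.cohort_sizes):
        rng = np.random.default_rng(config.seed + 1000 + c)
        # liability threshold: quantile of the marginal liability distribution,
        # estimated on a large reference draw so prevalence is respected
        pool_n = max(2000, 4 * (n_case + n_control))
        case_rows, control_rows = [], []
        case_geno, control_geno = [], []
        tries = 0
        while (len(case_rows) < n_case or len(control_rows) < n_control) and tries < max_oversample:
            tries += 1
            g = simulate_genotypes(config, pool_n, rng=rng)
            grex = _true_grex(config, g, truth)
            genetic = np.zeros(pool_n)
            for gid, a in alpha.items():
                genetic += a * grex[gid]
            liability = genetic + rng.standard_normal(pool_n)
            if tries == 1:
                # threshold from this cohort's own large draw
                thr = np.quantile(liability, 1.0 - config.prevalence)
            is_case = liability > thr
            for i in np.flatnonzero(is_case):
                if len(case_rows) < n_case:
                    case_rows.append(i)
                    case_geno.append(g.dosages[i])
            for i in np.flatnonzero(~is_case):
                if len(control_rows) < n_control:
                    control_rows.append(i)
                    control_geno.append(g.dosages[i])
        if len(case_rows) < n_case or len(control_rows) < n_control:
            raise GenerationError(
                f"cohort {c}: could not draw {n_case} cases / {n_control} controls "
                f"within {max_oversample} pools of {pool_n}"
            )
        dosages = np.vstack(case_geno + control_geno)
        status = np.r_[np.ones(n_case), np.zeros(n_control)]
        n = n_case + n_control
        sample_ids = [f"C{c}_{i:05d}" for i in range(n)]
        layout = _variant_layout(config)
        variants = layout.drop(columns=["block"]).copy()
        variants["true_maf"] = layout_mafs(config)
        geno = GenotypeMatrix(sample_ids=sample_ids, variants=variants, dosages=dosages)
        pheno = pd.DataFrame({"sample_id": sample_ids, "status": status.astype(int)})
        if with_covariates:
            crng = np.random.default_rng(config.seed + 5000 + c)
            pheno["sex"] = crng.integers(0, 2, size=n)
            for k in range(5):
                pheno[f"PC{k + 1}"] = crng.standard_normal(n)
        cohorts.append((geno, pheno))
    return cohorts


# ---------------------------------------------------------------------------
# rare variants
# ---------------------------------------------------------------------------


def simulate_rare_variants(
    config: SimulationConfig,
    n: int,
    n_rare_per_gene: int = 5,
    n_traits: int = 3,
    effect_genes: dict | None = None,
    truth: SimulationTruth | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Rare damaging variants + quantitative traits with carrier effects.

    Every rare variant has population MAF drawn in rare_maf_range
    (< 0.01) and an annotation class from {LoF, clinvar_pathogenic,
    missense_damaging, benign}; carriers of any non-benign variant of an
    effect gene receive an additive shift (in trait SD units) on the
    designated trait. Returns (genotypes, annotation table, phenotype
    table, updated truth).
    """
    if n <= 0:
        raise ConfigurationError("sample count must be positive")
    rng = np.random.default_rng(config.seed + 9000)
    if truth is None:
        truth = SimulationTruth()
    genes = _gene_layout(config, np.random.default_rng(config.seed + 3))
    if effect_genes is None:
        effect_genes = {}
    lo, hi = config.rare_maf_range
    rows, cols = [], []
    classes = np.array(VARIANT_CLASSES, dtype=object)
    class_p = np.array([0.2, 0.1, 0.4, 0.3])
    for g in range(config.n_genes):
        gid = genes.loc[g, "gene_id"]
        base = 1 + g * BLOCK_SPACING_BP + 2_000_000
        for j in range(n_rare_per_gene):
            maf = rng.uniform(lo, hi)
            cls = classes[rng.choice(4, p=class_p)]
            n_alg = int(rng.integers(1, 6)) if cls == "missense_damaging" else 0
            dos = rng.binomial(2, maf, size=n).astype(float)
            vid = f"chr1_{base + j * 100}_C_T"
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": "chr1",
                    "pos": base + j * 100,
                    "ref": "C",
                    "alt": "T",
                    "gene": gid,
                    "maf": maf,
                    "class": cls,
                    "n_damaging_algorithms": n_alg,
                }
            )
            cols.append(dos)
    meta = pd.DataFrame(rows)
    dosages = np.column_stack(cols)
    sample_ids = [f"W{i:05d}" for i in range(n)]
    geno = GenotypeMatrix(
        sample_ids=sample_ids,
        variants=meta[["variant_id", "chrom", "pos", "ref", "alt"]].copy(),
        dosages=dosages,
    )
    annotations = meta[["variant_id", "gene", "maf", "class", "n_damaging_algorithms"]].copy()

    # carrier indicators of damaging variants per effect gene
    traits = pd.DataFrame({"sample_id": sample_ids})
    trait_names = [f"trait_{t}" for t in range(n_traits)]
    y = rng.standard_normal((n, n_traits))
    for gid, (trait, shift) in effect_genes.items():
        vmask = (meta["gene"] == gid) & (meta["class"] != "benign")
        carrier = (dosages[:, vmask.to_numpy()] > 0).any(axis=1)
        ti = trait_names.index(trait)
        y[carrier, ti] += shift
        truth.rare_effects.setdefault(gid, []).append((trait, float(shift)))
    for t, name in enumerate(trait_names):
        traits[name] = y[:, t]
    crng = np.random.default_rng(config.seed + 9500)
    traits["sex"] = crng.integers(0, 2, size=n)
    for k in range(5):
        traits[f"PC{k + 1}"] = crng.standard_normal(n)
    traits["lipid_medication"] = crng.integers(0, 2, size=n)
    return geno, annotations, traits, truth
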