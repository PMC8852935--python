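"""Seeded orchestration of the full pipeline on simulated data.

Stages run in dependency order — simulate → qc → train → twas → coloc →
burden → network — writing each stage's tables under the run directory
plus a provenance manifest (config hash, seed, per-stage row counts and
output hashes). A rerun with the same config and seed reproduces every
output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .coloc import DEFAULT_PP4_MIN, SummaryStats, coloc_posteriors
from .burden import burden_scan, carrier_status, classify_damaging
from .models import (
    DEFAULT_ALPHA,
    DEFAULT_N_FOLDS,
    DEFAULT_R2_MIN,
    estimate_snp_priors,
    filter_models,
    train_weighted_elastic_net,
)
from .network import DEFAULT_R_MIN, coexpression_edges
from .qc import (
    DEFAULT_CALL_RATE_MIN,
    DEFAULT_HWE_MIN,
    DEFAULT_MAF_MIN,
    inverse_normal_genes,
    quantile_normalize_samples,
    variant_qc,
)
from .simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_gwas_cohorts,
    simulate_rare_variants,
    simulate_reference_panel,
)
from .twas import (
    annotate_novelty,
    associate_grex,
    bonferroni_threshold,
    impute_grex,
    merge_panels,
    meta_analyze,
    twas_genes,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "train", "twas", "coloc", "burden", "network")


@dataclass
class PipelineConfig:
    """All module parameters with their conventional defaults."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple = STAGES
    call_rate_min: float = DEFAULT_CALL_RATE_MIN
    maf_min: float = DEFAULT_MAF_MIN
    hwe_min: float = DEFAULT_HWE_MIN
    n_folds: int = DEFAULT_N_FOLDS
    elastic_net_alpha: float = DEFAULT_ALPHA
    r2_min: float = DEFAULT_R2_MIN
    alpha: float = 0.05
    window_bp: int = 1_000_000
    pp4_min: float = DEFAULT_PP4_MIN
    r_min: float = DEFAULT_R_MIN
    burden_maf_max: float = 0.01
    seed: int = 0

    KNOWN_KEYS = {
        "simulation", "stages", "call_rate_min", "maf_min", "hwe_min", "n_folds",
        "elastic_net_alpha", "r2_min", "alpha", "window_bp", "pp4_min", "r_min",
        "burden_maf_max", "seed",
    }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - cls.KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            for tuple_key in ("maf_range", "h2_cis_range", "rare_maf_range"):
                if tuple_key in sim:
                    sim[tuple_key] = tuple(sim[tuple_key])
            if "cohort_sizes" in sim:
                sim["cohort_sizes"] = [tuple(x) for x in sim["cohort_sizes"]]
            sim = SimulationConfig(**sim)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(simulation=sim, **d)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = self.simulation.as_dict()
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; returns the provenance manifest.

    A stage failure halts downstream stages; completed outputs are kept
    and the manifest records the failure.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            runner = _STAGE_RUNNERS[stage]
            info = runner(config, state, out)
            manifest["stages"][stage] = {"status": "complete", **info}
    except Exception as exc:  # noqa: BLE001 - recorded in the manifest
        logger.exception("stage failed")
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest["status"] = "failed"
    else:
        manifest["status"] = "complete"
    manifest["outputs"] = {
        p.name: _file_hash(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json"))
        if p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> dict:
    sim = config.simulation
    geno_a = simulate_genotypes(sim, sim.n_ref_a)
    expr_a, ann, truth = simulate_reference_panel(sim, geno_a, panel="A")
    geno_b = simulate_genotypes(
        sim, sim.n_ref_b, rng=np.random.default_rng(sim.seed + 77)
    )
    expr_b, _, truth = simulate_reference_panel(sim, geno_b, truth=truth, panel="B")
    cohorts = simulate_gwas_cohorts(sim, truth)
    rare_geno, rare_ann, rare_pheno, truth = simulate_rare_variants(
        sim,
        n=2000,
        effect_genes=_default_rare_effects(truth),
        truth=truth,
    )
    state.update(
        geno_a=geno_a, geno_b=geno_b, expr_a=expr_a, expr_b=expr_b,
        annotations=ann, truth=truth, cohorts=cohorts,
        rare=(rare_geno, rare_ann, rare_pheno),
    )
    tio.write_truth_json(truth, out / "truth.json")
    ann.to_csv(out / "annotations.tsv", sep="\t", index=False)
    tio.write_dosage_tsv(geno_a, out / "panel_a_dosages.tsv")
    tio.write_expression_tsv(expr_a["T0"], out / "panel_a_expression_T0.tsv")
    return {
        "n_ref_a": geno_a.n_samples,
        "n_ref_b": geno_b.n_samples,
        "n_cohorts": len(cohorts),
        "n_variants": geno_a.n_variants,
    }


def _default_rare_effects(truth) -> dict:
    genes = sorted(truth.causal_genes)[:2]
    return {g: ("trait_0", 1.0) for g in genes}


def _stage_qc(config: PipelineConfig, state: dict, out: Path) -> dict:
    reports = {}
    for panel in ("a", "b"):
        g, rep = variant_qc(
            state[f"geno_{panel}"], config.call_rate_min, config.maf_min, config.hwe_min
        )
        state[f"geno_{panel}"] = g
        reports[panel] = rep.as_dict()
        expr = state[f"expr_{panel}"]
        state[f"expr_{panel}"] = {
            t: inverse_normal_genes(quantile_normalize_samples(e)) for t, e in expr.items()
        }
    pd.DataFrame(reports).T.to_csv(out / "qc_report.tsv", sep="\t")
    return {"panel_a": reports["a"], "panel_b": reports["b"]}


def _stage_train(config: PipelineConfig, state: dict, out: Path) -> dict:
    ann = state["annotations"].set_index("variant_id")["annotated"]
    counts = {}
    for panel_key, panel in (("a", "A"), ("b", "B")):
        g = state[f"geno_{panel_key}"]
        models_all = []
        for tissue, e in state[f"expr_{panel_key}"].items():
            # marginal eQTL z-scores for the prior: best cis |z| per variant
            z = _marginal_z(g, e)
            flags = ann.reindex(g.variants["variant_id"]).fillna(0).to_numpy(dtype=int)
            priors = estimate_snp_priors(z, flags, list(g.variants["variant_id"]))
            m = train_weighted_elastic_net(
                g, e,
                priors=priors,
                cis_window_bp=config.simulation.cis_window_bp,
                mixing=config.elastic_net_alpha,
                n_folds=config.n_folds,
                panel=panel,
                seed=config.seed,
            )
            models_all.append(filter_models(m, config.r2_min))
        merged = models_all[0]
        for m in models_all[1:]:
            for e_ in m:
                merged.add(e_)
        state[f"models_{panel_key}"] = merged
        counts[panel] = len(merged)
        tio.write_model_store(
            merged, out / f"models_{panel}_weights.tsv", out / f"models_{panel}_summary.tsv"
        )
    return {"n_models": counts}


def _marginal_z(g, e) -> np.ndarray:
    """Best |z| over genes for each variant, from marginal correlations."""
    d = g.mean_impute().dosages
    sd = d.std(axis=0)
    ok = sd > 1e-12
    ds = np.zeros_like(d)
    ds[:, ok] = (d[:, ok] - d[:, ok].mean(axis=0)) / sd[ok]
    v = e.values
    vs = (v - v.mean(axis=1, keepdims=True)) / np.maximum(v.std(axis=1, keepdims=True), 1e-12)
    r = (vs @ ds) / g.n_samples  # genes x variants
    n = g.n_samples
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt(n - 3)  # Fisher-transform scale approximation
    return np.abs(z).max(axis=0)


def _stage_twas(config: PipelineConfig, state: dict, out: Path) -> dict:
    results = {}
    for panel_key in ("a", "b"):
        models = state[f"models_{panel_key}"]
        tables = []
        for geno, pheno in state["cohorts"]:
            grex = impute_grex(geno, models)
            if grex.values.shape[1] == 0:
                continue
            tab = associate_grex(grex, pheno["status"].to_numpy())
            tables.append(tab)
        results[panel_key] = (
            meta_analyze(tables) if tables else pd.DataFrame(
                columns=["gene", "tissue", "panel", "beta", "se", "z", "p"]
            )
        )
    merged, counts = merge_panels(results["a"], results["b"])
    m_tests = len(merged)
    threshold = bonferroni_threshold(config.alpha, max(m_tests, 1))
    gene_pos = state["expr_a"]["T0"].genes
    genes = twas_genes(merged, threshold, gene_positions=gene_pos)
    catalog = pd.DataFrame(columns=["chrom", "pos", "label"])
    genes = annotate_novelty(genes, catalog, window_bp=config.window_bp)
    merged.to_csv(out / "twas_associations.tsv", sep="\t", index=False)
    genes.to_csv(out / "twas_genes.tsv", sep="\t", index=False)
    state["twas_merged"] = merged
    state["twas_genes"] = genes
    state["twas_threshold"] = threshold
    return {
        "n_pairs_a": counts.n_a, "n_pairs_b": counts.n_b,
        "n_overlap": counts.n_overlap, "n_union": counts.n_union,
        "threshold": threshold,
        "n_significant": int(genes["significant"].sum()),
    }


def _stage_coloc(config: PipelineConfig, state: dict, out: Path) -> dict:
    """Colocalize eQTL and GWAS marginal signals at each significant gene."""
    geno_ref = state["geno_a"]
    expr = state["expr_a"]["T0"]
    geno_gwas, pheno = state["cohorts"][0]
    y = pheno["status"].to_numpy(dtype=float)
    sig = state["twas_genes"]
    rows = []
    for _, grow in sig[sig["significant"]].iterrows():
        gid = grow["gene"]
        gi = expr.genes.index[expr.genes["gene_id"] == gid]
        if len(gi) == 0:
            continue
        row = expr.genes.loc[gi[0]]
        cis = (
            (geno_ref.variants["chrom"] == row["chrom"])
            & ((geno_ref.variants["pos"] - row["tss_pos"]).abs() <= config.simulation.cis_window_bp)
        ).to_numpy()
        t_eqtl = _marginal_stats(geno_ref.take_variants(cis), expr.values[gi[0]])
        gwas_sub = geno_gwas.take_variants(
            geno_gwas.variants["variant_id"].isin(t_eqtl["variant_id"]).to_numpy()
        )
        t_gwas = _marginal_stats(gwas_sub, y)
        res = coloc_posteriors(
            SummaryStats(t_eqtl, "quantitative"),
            SummaryStats(t_gwas, "case_control", case_fraction=float(y.mean())),
            pp4_min=config.pp4_min,
        )
        rows.append({"gene": gid, **res.as_dict()})
    tab = pd.DataFrame(rows)
    tab.to_csv(out / "coloc.tsv", sep="\t", index=False)
    n_coloc = int(tab["colocalized"].sum()) if len(tab) else 0
    return {"n_loci": len(tab), "n_colocalized": n_coloc}


def _marginal_stats(g, y) -> pd.DataFrame:
    d = g.mean_impute().dosages
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    rows = []
    for j in range(g.n_variants):
        x = d[:, j]
        sx = x.std()
        if sx <= 1e-12:
            continue
        xc = x - x.mean()
        n = len(y)
        beta = float(xc @ yc / (xc @ xc))
        resid = yc - beta * xc
        se = float(np.sqrt((resid @ resid) / (n - 2) / (xc @ xc)))
        rows.append(
            {"variant_id": g.variants.loc[j, "variant_id"], "beta": beta, "se": max(se, 1e-12)}
        )
    return pd.DataFrame(rows)


def _stage_burden(config: PipelineConfig, state: dict, out: Path) -> dict:
    rare_geno, rare_ann, rare_pheno = state["rare"]
    damaging = classify_damaging(rare_ann, maf_max=config.burden_maf_max)
    gene_map = dict(zip(rare_ann["variant_id"], rare_ann["gene"]))
    carriers = carrier_status(rare_geno, damaging, gene_map)
    quant = [c for c in rare_pheno.columns if c.startswith("trait_")]
    tab = burden_scan(
        carriers, rare_pheno,
        binary_traits=[], quantitative_traits=quant,
        covariates=["sex", "PC1", "PC2", "PC3", "PC4", "PC5", "lipid_medication"],
    )
    n_tests = max(len(tab), 1)
    tab["bonferroni_sig"] = tab["p"] < config.alpha / n_tests
    tab.to_csv(out / "burden.tsv", sep="\t", index=False)
    return {"n_tests": len(tab), "n_damaging_variants": len(damaging)}


def _stage_network(config: PipelineConfig, state: dict, out: Path) -> dict:
    edges_all = []
    for tissue, e in state["expr_a"].items():
        edges_all.append(coexpression_edges(e, r_min=config.r_min, window_bp=config.window_bp))
    edges = pd.concat(edges_all, ignore_index=True)
    edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
    return {"n_edges": len(edges)}


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "train": _stage_train,
    "twas": _stage_twas,
    "coloc": _stage_coloc,
    "burden": _stage_burden,
    "network": _stage_network,
}
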