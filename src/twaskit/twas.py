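"""GReX imputation, case-control association, meta-analysis and merging.

Genetically regulated expression (GReX) is imputed per sample as the
weighted sum of alt-allele dosages over each model's variants. Per
cohort, case status is regressed on standardized GReX (plus optional
covariates) by logistic regression; cohorts are combined by
fixed-effect inverse-variance meta-analysis with Cochran's Q and I²
heterogeneity. The results from the two reference panels are merged by
keeping, per gene-tissue pair, the record with the smaller P; per gene
the minimum P across tissues defines the TWAS gene row, flagged
significant at the Bonferroni threshold and annotated known/novel
against a catalog of published GWAS loci (± 1 Mb window).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, chi2

from .datatypes import GenotypeMatrix, PredictionModelSet

logger = logging.getLogger(__name__)

DEFAULT_COVERAGE_FLOOR = 0.5
DEFAULT_WINDOW_BP = 1_000_000


@dataclass
class GReXMatrix:
    """samples × (gene, tissue, panel) imputed expression."""

    sample_ids: list[str]
    columns: list[tuple]  # (gene, tissue, panel)
    values: np.ndarray
    coverage: dict = field(default_factory=dict)  # column -> fraction of model SNPs found


def impute_grex(
    genotypes: GenotypeMatrix,
    models: PredictionModelSet,
    coverage_floor: float = DEFAULT_COVERAGE_FLOOR,
) -> GReXMatrix:
    """GReX(i, m) = Σ_j w_j · dosage(i, j) on each model's alt allele.

    Cohort variants whose ref/alt are swapped relative to the model are
    flipped (dosage → 2 − dosage); model variants absent from the cohort
    contribute 0. Models whose weighted variants are covered below
    `coverage_floor` are skipped with a warning.
    """
    g = genotypes.mean_impute()
    by_id = {}
    for j, (vid, ref, alt) in enumerate(
        zip(g.variants["variant_id"], g.variants["ref"], g.variants["alt"])
    ):
        by_id[vid] = (j, ref, alt)
    cols, vals, coverage = [], [], {}
    for e in models:
        nz_ids, nz_w = e.nonzero()
        x = np.zeros(g.n_samples)
        found = 0
        for vid, w in zip(nz_ids, nz_w):
            hit = by_id.get(vid)
            if hit is None:
                continue
            j, ref, alt = hit
            k = e.variant_ids.index(vid)
            if ref == e.ref[k] and alt == e.alt[k]:
                d = g.dosages[:, j]
            elif ref == e.alt[k] and alt == e.ref[k]:
                d = 2.0 - g.dosages[:, j]
            else:
                logger.warning("variant %s: allele mismatch, skipped", vid)
                continue
            x += w * d
            found += 1
        cov = found / len(nz_ids) if nz_ids else 1.0
        key = (e.gene, e.tissue, e.panel)
        if cov < coverage_floor:
            logger.warning("model %s coverage %.2f below floor, skipped", key, cov)
            continue
        coverage[key] = cov
        cols.append(key)
        vals.append(x)
    values = np.column_stack(vals) if vals else np.empty((g.n_samples, 0))
    return GReXMatrix(list(g.sample_ids), cols, values, coverage)


def associate_grex(
    grex: GReXMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    n_case_min: int = 10,
) -> pd.DataFrame:
    """Per-column logistic regression of case status on standardized GReX.

    Returns one row per (gene, tissue, panel) with Wald beta (per GReX
    SD), se, z, p and the case/control counts. Constant columns are
    skipped; non-converged or separated fits are dropped with a reason.
    """
    y = np.asarray(phenotype, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    n_case = int(y.sum())
    n_control = int(len(y) - n_case)
    if n_case < n_case_min or n_control < n_case_min:
        raise ValueError(f"need >= {n_case_min} cases and controls")
    rows = []
    for c, key in enumerate(grex.columns):
        x = grex.values[:, c]
        sd = x.std()
        if sd <= 1e-12:
            logger.info("constant GReX column %s skipped", key)
            continue
        xs = (x - x.mean()) / sd
        design = [np.ones_like(xs), xs]
        if covariates is not None:
            design.extend(np.asarray(covariates, dtype=float).T)
        X = np.column_stack(design)
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                raise RuntimeError("no convergence")
            beta, se = fit.params[1], fit.bse[1]
            if not (np.isfinite(beta) and np.isfinite(se)) or se > 50:
                raise RuntimeError("separation")
        except Exception as exc:  # noqa: BLE001 - dropped with reason, never silent
            logger.warning("association failed for %s: %s", key, exc)
            continue
        z = beta / se
        rows.append(
            {
                "gene": key[0],
                "tissue": key[1],
                "panel": key[2],
                "beta": beta,
                "se": se,
                "z": z,
                "p": 2.0 * norm.sf(abs(z)),
                "n_case": n_case,
                "n_control": n_control,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "tissue", "panel", "beta", "se", "z", "p", "n_case", "n_control"]
    )


def meta_analyze(tables: list[pd.DataFrame], method: str = "ivw") -> pd.DataFrame:
    """Combine per-cohort association tables across cohorts.

    Fixed-effect inverse-variance ("ivw", default): beta = Σw_kβ_k/Σw_k
    with w_k = 1/se_k², se = (Σw_k)^(−1/2), Cochran's Q and
    I² = max(0, (Q − (k−1))/Q). "stouffer" combines sample-size-weighted
    z-scores instead. Records present in a single cohort pass through
    with Q and I² missing.
    """
    if not tables:
        raise ValueError("no cohort tables")
    if method not in ("ivw", "stouffer"):
        raise ValueError(f"unknown method {method!r}")
    stacked = pd.concat([t.assign(cohort=i) for i, t in enumerate(tables)], ignore_index=True)
    rows = []
    for key, grp in stacked.groupby(["gene", "tissue", "panel"], sort=True):
        beta_k = grp["beta"].to_numpy()
        se_k = grp["se"].to_numpy()
        k = len(grp)
        if method == "ivw":
            w = 1.0 / se_k**2
            beta = float(np.sum(w * beta_k) / np.sum(w))
            se = float(np.sum(w) ** -0.5)
            z = beta / se
        else:
            n_k = (grp["n_case"] + grp["n_control"]).to_numpy(dtype=float)
            z_k = grp["z"].to_numpy()
            z = float(np.sum(np.sqrt(n_k) * z_k) / np.sqrt(np.sum(n_k)))
            w = 1.0 / se_k**2
            beta = float(np.sum(w * beta_k) / np.sum(w))
            se = abs(beta / z) if z != 0 else float("nan")
        if k > 1:
            w = 1.0 / se_k**2
            beta_fe = float(np.sum(w * beta_k) / np.sum(w))
            q = float(np.sum(w * (beta_k - beta_fe) ** 2))
            i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
            q_p = float(chi2.sf(q, k - 1))
        else:
            q, i2, q_p = np.nan, np.nan, np.nan
        rows.append(
            {
                "gene": key[0],
                "tissue": key[1],
                "panel": key[2],
                "beta": beta,
                "se": se,
                "z": z,
                "p": 2.0 * norm.sf(abs(z)),
                "n_cohorts": k,
                "n_case": int(grp["n_case"].sum()),
                "n_control": int(grp["n_control"].sum()),
                "Q": q,
                "Q_p": q_p,
                "I2": i2,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test significance level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


@dataclass
class MergeCounts:
    n_a: int
    n_b: int
    n_overlap: int

    @property
    def n_union(self) -> int:
        return self.n_a + self.n_b - self.n_overlap


def merge_panels(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, MergeCounts]:
    """Integrate two panels' association tables by lowest P per gene-tissue.

    Returns the union of gene-tissue pairs (winning panel recorded) and
    the count algebra n_union = n_a + n_b − n_overlap.
    """
    key = ["gene", "tissue"]
    frames = [t for t in (a, b) if len(t)] or [a]
    both = pd.concat(frames, ignore_index=True)
    merged = both.sort_values("p", kind="mergesort").drop_duplicates(subset=key, keep="first")
    merged = merged.sort_values(key).reset_index(drop=True)
    pairs_a = set(map(tuple, a[key].itertuples(index=False)))
    pairs_b = set(map(tuple, b[key].itertuples(index=False)))
    counts = MergeCounts(len(pairs_a), len(pairs_b), len(pairs_a & pairs_b))
    return merged, counts


def twas_genes(
    merged: pd.DataFrame,
    p_threshold: float,
    gene_positions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene summary: best tissue(s), min P, significance flag.

    gene_positions (gene_id, chrom, tss_pos) is carried through for
    novelty annotation; genes without a position are left unplaced.
    """
    rows = []
    for gene, grp in merged.groupby("gene", sort=True):
        i = grp["p"].idxmin()
        min_p = float(grp.loc[i, "p"])
        best = grp[grp["p"] == min_p]
        rows.append(
            {
                "gene": gene,
                "best_tissues": ";".join(sorted(best["tissue"].astype(str))),
                "best_panel": str(grp.loc[i, "panel"]),
                "z": float(grp.loc[i, "z"]),
                "min_p": min_p,
                "n_tissues_tested": grp["tissue"].nunique(),
                "significant": bool(min_p < p_threshold),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene", "best_tissues", "best_panel", "z", "min_p",
            "n_tissues_tested", "significant",
        ],
    )
    if gene_positions is not None:
        out = out.merge(
            gene_positions[["gene_id", "chrom", "tss_pos"]].rename(columns={"gene_id": "gene"}),
            on="gene",
            how="left",
        )
    return out


def annotate_novelty(
    genes: pd.DataFrame,
    catalog: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Mark each gene known/novel against a catalog of published loci.

    known ⇔ same chromosome and |gene TSS − locus pos| ≤ window_bp for
    any catalog entry; genes lacking a position are left 'unclassified'.
    Catalog columns: chrom, pos (1-based) [, label].
    """
    out = genes.copy()
    novelty = []
    for _, row in out.iterrows():
        chrom, tss = row.get("chrom"), row.get("tss_pos")
        if chrom is None or (isinstance(tss, float) and np.isnan(tss)) or pd.isna(chrom):
            novelty.append("unclassified")
            continue
        near = catalog[
            (catalog["chrom"] == chrom) & ((catalog["pos"] - tss).abs() <= window_bp)
        ]
        novelty.append("known" if len(near) else "novel")
    out["novelty"] = novelty
    return out
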