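"""Core in-memory containers shared across the pipeline.

Genotypes are held as a samples × variants dosage matrix (float, NaN =
missing call) with a variant metadata frame; expression as a genes ×
samples matrix with a gene metadata frame. Coordinates are 1-based,
following VCF convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]
GENE_COLUMNS = ["gene_id", "chrom", "tss_pos", "biotype"]

BIOTYPES = ("coding", "lncRNA")


@dataclass
class GenotypeMatrix:
    """Samples × variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    sample_ids : list of str
    variants : DataFrame with columns variant_id, chrom, pos (1-based),
        ref, alt; one row per dosage column, variant_id unique.
    dosages : float array, shape (n_samples, n_variants), entries in
        [0, 2], NaN for missing calls.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicated variant ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per variant among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency: min(p, 1-p) of the alt frequency."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def hwe_p(self) -> np.ndarray:
        """Exact Hardy-Weinberg P per variant (hard calls; dosages rounded)."""
        from .qc import hwe_exact_p

        out = np.ones(self.n_variants)
        hard = np.rint(self.dosages)
        for j in range(self.n_variants):
            col = hard[:, j]
            col = col[~np.isnan(col)]
            n_hom_ref = int(np.sum(col == 0))
            n_het = int(np.sum(col == 1))
            n_hom_alt = int(np.sum(col == 2))
            if n_hom_ref + n_het + n_hom_alt == 0:
                out[j] = 1.0
            else:
                out[j] = hwe_exact_p(n_hom_ref, n_het, n_hom_alt)
        return out

    def take_variants(self, mask_or_idx) -> "GenotypeMatrix":
        """Subset variants by boolean mask or integer index, keeping order."""
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(idx), dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )

    def mean_impute(self) -> "GenotypeMatrix":
        """Replace missing dosages by the per-variant mean (post-QC step)."""
        d = self.dosages.copy()
        col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.nonzero(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
        return replace(self, dosages=d)


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix for one tissue.

    genes : DataFrame with columns gene_id, chrom, tss_pos (1-based),
        biotype in {coding, lncRNA}.
    values : float array, shape (n_genes, n_samples).
    """

    genes: pd.DataFrame
    sample_ids: list[str]
    values: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.sample_ids)} samples"
            )
        missing = [c for c in GENE_COLUMNS if c not in self.genes.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicated gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_values(self, gene_id: str) -> np.ndarray:
        i = self.genes.index[self.genes["gene_id"] == gene_id]
        if len(i) == 0:
            raise KeyError(gene_id)
        return self.values[i[0]]


@dataclass
class ModelEntry:
    """One trained cis expression prediction model."""

    gene: str
    tissue: str
    panel: str
    variant_ids: list[str]
    weights: np.ndarray  # effect per alt-allele dosage unit
    ref: list[str]
    alt: list[str]
    intercept: float
    cv_r2: float  # squared out-of-fold Pearson correlation
    cv_r2_var: float  # 1 - MSE/Var variant of the same quantity
    n_train: int

    def nonzero(self) -> tuple[list[str], np.ndarray]:
        keep = np.flatnonzero(self.weights != 0)
        return [self.variant_ids[i] for i in keep], self.weights[keep]


@dataclass
class PredictionModelSet:
    """Collection of ModelEntry keyed by (gene, tissue, panel)."""

    entries: dict = field(default_factory=dict)

    def add(self, entry: ModelEntry) -> None:
        self.entries[(entry.gene, entry.tissue, entry.panel)] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.values())

    def get(self, gene: str, tissue: str, panel: str) -> ModelEntry:
        return self.entries[(gene, tissue, panel)]

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": e.gene,
                "tissue": e.tissue,
                "panel": e.panel,
                "cv_r2": e.cv_r2,
                "cv_r2_var": e.cv_r2_var,
                "n_snps": int(np.sum(e.weights != 0)),
                "n_train": e.n_train,
            }
            for e in self
        ]
        return pd.DataFrame(
            rows,
            columns=["gene", "tissue", "panel", "cv_r2", "cv_r2_var", "n_snps", "n_train"],
        )
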