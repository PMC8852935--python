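"""Variant-level genotype QC and the two-step expression normalisation.

Genotype QC removes variants failing any of three filters — call rate,
minor allele frequency, and an exact Hardy–Weinberg equilibrium test —
with the conventional defaults call rate ≥ 0.95, MAF ≥ 0.01 and HWE
P ≥ 1e-6. Expression is normalised in two steps: sample-level quantile
normalisation (every sample gets the same marginal distribution) followed
by gene-level inverse-normal transformation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, ndtri

from .datatypes import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_CALL_RATE_MIN = 0.95
DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_MIN = 1e-6


@dataclass
class QCReport:
    """Per-rule removal counts; a variant failing several rules counts under each."""

    n_input: int
    n_retained: int
    n_fail_call_rate: int
    n_fail_maf: int
    n_fail_hwe: int

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "call_rate": self.n_fail_call_rate,
            "maf": self.n_fail_maf,
            "hwe": self.n_fail_hwe,
        }


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg equilibrium P for one biallelic variant.

    Two-sided exact test conditional on the observed allele counts:
    sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count. Monomorphic
    sites return 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    probs = _het_count_probs(n, n_minor)
    # heterozygote counts share parity with the minor-allele count
    obs = probs.get(n_het)
    if obs is None:
        raise ValueError("heterozygote count incompatible with allele counts")
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12))
    return min(1.0, p)


@lru_cache(maxsize=100_000)
def _het_count_probs(n: int, n_minor: int) -> dict:
    """Conditional distribution of the heterozygote count given allele counts.

    P(het = h | n, n_minor) over h with the same parity as n_minor, from
    the permutation formula of the exact conditional test.
    """
    n_major = 2 * n - n_minor
    hs = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hs) // 2
    hom_major = n - hs - hom_minor
    valid = hom_major >= 0
    hs, hom_minor, hom_major = hs[valid], hom_minor[valid], hom_major[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hs + 1)
        - gammaln(hom_minor + 1)
        + hs * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return {int(h): float(v) for h, v in zip(hs, p)}


def variant_qc(
    g: GenotypeMatrix,
    call_rate_min: float = DEFAULT_CALL_RATE_MIN,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_min: float = DEFAULT_HWE_MIN,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter variants on call rate, MAF and HWE; pure row filter.

    A variant is retained iff call_rate ≥ call_rate_min AND
    maf ≥ maf_min AND hwe_p ≥ hwe_min. Retained dosage columns are
    bit-identical to the input.
    """
    for name, t in (("call_rate_min", call_rate_min), ("maf_min", maf_min), ("hwe_min", hwe_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {t}")
    if g.n_variants == 0:
        raise ValueError("empty genotype matrix")
    cr = g.call_rate()
    maf = g.maf()
    hwe = g.hwe_p()
    fail_cr = cr < call_rate_min
    fail_maf = maf < maf_min
    fail_hwe = hwe < hwe_min
    keep = ~(fail_cr | fail_maf | fail_hwe)
    report = QCReport(
        n_input=g.n_variants,
        n_retained=int(keep.sum()),
        n_fail_call_rate=int(fail_cr.sum()),
        n_fail_maf=int(fail_maf.sum()),
        n_fail_hwe=int(fail_hwe.sum()),
    )
    if report.n_retained == 0:
        logger.warning("variant QC removed every variant (%d input)", g.n_variants)
    return g.take_variants(keep), report


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    from scipy.stats import rankdata

    return rankdata(x, method="average")


def quantile_normalize_samples(e: ExpressionMatrix) -> ExpressionMatrix:
    """Sample-level quantile normalisation.

    Each sample (column) is mapped onto the across-sample mean of sorted
    value vectors, preserving within-sample ranks; ties receive the mean
    of the target values they span. Idempotent.
    """
    if e.n_samples < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    v = e.values
    sorted_mean = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        ranks = _average_ranks(v[:, j])  # 1..n_genes, ties averaged
        # interpolate so tied observations get the mean of spanned targets
        out[:, j] = np.interp(ranks, np.arange(1, v.shape[0] + 1), sorted_mean)
    return replace(e, values=out)


def inverse_normal_genes(e: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-level inverse-normal (rank-based) transformation.

    Per gene, values become Φ⁻¹((rank − 0.5)/n) with average ranks for
    ties; the offset keeps the transform symmetric and finite.
    """
    if e.n_samples < 3:
        raise ValueError("inverse-normal transform needs at least 3 samples")
    v = e.values
    out = np.empty_like(v)
    n = v.shape[1]
    for i in range(v.shape[0]):
        ranks = _average_ranks(v[i, :])
        out[i, :] = ndtri((ranks - 0.5) / n)
    return replace(e, values=out)
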