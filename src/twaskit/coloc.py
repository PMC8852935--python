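"""Bayesian colocalization of eQTL and GWAS signals at a locus.

Under the single-causal-variant assumption, each variant's evidence for
association with a trait is summarised by the Wakefield approximate
Bayes factor computed from its effect estimate and standard error, and
the five sharing hypotheses are scored:

    H0 no association with either trait
    H1 association with trait 1 only
    H2 association with trait 2 only
    H3 both traits, distinct causal variants
    H4 both traits, one shared causal variant

Posterior probabilities PP0…PP4 follow from the per-hypothesis masses
with priors p1, p2 (single-trait) and p12 (shared). The decision rule
used downstream is PP4 > 0.55.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_PP4_MIN = 0.55
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class SummaryStats:
    """Per-variant summary statistics for one trait at one locus."""

    table: pd.DataFrame  # variant_id, beta, se [, ref, alt]
    trait_type: str = "quantitative"  # or "case_control"
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        need = {"variant_id", "beta", "se"}
        if not need <= set(self.table.columns):
            raise ValueError(f"summary stats need columns {sorted(need)}")
        if (self.table["se"] <= 0).any():
            raise ValueError("all standard errors must be positive")
        if self.table["variant_id"].duplicated().any():
            raise ValueError("duplicated variant ids")
        if self.trait_type not in ("quantitative", "case_control"):
            raise ValueError("trait_type must be quantitative or case_control")

    @property
    def default_prior_sd(self) -> float:
        return (
            PRIOR_SD_CASE_CONTROL if self.trait_type == "case_control" else PRIOR_SD_QUANTITATIVE
        )


def se_from_z(z: np.ndarray, maf: np.ndarray, n: np.ndarray, case_fraction=None) -> np.ndarray:
    """Approximate the standard error from z, MAF and sample size.

    Var(beta) ≈ 1 / (2·maf·(1−maf)·n) for quantitative traits, divided
    by s(1−s) for case-control traits with case fraction s.
    """
    v = 1.0 / (2.0 * maf * (1.0 - maf) * n)
    if case_fraction is not None:
        v = v / (case_fraction * (1.0 - case_fraction))
    return np.sqrt(v)


def wakefield_log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for a single variant.

    With V = se², W = prior_sd², r = W/(V+W) and z = beta/se:
    log ABF = ½[log(1 − r) + r z²].
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    p1: float
    p2: float
    p12: float
    pp4_min: float = DEFAULT_PP4_MIN

    @property
    def colocalized(self) -> bool:
        return self.pp4 > self.pp4_min

    def as_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4, "n_variants": self.n_variants,
            "colocalized": self.colocalized,
        }


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a ≥ b; −inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def intersect_stats(t1: SummaryStats, t2: SummaryStats, drop_palindromic: bool = True):
    """Align two summary-stat tables on variant id (and alleles when given)."""
    a, b = t1.table, t2.table
    merged = a.merge(b, on="variant_id", suffixes=("_1", "_2"))
    if {"ref_1", "alt_1", "ref_2", "alt_2"} <= set(merged.columns):
        same = (merged["ref_1"] == merged["ref_2"]) & (merged["alt_1"] == merged["alt_2"])
        flipped = (merged["ref_1"] == merged["alt_2"]) & (merged["alt_1"] == merged["ref_2"])
        merged.loc[flipped, "beta_2"] = -merged.loc[flipped, "beta_2"]
        merged = merged[same | flipped]
        if drop_palindromic:
            pal = [
                (r, a_) in PALINDROMIC for r, a_ in zip(merged["ref_1"], merged["alt_1"])
            ]
            if any(pal):
                logger.warning("dropping %d strand-ambiguous palindromic variants", sum(pal))
            merged = merged[~np.asarray(pal)]
    return merged


def coloc_posteriors(
    t1: SummaryStats,
    t2: SummaryStats,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd_1: float | None = None,
    prior_sd_2: float | None = None,
    pp4_min: float = DEFAULT_PP4_MIN,
) -> ColocResult:
    """Posterior probabilities of the five sharing hypotheses for one locus.

    All sums run in log space (log-sum-exp) so strong signals cannot
    overflow. The H3 mass uses the off-diagonal product sum
    Σ_{i≠j} ABF1_i ABF2_j = Σ_i ABF1_i · Σ_j ABF2_j − Σ_i ABF1_i ABF2_i.
    """
    for name, pr in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not 0.0 < pr < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    merged = intersect_stats(t1, t2)
    if len(merged) == 0:
        raise ValueError("no shared variants between the two traits")
    sd1 = prior_sd_1 if prior_sd_1 is not None else t1.default_prior_sd
    sd2 = prior_sd_2 if prior_sd_2 is not None else t2.default_prior_sd
    l1 = np.atleast_1d(
        wakefield_log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), sd1)
    )
    l2 = np.atleast_1d(
        wakefield_log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), sd2)
    )
    pp = posteriors_from_log_abf(l1, l2, p1, p2, p12)
    return ColocResult(
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        n_variants=int(len(merged)), p1=p1, p2=p2, p12=p12, pp4_min=pp4_min,
    )


def posteriors_from_log_abf(
    l1: np.ndarray,
    l2: np.ndarray,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> np.ndarray:
    """PP0…PP4 from aligned per-variant log Bayes factors of both traits.

    All hypothesis masses are accumulated in log space (log-sum-exp),
    so arbitrarily large log ABFs — hundreds of log units — cannot
    overflow; only ratios of masses enter the posteriors.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("log ABF vectors must be aligned")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)
    q = len(l1)
    if q == 1:
        s3 = -np.inf  # no distinct-variant configuration exists
    elif q <= 500:
        # exact off-diagonal log-sum-exp; avoids cancellation on small loci
        pair = l1[:, None] + l2[None, :]
        s3 = logsumexp(pair[~np.eye(q, dtype=bool)])
    else:
        s3 = _logdiffexp(s1 + s2, s12)
    log_h = np.array(
        [
            0.0,
            np.log(p1) + s1,
            np.log(p2) + s2,
            np.log(p1) + np.log(p2) + s3,
            np.log(p12) + s12,
        ]
    )
    pp = np.exp(log_h - logsumexp(log_h))
    return pp / pp.sum()
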