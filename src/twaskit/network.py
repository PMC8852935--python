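"""lncRNA–coding co-expression edges and hypergeometric gene-set enrichment.

An edge connects a lncRNA gene to a protein-coding gene when the
absolute Pearson correlation of their expression exceeds the threshold
(default 0.4, strict). By default pairs are restricted to cis
neighbourhoods (same chromosome, TSS distance ≤ 1 Mb). Enrichment of a
query gene list against named gene sets uses the right-tailed
hypergeometric test with Benjamini–Hochberg FDR across sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_R_MIN = 0.4
DEFAULT_WINDOW_BP = 1_000_000


def coexpression_edges(
    e: ExpressionMatrix,
    r_min: float = DEFAULT_R_MIN,
    cis_only: bool = True,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """lncRNA × coding pairs with |Pearson r| strictly above r_min.

    Constant genes are skipped; r is reported signed. Columns:
    gene_a (lncRNA), gene_b (coding), tissue, r.
    """
    if e.n_samples < 10:
        raise ValueError("need at least 10 samples for co-expression")
    genes = e.genes
    lnc = np.flatnonzero((genes["biotype"] == "lncRNA").to_numpy())
    cod = np.flatnonzero((genes["biotype"] == "coding").to_numpy())
    sd = e.values.std(axis=1)
    lnc = lnc[sd[lnc] > 1e-12]
    cod = cod[sd[cod] > 1e-12]
    rows = []
    if len(lnc) and len(cod):
        vl = e.values[lnc]
        vc = e.values[cod]
        zl = (vl - vl.mean(axis=1, keepdims=True)) / vl.std(axis=1, keepdims=True)
        zc = (vc - vc.mean(axis=1, keepdims=True)) / vc.std(axis=1, keepdims=True)
        r = (zl @ zc.T) / e.n_samples
        for i, gi in enumerate(lnc):
            for j, gj in enumerate(cod):
                if cis_only:
                    if genes.loc[gi, "chrom"] != genes.loc[gj, "chrom"]:
                        continue
                    if abs(int(genes.loc[gi, "tss_pos"]) - int(genes.loc[gj, "tss_pos"])) > window_bp:
                        continue
                if abs(r[i, j]) > r_min:
                    rows.append(
                        {
                            "gene_a": genes.loc[gi, "gene_id"],
                            "gene_b": genes.loc[gj, "gene_id"],
                            "tissue": e.tissue,
                            "r": float(r[i, j]),
                        }
                    )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tissue", "r"])


def hypergeometric_enrichment(
    query: set[str], sets: dict[str, set[str]], universe: set[str]
) -> pd.DataFrame:
    """Right-tailed hypergeometric enrichment with BH FDR across sets.

    P = P(X ≥ k), X ~ Hypergeom(N=len(universe), K=|set ∩ universe|,
    n=|query|); gene sets are intersected with the universe before
    testing. Rows sorted by P.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    N, n = len(universe), len(query)
    for set_id, members in sets.items():
        K = len(members & universe)
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append({"set_id": set_id, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_id", "k", "K", "n", "N", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = []
    return out


def write_sif(edges: pd.DataFrame, path: str) -> None:
    """Cytoscape SIF export: gene_a coexpr gene_b, one edge per line."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['gene_a']}\tcoexpr\t{row['gene_b']}\n")
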