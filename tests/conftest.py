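import numpy as np
import pandas as pd
import pytest

from twaskit.datatypes import ExpressionMatrix, GenotypeMatrix
from twaskit.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=20,
        n_ref_a=200,
        n_ref_b=150,
        n_tissues=2,
        cohort_sizes=[(150, 150), (150, 150)],
        causal_gene_fraction=0.1,
        liability_effect_sd=0.6,
        seed=42,
    )


def make_genotypes(dosages, positions=None, chrom="chr1", ref="A", alt="G"):
    """GenotypeMatrix from a samples × variants array with default metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
        }
    )
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)], variants=variants, dosages=dosages
    )


def make_expression(values, tss=None, biotype=None, tissue="T0"):
    """ExpressionMatrix from a genes × samples array with default metadata."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    if tss is None:
        tss = [1000 * (i + 1) for i in range(g)]
    if biotype is None:
        biotype = ["coding"] * g
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(g)],
            "chrom": "chr1",
            "tss_pos": tss,
            "biotype": biotype,
        }
    )
    return ExpressionMatrix(
        genes=genes, sample_ids=[f"s{i}" for i in range(n)], values=values, tissue=tissue
    )
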