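"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 (GT + DS FORMAT fields; read back through
pysam) or as a plain TSV dosage matrix (variants × samples with a
metadata block). Expression, annotations, association results and the
model store are TSV; ground truth is JSON; gene sets are GMT.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, ModelEntry, PredictionModelSet
from .simulate import SimulationTruth

# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT (hard call from rounded dosage) and DS."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        chroms = list(dict.fromkeys(g.variants["chrom"]))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(g.n_variants):
            v = g.variants.iloc[j]
            fields = [str(v["chrom"]), str(int(v["pos"])), str(v["variant_id"]),
                      str(v["ref"]), str(v["alt"]), ".", "PASS", ".", "GT:DS"]
            col = g.dosages[:, j]
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gts[int(round(d))]}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read an uncompressed VCF via pysam, preferring DS over GT."""
    import pysam

    vf = pysam.VariantFile(str(path))
    sample_ids = list(vf.header.samples)
    rows, cols = [], []
    for rec in vf:
        alt = rec.alts[0] if rec.alts else "."
        vid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}_{rec.pos}_{rec.ref}_{alt}"
        rows.append(
            {"variant_id": vid, "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref, "alt": alt}
        )
        col = np.full(len(sample_ids), np.nan)
        for i, s in enumerate(sample_ids):
            smp = rec.samples[s]
            ds = smp.get("DS")
            if ds is not None:
                col[i] = float(ds)
            else:
                gt = smp.get("GT")
                if gt is not None and None not in gt:
                    col[i] = float(sum(gt))
        cols.append(col)
    dosages = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(sample_ids=sample_ids, variants=pd.DataFrame(rows), dosages=dosages)


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Variants × samples dosage TSV with a leading metadata block."""
    meta = g.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    dos = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    pd.concat([meta.reset_index(drop=True), dos], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variants=df[meta_cols].copy(),
        dosages=df[sample_ids].to_numpy(dtype=float).T,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def write_expression_tsv(e: ExpressionMatrix, path: str | Path) -> None:
    meta = e.genes[["gene_id", "chrom", "tss_pos", "biotype"]].copy()
    vals = pd.DataFrame(e.values, columns=e.sample_ids)
    out = pd.concat([meta.reset_index(drop=True), vals], axis=1)
    out.insert(0, "tissue", e.tissue)
    out.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    meta_cols = ["tissue", "gene_id", "chrom", "tss_pos", "biotype"]
    sample_ids = [c for c in df.columns if c not in meta_cols]
    tissue = str(df["tissue"].iloc[0]) if len(df) else ""
    return ExpressionMatrix(
        genes=df[["gene_id", "chrom", "tss_pos", "biotype"]].copy(),
        sample_ids=sample_ids,
        values=df[sample_ids].to_numpy(dtype=float),
        tissue=tissue,
    )


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def write_model_store(models: PredictionModelSet, weights_path, summary_path) -> None:
    """TSV pair: per-variant nonzero weights + per-model summary."""
    wrows = []
    for e in models:
        for k, vid in enumerate(e.variant_ids):
            if e.weights[k] != 0:
                wrows.append(
                    {
                        "gene": e.gene, "tissue": e.tissue, "panel": e.panel,
                        "variant_id": vid, "ref": e.ref[k], "alt": e.alt[k],
                        "weight": repr(float(e.weights[k])),
                        "intercept": repr(float(e.intercept)),
                    }
                )
    pd.DataFrame(
        wrows,
        columns=["gene", "tissue", "panel", "variant_id", "ref", "alt", "weight", "intercept"],
    ).to_csv(weights_path, sep="\t", index=False)
    summ = models.summary_frame()
    summ.to_csv(summary_path, sep="\t", index=False, float_format="%.17g")


def read_model_store(weights_path, summary_path) -> PredictionModelSet:
    w = pd.read_csv(weights_path, sep="\t", float_precision="round_trip")
    s = pd.read_csv(summary_path, sep="\t", float_precision="round_trip")
    out = PredictionModelSet()
    skey = {(r.gene, r.tissue, r.panel): r for r in s.itertuples()}
    grouped = w.groupby(["gene", "tissue", "panel"], sort=True)
    for key, grp in grouped:
        meta = skey[key]
        out.add(
            ModelEntry(
                gene=key[0], tissue=key[1], panel=key[2],
                variant_ids=list(grp["variant_id"]),
                weights=grp["weight"].to_numpy(dtype=float),
                ref=list(grp["ref"]),
                alt=list(grp["alt"]),
                intercept=float(grp["intercept"].iloc[0]),
                cv_r2=float(meta.cv_r2),
                cv_r2_var=float(meta.cv_r2_var),
                n_train=int(meta.n_train),
            )
        )
    # models that survived training but kept no nonzero weights only
    # appear in the summary; restore them with empty weight lists
    for key, meta in skey.items():
        if key not in out.entries:
            out.add(
                ModelEntry(
                    gene=key[0], tissue=key[1], panel=key[2],
                    variant_ids=[], weights=np.array([]), ref=[], alt=[],
                    intercept=0.0, cv_r2=float(meta.cv_r2),
                    cv_r2_var=float(meta.cv_r2_var), n_train=int(meta.n_train),
                )
            )
    return out


# ---------------------------------------------------------------------------
# misc tables
# ---------------------------------------------------------------------------


def write_truth_json(truth: SimulationTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.as_dict(), fh, indent=1, sort_keys=True)


def read_truth_json(path: str | Path) -> SimulationTruth:
    with open(path) as fh:
        return SimulationTruth.from_dict(json.load(fh))


def read_locus_catalog(path: str | Path) -> pd.DataFrame:
    """TSV of chrom, pos (1-based) [, label] published GWAS loci."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "pos"} <= set(df.columns):
        raise ValueError("locus catalog needs chrom and pos columns")
    if "label" in df.columns and df["label"].duplicated().any():
        raise ValueError("locus labels must be unique")
    if (df["pos"] <= 0).any():
        raise ValueError("locus positions must be positive")
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
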