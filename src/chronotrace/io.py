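"""Readers/writers for the plain-text formats the pipeline exchanges.

10x-style MTX triples (matrix.mtx + features.tsv + barcodes.tsv), TSV
tables, BED (0-based half-open) with a motif_id column, and a minimal GTF
for gene models.  Matrices travel as AnnData in memory.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .motifs import GeneModel

__all__ = [
    "write_mtx_triple",
    "read_mtx_triple",
    "write_bed",
    "read_bed",
    "write_gene_models_gtf",
    "read_gene_models",
    "gene_models_from_tsv",
]


def write_mtx_triple(adata: ad.AnnData, outdir: str | os.PathLike) -> None:
    """Write an AnnData as a 10x-style triple (genes x cells on disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.csc_matrix(adata.X).T  # features x cells, CellRanger orientation
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)


def read_mtx_triple(indir: str | os.PathLike) -> ad.AnnData:
    indir = Path(indir)
    mat = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx"))).T
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=mat)
    adata.var_names = features.to_list()
    adata.obs_names = cells.to_list()
    return adata


def write_bed(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """BED with columns chrom, start, end, motif_id (name), score, strand."""
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    name_col = "motif_id" if "motif_id" in out.columns else "name"
    out[["chrom", "start", "end", name_col, "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "motif_id", "score", "strand"])
    df["site_id"] = [f"site{i}" for i in range(len(df))]
    return df


def write_gene_models_gtf(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Minimal GTF: one `gene` feature per model (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write("\t".join([
                g.chrom, "chronotrace", "gene",
                str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
            ]) + "\n")


def read_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            gene_id = f[8].split('"')[1]
            genes.append(GeneModel(gene_id, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return genes


def gene_models_from_tsv(path_or_df) -> list[GeneModel]:
    """Gene models from a minimal TSV: gene, chrom, strand, start, end."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    return [
        GeneModel(str(r["gene"]), str(r["chrom"]), int(r["start"]), int(r["end"]),
                  str(r["strand"]))
        for _, r in df.iterrows()
    ]
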