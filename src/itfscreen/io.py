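"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, 10x-style MTX triplets via scipy/anndata, gene sets
via gseapy's GMT parser, plain-text gene lists one symbol per line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tags import OrfRecord, VectorContext


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA as an ordered {name: uppercase sequence} mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_orfs_fasta(path: str | Path) -> list[OrfRecord]:
    """One ORF per record; the header is the TF name."""
    return [OrfRecord(name=n, cds=s) for n, s in read_fasta(path).items()]


def read_vector_fasta(path: str | Path) -> VectorContext:
    """Vector context from a 2-record FASTA named ``upstream``/``downstream``.

    Falls back to record order when the names are absent.
    """
    seqs = read_fasta(path)
    if {"upstream", "downstream"} <= set(seqs):
        return VectorContext(upstream=seqs["upstream"], downstream=seqs["downstream"])
    if len(seqs) < 2:
        raise ValueError("vector FASTA needs upstream and downstream records")
    vals = list(seqs.values())
    return VectorContext(upstream=vals[0], downstream=vals[1])


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix as cells × genes: an MTX triplet directory or a dense TSV.

    MTX directories follow the 10x layout (matrix.mtx, features/genes.tsv,
    barcodes.tsv; matrix stored genes × cells). Dense TSV is cells in rows,
    genes in columns, first column = barcode.
    """
    p = Path(path)
    if p.is_dir():
        return read_mtx_dir(p)
    return pd.read_csv(p, sep="\t", index_col=0)


def read_mtx_dir(path: str | Path) -> pd.DataFrame:
    from scipy.io import mmread

    p = Path(path)
    mat = mmread(str(p / "matrix.mtx"))
    barcodes = pd.read_csv(p / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    feat_path = p / "features.tsv" if (p / "features.tsv").exists() else p / "genes.tsv"
    features = pd.read_csv(feat_path, sep="\t", header=None)
    genes = features.iloc[:, -1] if features.shape[1] == 1 else features.iloc[:, 1]
    dense = np.asarray(mat.todense())
    return pd.DataFrame(dense.T, index=barcodes.to_numpy(),
                        columns=genes.astype(str).to_numpy())


def write_mtx_dir(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a cells × genes matrix as a 10x-style genes × cells MTX triplet."""
    from scipy import sparse
    from scipy.io import mmwrite

    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    mmwrite(str(p / "matrix.mtx"), sparse.coo_matrix(counts.to_numpy().T))
    pd.Series(counts.index).to_csv(p / "barcodes.tsv", sep="\t", header=False,
                                   index=False)
    pd.DataFrame({"id": counts.columns, "name": counts.columns}).to_csv(
        p / "features.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (set name, description, members)."""
    import gseapy

    return {name: list(genes) for name, genes in gseapy.read_gmt(str(path)).items()}


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one symbol per line, blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
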