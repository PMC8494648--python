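"""Plain-text interchange: Matrix Market counts + TSV metadata, spatial CSVs,
and Newick export for dendrograms."""

from __future__ import annotations

import os

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from scipy.cluster.hierarchy import to_tree


def write_atlas(adata: ad.AnnData, outdir: str, truth=None) -> None:
    """Write counts as genes x cells Matrix Market plus cells.tsv/genes.tsv.

    If an AtlasTruth is given its columns are appended to the metadata tables.
    """
    os.makedirs(outdir, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    sio.mmwrite(os.path.join(outdir, "counts.mtx"), X.T.tocoo())
    cells = adata.obs.copy()
    genes = adata.var.copy()
    if truth is not None:
        cells = cells.join(truth.cells.add_prefix("truth_"))
        genes = genes.join(truth.genes.add_prefix("truth_"))
    cells.to_csv(os.path.join(outdir, "cells.tsv"), sep="\t")
    genes.to_csv(os.path.join(outdir, "genes.tsv"), sep="\t")


def read_atlas(outdir: str) -> ad.AnnData:
    """Read an atlas written by :func:`write_atlas` (truth columns ride along
    in obs/var)."""
    X = sio.mmread(os.path.join(outdir, "counts.mtx")).tocsr().T.tocsr()
    cells = pd.read_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index_col=0)
    genes = pd.read_csv(os.path.join(outdir, "genes.tsv"), sep="\t", index_col=0)
    genes_bool = genes.get("mito")
    if genes_bool is not None:
        genes["mito"] = genes_bool.astype(bool)
    return ad.AnnData(X=X.astype(np.int64), obs=cells, var=genes)


def write_spatial(scene, outdir: str, truth: pd.Series | None = None) -> None:
    os.makedirs(outdir, exist_ok=True)
    scene.nuclei.to_csv(os.path.join(outdir, "nuclei.csv"), index=False)
    spots = scene.spots.copy()
    if truth is not None:
        spots["truth_nucleus"] = truth.to_numpy()
    spots.to_csv(os.path.join(outdir, "spots.csv"), index=False)


def read_spatial(outdir: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    nuclei = pd.read_csv(os.path.join(outdir, "nuclei.csv"))
    spots = pd.read_csv(os.path.join(outdir, "spots.csv"))
    return nuclei, spots


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        dl = node.dist - left.dist
        dr = node.dist - right.dist
        return f"({render(left)}:{dl:.6g},{render(right)}:{dr:.6g})"

    return render(tree) + ";"
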