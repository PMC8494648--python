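"""Shared preprocessing: library-size normalization, HVG selection, PCA.

Thin deterministic wrappers over scanpy.  Raw counts always stay in ``X``;
normalized values live in ``layers["lognorm"]`` and PCs in ``obsm["X_pca"]``.
"""

from __future__ import annotations

import numpy as np
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData

TARGET_SUM = 1e4


def lognorm(adata: AnnData) -> AnnData:
    """Add ``layers['lognorm']`` = log1p of counts scaled to 10,000 per cell."""
    X = adata.X
    dense = X.astype(np.float64) if sp.issparse(X) else np.asarray(X, dtype=np.float64)
    tmp = AnnData(X=dense.copy())
    sc.pp.normalize_total(tmp, target_sum=TARGET_SUM)
    sc.pp.log1p(tmp)
    adata.layers["lognorm"] = tmp.X.astype(np.float64)
    return adata


def pca_embed(adata: AnnData, n_hvg: int = 2000, n_pcs: int = 50) -> np.ndarray:
    """Select up to ``n_hvg`` variable genes on the lognorm layer, scale, and
    return a deterministic PCA embedding (also stored in ``obsm['X_pca']``)."""
    if "lognorm" not in adata.layers:
        lognorm(adata)
    L = adata.layers["lognorm"]
    L = L.toarray() if sp.issparse(L) else np.asarray(L)
    var = L.var(axis=0)
    n_hvg = min(n_hvg, L.shape[1])
    hv = np.sort(np.argsort(-var, kind="stable")[:n_hvg])
    # centered but not variance-scaled: per-gene z-scaling lets the many
    # uninformative genes dominate kNN distances on sparse-signal data
    M = L[:, hv] - L[:, hv].mean(axis=0)
    n_pcs = min(n_pcs, M.shape[0] - 1, M.shape[1])
    n_pcs = max(n_pcs, 1)
    # full SVD is deterministic; matrices here are at most ~1e4 x 2e3
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    pcs = U[:, :n_pcs] * s[:n_pcs]
    # fix sign convention: largest-magnitude loading positive per component
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    adata.obsm["X_pca"] = pcs
    return pcs
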