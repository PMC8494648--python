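"""Stringent cell filtering: doublet scoring, gene-count and mitochondrial
thresholds.

Doublet scoring is a simplified simulated-doublet kNN scheme, applied one
capture lane (individual) at a time: synthetic doublets are sums of random
observed cell pairs; observed and simulated cells are embedded in one PC
space; a cell's score is the fraction of its nearest neighbors that are
simulated.  Filtering then keeps cells with at least ``min_genes_per_cell``
detected genes and at most ``max_mito_fraction`` mitochondrial counts
(boundary cells at exactly 750 genes or exactly 10% mito are kept: the
removal rules are <750 and >10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from sklearn.neighbors import NearestNeighbors

from . import preprocess


@dataclass
class QCConfig:
    min_genes_per_cell: int = 750
    max_mito_fraction: float = 0.10
    doublet_score_threshold: float = 0.25
    n_simulated_doublets: int | None = None  # None -> one per observed cell
    knn_k: int = 15
    n_pcs: int = 30
    n_hvg: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 1:
            raise ValueError("min_genes_per_cell must be >= 1")
        if not (0 < self.max_mito_fraction < 1):
            raise ValueError("max_mito_fraction must lie in (0,1)")
        if not (0 <= self.doublet_score_threshold <= 1):
            raise ValueError("doublet_score_threshold must lie in [0,1]")


@dataclass
class QCReport:
    """Per-cell QC metrics and pass/fail bookkeeping."""

    per_cell: pd.DataFrame  # genes_detected, mito_fraction, doublet_score, pass, reasons
    summary: dict[str, int] = field(default_factory=dict)


def doublet_score(adata: AnnData, config: QCConfig) -> np.ndarray:
    """Simulated-doublet kNN score in [0,1] for one capture lane."""
    n = adata.n_obs
    if n == 0:
        raise ValueError("empty matrix")
    if n < config.knn_k + 1:
        raise ValueError(f"need at least knn_k+1={config.knn_k + 1} cells, got {n}")
    n_sim = config.n_simulated_doublets if config.n_simulated_doublets is not None else n
    if n_sim < 1:
        raise ValueError("n_simulated_doublets must be >= 1")
    rng = np.random.default_rng(config.seed)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    p1 = rng.integers(0, n, size=n_sim)
    p2 = (p1 + rng.integers(1, n, size=n_sim)) % n
    sim = X[p1] + X[p2]
    combined = AnnData(X=sp.vstack([X, sim], format="csr"))
    preprocess.lognorm(combined)
    pcs = preprocess.pca_embed(combined, n_hvg=config.n_hvg, n_pcs=config.n_pcs)
    nn = NearestNeighbors(n_neighbors=config.knn_k + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs[:n])
    scores = np.empty(n)
    for i in range(n):
        row = idx[i][idx[i] != i][: config.knn_k]  # self excluded
        scores[i] = (row >= n).mean()
    return scores


def filter_cells(adata: AnnData, config: QCConfig) -> tuple[AnnData, QCReport]:
    """Apply the lane-wise doublet filter then the gene/mito thresholds.

    Requires ``var['mito']`` and (for lane-wise scoring) ``obs['individual']``;
    with a single lane the whole matrix is one lane.  Raises if nothing
    survives, rather than returning a silently empty matrix.
    """
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_mask = adata.var["mito"].to_numpy().astype(bool)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_fraction = np.where(total > 0, mito_counts / np.maximum(total, 1.0), 0.0)

    scores = np.zeros(adata.n_obs)
    lanes = (
        adata.obs["individual"].astype(str)
        if "individual" in adata.obs
        else pd.Series("lane0", index=adata.obs_names)
    )
    for lane in lanes.unique():
        sel = (lanes == lane).to_numpy()
        scores[sel] = doublet_score(adata[sel], config)

    fail_doublet = scores >= config.doublet_score_threshold
    fail_genes = genes_detected < config.min_genes_per_cell
    fail_mito = mito_fraction > config.max_mito_fraction
    ok = ~(fail_doublet | fail_genes | fail_mito)

    reasons = []
    for d, g, m in zip(fail_doublet, fail_genes, fail_mito):
        r = []
        if d:
            r.append("doublet")
        if g:
            r.append("low_genes")
        if m:
            r.append("high_mito")
        reasons.append(",".join(r))
    per_cell = pd.DataFrame(
        {
            "genes_detected": genes_detected,
            "mito_fraction": mito_fraction,
            "doublet_score": scores,
            "pass": ok,
            "reasons": reasons,
        },
        index=adata.obs_names,
    )
    summary = {
        "n_input": int(adata.n_obs),
        "n_retained": int(ok.sum()),
        "fail_doublet": int(fail_doublet.sum()),
        "fail_low_genes": int(fail_genes.sum()),
        "fail_high_mito": int(fail_mito.sum()),
    }
    if not ok.any():
        raise ValueError("empty after QC: every cell failed at least one filter")
    return adata[ok].copy(), QCReport(per_cell=per_cell, summary=summary)
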