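"""Shared fixtures: small constructed matrices and the default-conditions
atlas pipeline (session-scoped; the expensive end-to-end run is computed once
and reused by every test that needs it)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from arealize import qc as qcmod
from arealize.pipeline import run_atlas_pipeline
from arealize.synthdata import AtlasConfig


def make_adata(counts: np.ndarray, mito_flags=None, obs: pd.DataFrame | None = None) -> AnnData:
    """Dense integer counts (cells x genes) -> AnnData with mito flags."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    gene_names = [f"g{j}" for j in range(n_genes)]
    var = pd.DataFrame(
        {"mito": np.zeros(n_genes, bool) if mito_flags is None else np.asarray(mito_flags, bool)},
        index=gene_names,
    )
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    return AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture(scope="session")
def default_pipeline():
    """The default synthetic atlas (3 individuals x 3,000 cells x 2,000 genes,
    fold change 4) run through QC, recursive clustering and merging."""
    return run_atlas_pipeline(AtlasConfig(seed=1))


def build_qc_boundary_fixture(seed: int = 7):
    """100-cell matrix with 10 planted violations per QC filter, disjoint.

    Two well-separated noiseless-ish cell types A and B; 70 clean cells
    (including one boundary cell at exactly 750 detected genes and exactly
    10% mitochondrial counts), 10 cells detecting exactly 749 genes, 10 cells
    with >10% mito, and 10 true A+B doublets.  Returns (adata, QCConfig,
    expected reason per cell).
    """
    rng = np.random.default_rng(seed)
    n_genes = 1200
    mito = np.zeros(n_genes, bool)
    mito[-10:] = True
    base_a = np.zeros(n_genes, int)
    base_a[:800] = 2  # type A detects genes 0..799
    base_b = np.zeros(n_genes, int)
    base_b[300:1100] = 2  # type B detects genes 300..1099

    def jitter(profile):
        out = profile.copy()
        detected = np.flatnonzero(profile)
        bump = rng.choice(detected, size=20, replace=False)
        out[bump] += 1
        return out

    cells, reasons = [], []
    # boundary cell: exactly 750 detected genes and exactly 10% mito counts
    # (740 non-mito genes totalling 1800 counts + 10 mito genes totalling
    # 200 counts -> 200/2000 = 0.10)
    boundary = np.zeros(n_genes, int)
    boundary[:740] = 2
    boundary[:320] += 1
    boundary[-10:] = 20
    cells.append(boundary)
    reasons.append("")
    for i in range(34):
        cells.append(jitter(base_a))
        reasons.append("")
    for i in range(35):
        cells.append(jitter(base_b))
        reasons.append("")
    for i in range(10):  # exactly 749 detected genes
        low = np.zeros(n_genes, int)
        low[:749] = 2
        bump = rng.choice(749, size=20, replace=False)
        low[bump] += 1
        cells.append(low)
        reasons.append("low_genes")
    for i in range(10):  # mito fraction > 0.10
        hi = jitter(base_b)
        hi[-10:] = 40  # 400 mito counts vs ~1640 total non-mito
        cells.append(hi)
        reasons.append("high_mito")
    for i in range(10):  # true heterotypic doublets
        cells.append(jitter(base_a) + jitter(base_b))
        reasons.append("doublet")
    counts = np.vstack(cells)
    adata = make_adata(counts, mito_flags=mito)
    config = qcmod.QCConfig(
        min_genes_per_cell=750,
        max_mito_fraction=0.10,
        doublet_score_threshold=0.6,
        knn_k=15,
        n_pcs=10,
        seed=0,
    )
    return adata, config, reasons
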