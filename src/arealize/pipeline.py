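"""End-to-end driver tying the stages together on one atlas.

Used by the analysis scripts, the acceptance tests and the acceptance
script so that every consumer runs the identical computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from . import cluster as cl
from . import constellation as cn
from . import markers as mk
from . import qc as qcmod
from . import preprocess
from .synthdata import AtlasConfig, AtlasTruth, generate_atlas


def truth_marker_panel(truth: AtlasTruth) -> dict[str, list[str]]:
    """Canonical marker panel from the planted cell-type markers."""
    g = truth.genes
    panel: dict[str, list[str]] = {}
    for t in sorted(g.loc[g["role"] == "celltype_marker", "owner_type"].unique()):
        panel[t] = list(g.index[(g["role"] == "celltype_marker") & (g["owner_type"] == t)])
    return panel


@dataclass
class AtlasPipelineResult:
    adata: AnnData
    truth: AtlasTruth
    qc_report: qcmod.QCReport
    cluster_table: pd.DataFrame  # levels 1-3 per QC-passing cell
    level3: pd.Series
    profiles: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_atlas_pipeline(
    config: AtlasConfig | None = None,
    qc_config: qcmod.QCConfig | None = None,
    params: cl.ClusterParams | None = None,
) -> AtlasPipelineResult:
    """Simulate -> QC -> recursive clustering -> merge, returning all stages."""
    config = config or AtlasConfig()
    qc_config = qc_config or qcmod.QCConfig(seed=config.seed)
    params = params or cl.ClusterParams(seed=config.seed)
    raw, truth = generate_atlas(config)
    filtered, report = qcmod.filter_cells(raw, qc_config)
    panel = truth_marker_panel(truth)
    table = cl.recursive_cluster(filtered, panel, params)
    level3, record = cl.correlate_and_merge(filtered, table, params.merge_threshold)
    table = table.copy()
    table["level3"] = level3
    profiles = cl.gene_score_profiles(filtered, level3)
    return AtlasPipelineResult(
        adata=filtered,
        truth=truth,
        qc_report=report,
        cluster_table=table,
        level3=level3,
        profiles=profiles,
        extras={"merge_record": record},
    )


def constellation_by_group(
    adata: AnnData,
    labels,
    config: cn.ConstellationConfig | None = None,
    embedding: np.ndarray | None = None,
) -> cn.ConstellationGraph:
    """Neighbor fractions in PC space + constellation graph; the 2-D node
    layout defaults to the first two PCs when no embedding is supplied."""
    config = config or cn.ConstellationConfig()
    if "X_pca" not in adata.obsm:
        preprocess.pca_embed(adata, n_pcs=config.n_pcs)
    pcs = adata.obsm["X_pca"][:, : config.n_pcs]
    emb = embedding if embedding is not None else pcs[:, :2]
    fractions, _ = cn.neighbor_fractions(pcs, labels, config.knn_k, mode=config.fraction_mode)
    return cn.build_constellation(fractions, emb, labels, config)
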