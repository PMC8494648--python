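"""Signature-overlap quantification across cell types, areas and stages:
row-normalized overlap matrices, hierarchical clustering of signature nodes,
and Sankey link tables between consecutive stages."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .markers import STAGE_ORDER

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureNode:
    """A marker gene set identified by cell type x area x stage."""

    id: str
    genes: frozenset[str]
    cell_type: str = ""
    area: str = ""
    stage: str = ""


def signature_overlap(nodes: list[SignatureNode], symmetric: bool = False) -> pd.DataFrame:
    """Overlap matrix: entry (i, j) = |genes_i n genes_j| / |genes_i|
    (row-normalized, asymmetric); with ``symmetric=True``, Jaccard instead."""
    if len(nodes) < 2:
        raise ValueError("need at least 2 signature nodes")
    ids = [n.id for n in nodes]
    if len(set(ids)) != len(ids):
        raise ValueError("signature node ids must be unique")
    for n in nodes:
        if not n.genes:
            raise ValueError(f"signature node {n.id} has an empty gene set")
    M = pd.DataFrame(0.0, index=ids, columns=ids)
    for a in nodes:
        for b in nodes:
            inter = len(a.genes & b.genes)
            denom = len(a.genes | b.genes) if symmetric else len(a.genes)
            M.loc[a.id, b.id] = inter / denom
    return M


def overlap_hierarchy(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over nodes at Euclidean distance between their
    shared-proportion row vectors; rows sorted by id for deterministic ties."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 nodes")
    matrix = matrix.reindex(sorted(matrix.index))[sorted(matrix.index)]
    Z = linkage(pdist(matrix.to_numpy(dtype=float), metric="euclidean"), method="average")
    return Z, [str(i) for i in matrix.index]


def sankey_links(nodes: list[SignatureNode]) -> pd.DataFrame:
    """Shared-gene link table between nodes of consecutive stages.

    Links run early->middle and middle->late only; weight is the size of the
    gene-set intersection and zero-weight links are omitted.
    """
    stages_present = [s for s in STAGE_ORDER if any(n.stage == s for n in nodes)]
    if len(stages_present) < 2:
        log.warning("sankey_links: fewer than 2 stages present; empty link table")
        return pd.DataFrame(columns=["source", "target", "shared_genes"])
    rows = []
    for s_from, s_to in zip(stages_present, stages_present[1:]):
        for a in nodes:
            if a.stage != s_from:
                continue
            for b in nodes:
                if b.stage != s_to:
                    continue
                w = len(a.genes & b.genes)
                if w > 0:
                    rows.append({"source": a.id, "target": b.id, "shared_genes": w})
    return pd.DataFrame(rows, columns=["source", "target", "shared_genes"])


def nodes_from_marker_table(table: pd.DataFrame) -> list[SignatureNode]:
    """Build signature nodes from a combined marker table with columns
    cell_type, area, stage, gene (significant up-regulated markers)."""
    out = []
    for (t, a, s), grp in table.groupby(["cell_type", "area", "stage"]):
        genes = frozenset(grp["gene"].astype(str))
        if genes:
            out.append(
                SignatureNode(id=f"{t}|{a}|{s}", genes=genes, cell_type=t, area=a, stage=s)
            )
    return out
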