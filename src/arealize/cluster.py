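"""Recursive clustering: per-individual Louvain–Jaccard, within-cell-type
subclustering, and iterative cross-individual merging by Pearson correlation
of gene-score profiles; plus one-minus-correlation cluster dendrograms.

The batch-bridging step is deliberately not an embedding correction: clusters
from different individuals are compared only through their marker gene-score
profiles, and merged by single-linkage grouping of pairs whose profiles
correlate at or above ``merge_threshold`` — once within each cell type, and
once more across everything after recomputing profiles from pooled cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from . import markers, preprocess

log = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Directed kNN lists plus the undirected Jaccard-weighted graph."""

    neighbors: np.ndarray  # (n_cells, k) neighbor indices
    weights: sp.csr_matrix  # symmetric Jaccard weights, zero diagonal

    @property
    def n_cells(self) -> int:
        return self.neighbors.shape[0]


def exact_knn(coords: np.ndarray, k: int, chunk: int = 512) -> np.ndarray:
    """Exact k nearest neighbors (self excluded), ties at equal distance
    broken by lower cell index.  Deterministic by construction."""
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    out = np.empty((n, k), dtype=np.int64)
    sq = np.einsum("ij,ij->i", coords, coords)
    idx_all = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = sq[start:stop, None] + sq[None, :] - 2.0 * coords[start:stop] @ coords.T
        for r in range(stop - start):
            i = start + r
            row = d[r].copy()
            row[i] = np.inf  # exclude self
            order = np.lexsort((idx_all, row))
            out[i] = order[:k]
    return out


def build_knn_jaccard_graph(pc_coords: np.ndarray, k: int) -> NeighborGraph:
    """Jaccard-of-neighborhoods graph over exact kNN lists.

    For every cell pair whose k-neighbor sets intersect, the edge weight is
    |N(i) n N(j)| / |N(i) u N(j)| (self excluded from both sets).
    """
    coords = np.asarray(pc_coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("PC matrix must be finite")
    n = coords.shape[0]
    neigh = exact_knn(coords, k)
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix(
        (np.ones(n * k, dtype=np.int32), (rows, neigh.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()
    mask = inter.row != inter.col
    r, c, i_cnt = inter.row[mask], inter.col[mask], inter.data[mask]
    union = 2 * k - i_cnt
    w = i_cnt / union
    W = sp.csr_matrix((w, (r, c)), shape=(n, n))
    return NeighborGraph(neighbors=neigh, weights=W)


def louvain_cluster(graph, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Louvain community detection on the Jaccard-weighted graph.

    Accepts a :class:`NeighborGraph` or a symmetric scipy sparse weight
    matrix.  Labels are contiguous integers, deterministically ordered by
    each community's smallest member index; deterministic for a fixed seed.
    """
    W = graph.weights if isinstance(graph, NeighborGraph) else sp.csr_matrix(graph)
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty graph")
    G = nx.Graph()
    G.add_nodes_from(range(n))
    coo = sp.triu(W, k=1).tocoo()
    G.add_weighted_edges_from(zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist()))
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = np.empty(n, dtype=np.int64)
    for lab, members in enumerate(comms):
        labels[members] = lab
    return labels


@dataclass
class ClusterParams:
    resolution: float = 1.0
    knn_k: int = 15
    n_pcs: int = 50
    n_hvg: int = 2000
    min_cells: int = 50  # cell types below this skip subclustering
    merge_threshold: float = 0.7
    seed: int = 0


def annotate_clusters(
    adata: AnnData, labels: np.ndarray, marker_panel: dict[str, list[str]]
) -> dict[int, str]:
    """Assign each cluster the cell type whose canonical panel genes have the
    highest mean z-scored (across clusters) mean expression — a marker-based
    vote over the cluster's expression profile."""
    if "lognorm" not in adata.layers:
        preprocess.lognorm(adata)
    L = adata.layers["lognorm"]
    L = L.toarray() if sp.issparse(L) else np.asarray(L)
    uniq = np.unique(labels)
    cluster_means = np.vstack([L[labels == c].mean(axis=0) for c in uniq])
    sd = cluster_means.std(axis=0)
    sd[sd == 0] = 1.0
    z = (cluster_means - cluster_means.mean(axis=0)) / sd
    gpos = {g: j for j, g in enumerate(adata.var_names)}
    out: dict[int, str] = {}
    for row, c in enumerate(uniq):
        best_t, best_v = None, -np.inf
        for t in sorted(marker_panel):
            cols = [gpos[g] for g in marker_panel[t] if g in gpos]
            if not cols:
                continue
            v = z[row, cols].mean()
            if v > best_v:
                best_t, best_v = t, v
        out[int(c)] = best_t if best_t is not None else "unknown"
    return out


def _cluster_subset(sub: AnnData, params: ClusterParams, seed: int) -> np.ndarray:
    pcs = preprocess.pca_embed(sub, n_hvg=params.n_hvg, n_pcs=params.n_pcs)
    k = min(params.knn_k, sub.n_obs - 1)
    graph = build_knn_jaccard_graph(pcs, k)
    return louvain_cluster(graph, resolution=params.resolution, seed=seed)


def recursive_cluster(
    adata: AnnData,
    marker_panel: dict[str, list[str]],
    params: ClusterParams | None = None,
) -> pd.DataFrame:
    """Levels 1–2 of the recursive workflow.

    Level 1: Louvain–Jaccard per individual, annotated to cell types by the
    marker panel.  Level 2: cells of each (individual, cell type) re-embedded
    and re-clustered; cell types with fewer than ``min_cells`` cells keep
    their level-1 label.  Returns a per-cell table with columns
    individual, level1, cell_type, level2.
    """
    params = params or ClusterParams()
    obs = adata.obs
    table = pd.DataFrame(
        index=adata.obs_names,
        columns=["individual", "level1", "cell_type", "level2"],
        dtype=object,
    )
    table["individual"] = obs["individual"].astype(str).to_numpy()
    for ind in sorted(obs["individual"].astype(str).unique()):
        sel = (obs["individual"].astype(str) == ind).to_numpy()
        sub = adata[sel].copy()
        lab1 = _cluster_subset(sub, params, params.seed)
        ann = annotate_clusters(sub, lab1, marker_panel)
        names = np.asarray(sub.obs_names)
        table.loc[names, "level1"] = [f"{ind}.L1-{c}" for c in lab1]
        ctypes = np.array([ann[int(c)] for c in lab1], dtype=object)
        table.loc[names, "cell_type"] = ctypes
        for t in sorted(set(ctypes)):
            tmask = ctypes == t
            tnames = names[tmask]
            if tmask.sum() < params.min_cells:
                table.loc[tnames, "level2"] = table.loc[tnames, "level1"]
                continue
            sub2 = sub[tmask].copy()
            lab2 = _cluster_subset(sub2, params, params.seed)
            table.loc[tnames, "level2"] = [f"{ind}.{t}.{c}" for c in lab2]
    return table


def gene_score_profiles(
    adata: AnnData, labels: pd.Series | np.ndarray, min_cells: int = 3
) -> pd.DataFrame:
    """Clusters x union-of-marker-genes matrix of gene scores.

    Each cluster is tested against the complement within ``adata``; a gene's
    entry is its gene score where it is a significant up-regulated marker of
    that cluster and 0 elsewhere.
    """
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    per_cluster: dict[str, pd.Series] = {}
    for c in sorted(labels.unique()):
        n_in = int((labels == c).sum())
        if n_in < min_cells or n_in == adata.n_obs:
            per_cluster[c] = pd.Series(dtype=float)
            continue
        de = markers.wilcoxon_de(adata, labels, c)
        sig = de[(de["significant"]) & (de["avg_logFC"] > 0)]
        per_cluster[c] = pd.Series(sig["gene_score"].to_numpy(), index=sig["gene"])
    union = sorted(set().union(*[set(s.index) for s in per_cluster.values()]))
    prof = pd.DataFrame(0.0, index=sorted(per_cluster), columns=union)
    for c, s in per_cluster.items():
        prof.loc[c, s.index] = s.to_numpy()
    return prof


def merge_by_correlation(
    profiles: pd.DataFrame,
    merge_threshold: float,
    groups: pd.Series | None = None,
) -> dict[str, str]:
    """Single-linkage grouping of clusters whose profiles correlate at
    r >= merge_threshold (optionally restricted to pairs sharing ``groups``).

    Zero-variance profiles are unmergeable and logged.  Returns a map
    cluster -> merged label (the lexicographically smallest member).
    """
    if not (0 < merge_threshold < 1):
        raise ValueError("merge_threshold must lie in (0,1)")
    names = list(profiles.index)
    M = profiles.to_numpy(dtype=float)
    sd = M.std(axis=1)
    degenerate = sd == 0
    for nm in np.asarray(names)[degenerate]:
        log.warning("cluster %s has a zero-variance profile; treated as unmergeable", nm)
    parent = {nm: nm for nm in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    with np.errstate(invalid="ignore"):
        C = np.corrcoef(M)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if degenerate[i] or degenerate[j]:
                continue
            if groups is not None and groups[names[i]] != groups[names[j]]:
                continue
            if C[i, j] >= merge_threshold:
                union(names[i], names[j])
    return {nm: find(nm) for nm in names}


def correlate_and_merge(
    adata: AnnData,
    cluster_table: pd.DataFrame,
    merge_threshold: float = 0.7,
) -> tuple[pd.Series, dict]:
    """Two-round cross-individual merging producing level-3 labels.

    Round 1 merges level-2 clusters of the same cell type across individuals,
    using per-individual gene-score profiles.  Profiles of the merged
    clusters are then recomputed from the pooled cells (cluster vs the rest
    of the whole matrix) and round 2 merges across all clusters and cell
    types.  Returns the per-cell level-3 labels and a record of both rounds.
    """
    obs_names = np.asarray(adata.obs_names)
    level2 = pd.Series(cluster_table["level2"].astype(str).to_numpy(), index=obs_names)
    ctype_of_cluster = (
        cluster_table.assign(level2=level2.to_numpy())
        .groupby("level2")["cell_type"]
        .agg(lambda s: s.iloc[0])
    )
    # per-individual profiles, concatenated (cluster labels are unique per
    # individual so rows never collide)
    profs = []
    for ind in sorted(cluster_table["individual"].astype(str).unique()):
        sel = (cluster_table["individual"].astype(str) == ind).to_numpy()
        sub = adata[sel].copy()
        profs.append(gene_score_profiles(sub, level2[sel]))
    profiles1 = pd.concat(profs).fillna(0.0)
    profiles1 = profiles1.reindex(sorted(profiles1.index)).fillna(0.0)
    map1 = merge_by_correlation(
        profiles1, merge_threshold, groups=ctype_of_cluster
    )
    merged1 = level2.map(map1)

    profiles2 = gene_score_profiles(adata, merged1)
    map2 = merge_by_correlation(profiles2, merge_threshold, groups=None)
    level3 = merged1.map(map2)
    record = {"round1": map1, "round2": map2}
    return level3, record


def cluster_dendrogram(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage tree over clusters at distance 1 - Pearson r.

    Rows are sorted by label first so that tie-breaking is deterministic.
    Raises on constant rows, naming the offending cluster.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 clusters")
    profiles = profiles.reindex(sorted(profiles.index))
    M = profiles.to_numpy(dtype=float)
    sd = M.std(axis=1)
    if np.any(sd == 0):
        bad = [str(n) for n, s in zip(profiles.index, sd) if s == 0]
        raise ValueError(f"constant gene-score profile for cluster(s): {', '.join(bad)}")
    D = 1.0 - np.corrcoef(M)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, [str(n) for n in profiles.index]
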