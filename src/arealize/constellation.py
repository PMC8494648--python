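"""Constellation graphs over cell groupings and the connectivity index.

A constellation summarizes how cell groups mix in kNN space: each group is a
node at its embedding centroid, and a directed fraction f(A->B) records how
much of A's neighborhoods point into B.  An undirected edge is drawn when
f exceeds the threshold in at least one direction (strictly: > threshold).
The connectivity index between two node collections is the number of edges
between them times the mean of the threshold-passing endpoint fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import exact_knn


@dataclass
class ConstellationConfig:
    knn_k: int = 15
    n_pcs: int = 50
    edge_threshold: float = 0.05
    fraction_mode: str = "slots"  # "slots" (pooled neighbor slots) or "cells"

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if not (0 < self.edge_threshold < 1):
            raise ValueError("edge_threshold must lie in (0,1)")
        if self.fraction_mode not in ("slots", "cells"):
            raise ValueError("fraction_mode must be 'slots' or 'cells'")


@dataclass
class ConstellationGraph:
    nodes: pd.DataFrame  # index=group, columns: centroid_x, centroid_y, size, flagged
    fractions: pd.DataFrame  # directed fraction table, groups x groups
    edges: pd.DataFrame  # a, b, f_ab, f_ba, width_a, width_b
    normalization: float
    threshold: float


def neighbor_fractions(
    pc_coords: np.ndarray,
    labels,
    knn_k: int = 15,
    mode: str = "slots",
) -> tuple[pd.DataFrame, pd.Series]:
    """Directed neighbor-fraction table over the exact kNN graph.

    ``slots`` mode (default): f(A->B) is the fraction of all k-neighbor slots
    of A's cells occupied by B's cells.  ``cells`` mode: the fraction of A's
    cells with at least one neighbor in B.  Self-neighbors are excluded by
    the kNN construction.  Groups smaller than 2 cells are computed but
    flagged.
    """
    labels = np.asarray(labels).astype(str)
    coords = np.asarray(pc_coords, dtype=float)
    n = coords.shape[0]
    if n < knn_k + 1:
        raise ValueError("need at least knn_k+1 cells")
    if len(labels) != n:
        raise ValueError("labels must cover every cell")
    neigh = exact_knn(coords, knn_k)
    uniq = sorted(set(labels))
    lab_idx = {g: i for i, g in enumerate(uniq)}
    li = np.array([lab_idx[g] for g in labels])
    ni = li[neigh]  # (n, k) neighbor group ids
    F = np.zeros((len(uniq), len(uniq)))
    for a_id in range(len(uniq)):
        rows = ni[li == a_id]
        if rows.size == 0:
            continue
        if mode == "slots":
            counts = np.bincount(rows.ravel(), minlength=len(uniq))
            F[a_id] = counts / rows.size
        elif mode == "cells":
            for b_id in range(len(uniq)):
                F[a_id, b_id] = (rows == b_id).any(axis=1).mean()
        else:
            raise ValueError(f"unknown mode {mode!r}")
    fractions = pd.DataFrame(F, index=uniq, columns=uniq)
    sizes = pd.Series(labels).value_counts()
    flagged = pd.Series({g: bool(sizes[g] < 2) for g in uniq})
    return fractions, flagged


def build_constellation(
    fractions: pd.DataFrame,
    embedding: np.ndarray,
    labels,
    config: ConstellationConfig | None = None,
) -> ConstellationGraph:
    """Assemble the constellation graph from a directed fraction table.

    Edge rule is strict: f(A->B) > threshold in at least one direction.
    End widths are each direction's fraction divided by the maximum
    off-diagonal fraction across all ordered group pairs (the largest
    observed mixing renders at width 1).
    """
    config = config or ConstellationConfig()
    labels = np.asarray(labels).astype(str)
    uniq = sorted(set(labels))
    if sorted(fractions.index) != uniq or sorted(fractions.columns) != uniq:
        raise ValueError("fraction table and labels disagree on the group set")
    emb = np.asarray(embedding, dtype=float)
    nodes = pd.DataFrame(index=uniq, columns=["centroid_x", "centroid_y", "size"], dtype=float)
    for g in uniq:
        sel = labels == g
        nodes.loc[g, "centroid_x"] = emb[sel, 0].mean()
        nodes.loc[g, "centroid_y"] = emb[sel, 1].mean()
        nodes.loc[g, "size"] = int(sel.sum())
    off = fractions.to_numpy(dtype=float).copy()
    np.fill_diagonal(off, 0.0)
    norm = float(off.max()) if off.size else 0.0
    rows = []
    for i, a in enumerate(uniq):
        for j, b in enumerate(uniq):
            if j <= i:
                continue
            f_ab = float(fractions.loc[a, b])
            f_ba = float(fractions.loc[b, a])
            if f_ab > config.edge_threshold or f_ba > config.edge_threshold:
                rows.append(
                    {
                        "a": a,
                        "b": b,
                        "f_ab": f_ab,
                        "f_ba": f_ba,
                        "width_a": f_ab / norm if norm > 0 else 0.0,
                        "width_b": f_ba / norm if norm > 0 else 0.0,
                    }
                )
    edges = pd.DataFrame(rows, columns=["a", "b", "f_ab", "f_ba", "width_a", "width_b"])
    return ConstellationGraph(
        nodes=nodes,
        fractions=fractions,
        edges=edges,
        normalization=norm,
        threshold=config.edge_threshold,
    )


def connectivity_index(
    graph: ConstellationGraph, collection_a, collection_b
) -> float:
    """Edges between the two node collections times the mean of the
    threshold-passing endpoint fractions on those edges; 0 with no edges."""
    A = {str(x) for x in collection_a}
    B = {str(x) for x in collection_b}
    known = set(graph.nodes.index)
    unknown = (A | B) - known
    if unknown:
        raise ValueError(f"unknown node(s) in collection: {sorted(unknown)}")
    passing: list[float] = []
    n_edges = 0
    for _, e in graph.edges.iterrows():
        a, b = e["a"], e["b"]
        if (a in A and b in B) or (a in B and b in A):
            n_edges += 1
            for f in (e["f_ab"], e["f_ba"]):
                if f > graph.threshold:
                    passing.append(f)
    if n_edges == 0:
        return 0.0
    return n_edges * float(np.mean(passing))


def connectivity_index_matrix(
    graph: ConstellationGraph, collections: dict[str, list[str]]
) -> pd.DataFrame:
    """Symmetric connectivity-index matrix over named node collections."""
    names = sorted(collections)
    M = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            v = connectivity_index(graph, collections[a], collections[b])
            M.loc[a, b] = M.loc[b, a] = v
    return M
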