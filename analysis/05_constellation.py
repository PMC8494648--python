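#!/usr/bin/env python
"""Constellation graphs over the clustered atlas: neighbor fractions in PC
space, the strict >5% edge rule, and connectivity indices between cell-type
node collections — including the cell-type x area grouping that exposes the
PFC/V1 pole structure."""

import argparse
import json

import pandas as pd

from arealize import constellation as cn
from arealize import io, preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--k", type=int, default=15)
    ap.add_argument("--pcs", type=int, default=50)
    ap.add_argument("--threshold", type=float, default=0.05)
    ap.add_argument("--data", default="results/data")
    args = ap.parse_args()

    adata = io.read_atlas(f"{args.data}/atlas_qc")
    clusters = pd.read_csv(f"{args.data}/clusters.tsv", sep="\t", index_col=0)
    config = cn.ConstellationConfig(knn_k=args.k, n_pcs=args.pcs,
                                    edge_threshold=args.threshold)
    pcs = preprocess.pca_embed(adata, n_pcs=args.pcs)

    # cell-type constellation
    labels = clusters.loc[adata.obs_names, "cell_type"].to_numpy()
    fractions, _ = cn.neighbor_fractions(pcs, labels, args.k)
    graph = cn.build_constellation(fractions, pcs[:, :2], labels, config)
    fractions.to_csv(f"{args.data}/constellation_fractions.tsv", sep="\t")
    graph.edges.to_csv(f"{args.data}/constellation_edges.tsv", sep="\t", index=False)
    nodes = graph.nodes.reset_index(names="group")
    with open(f"{args.data}/constellation.json", "w") as fh:
        json.dump({"nodes": nodes.to_dict("records"),
                   "edges": graph.edges.to_dict("records"),
                   "normalization": graph.normalization}, fh, indent=1)
    print(f"cell-type constellation: {len(graph.nodes)} nodes, {len(graph.edges)} edges")

    # excitatory lineage by (cell type, area): connectivity between types
    lineage = clusters["cell_type"].isin(["RG", "IPC", "neuron"]).to_numpy()
    sub = adata[lineage].copy()
    sub_pcs = preprocess.pca_embed(sub, n_pcs=args.pcs)
    ta = (clusters.loc[sub.obs_names, "cell_type"].astype(str) + "|"
          + sub.obs["area"].astype(str)).to_numpy()
    fr2, _ = cn.neighbor_fractions(sub_pcs, ta, args.k)
    g2 = cn.build_constellation(fr2, sub_pcs[:, :2], ta, config)
    groups = sorted(set(ta))
    collections = {t: [g for g in groups if g.startswith(t + "|")]
                   for t in ("RG", "IPC", "neuron")}
    M = cn.connectivity_index_matrix(g2, collections)
    M.to_csv(f"{args.data}/connectivity_index.tsv", sep="\t")
    print("connectivity index between cell-type collections:")
    print(M.round(3).to_string())


if __name__ == "__main__":
    main()
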