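#!/usr/bin/env python
"""Recursive clustering of the QC-passed atlas: per-individual
Louvain–Jaccard, within-type subclustering, then two rounds of
gene-score-correlation merging across individuals.  Writes clusters.tsv
(all three levels), the merged gene-score profiles, and the cluster
dendrogram as Newick."""

import argparse

import pandas as pd

from arealize import cluster as cl
from arealize import io


def truth_panel_from_genes(genes: pd.DataFrame) -> dict[str, list[str]]:
    mk = genes[genes["truth_role"] == "celltype_marker"]
    return {t: list(mk.index[mk["truth_owner_type"] == t])
            for t in sorted(mk["truth_owner_type"].unique())}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--resolution", type=float, default=1.0)
    ap.add_argument("--merge-threshold", type=float, default=0.7)
    ap.add_argument("--data", default="results/data")
    args = ap.parse_args()

    adata = io.read_atlas(f"{args.data}/atlas_qc")
    genes = pd.read_csv(f"{args.data}/atlas/genes.tsv", sep="\t", index_col=0)
    panel = truth_panel_from_genes(genes)
    params = cl.ClusterParams(resolution=args.resolution,
                              merge_threshold=args.merge_threshold, seed=args.seed)
    table = cl.recursive_cluster(adata, panel, params)
    level3, record = cl.correlate_and_merge(adata, table, args.merge_threshold)
    table["level3"] = level3
    table.to_csv(f"{args.data}/clusters.tsv", sep="\t")
    profiles = cl.gene_score_profiles(adata, level3)
    profiles.to_csv(f"{args.data}/profiles.tsv", sep="\t")
    with_markers = profiles[profiles.std(axis=1) > 0]
    if len(with_markers) < len(profiles):
        print(f"note: {len(profiles) - len(with_markers)} cluster(s) without "
              "significant markers left out of the dendrogram")
    if len(with_markers) >= 2:
        Z, labels = cl.cluster_dendrogram(with_markers)
        with open(f"{args.data}/dendrogram.nwk", "w") as fh:
            fh.write(io.linkage_to_newick(Z, labels) + "\n")
    print(f"{table['level1'].nunique()} level-1 clusters -> "
          f"{table['level2'].nunique()} subclusters -> "
          f"{level3.nunique()} merged clusters")
    print("merged cluster sizes:")
    print(level3.value_counts().to_string())


if __name__ == "__main__":
    main()
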