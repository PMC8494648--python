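#!/usr/bin/env python
"""Marker statistics on the merged clusters: rank-sum differential
expression with gene scores, area markers per cell type combined across
individuals with stage annotation, transcription-factor annotation, and the
dot-plot z-score table for the top areal markers."""

import argparse
import json

import pandas as pd

from arealize import io
from arealize import markers as mk


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--tf-list", default=None,
                    help="one-symbol-per-line TF list; defaults to the planted TF stand-in")
    args = ap.parse_args()

    adata = io.read_atlas(f"{args.data}/atlas_qc")
    clusters = pd.read_csv(f"{args.data}/clusters.tsv", sep="\t", index_col=0)
    level3 = clusters.loc[adata.obs_names, "level3"]

    frames = [mk.wilcoxon_de(adata, level3, c, cluster_name=c) for c in sorted(level3.unique())]
    table = pd.concat(frames, ignore_index=True)
    table = table[table["significant"] & (table["avg_logFC"] > 0)]
    table.to_csv(f"{args.data}/markers.tsv", sep="\t", index=False)
    print(f"{len(table)} significant up-regulated marker records over "
          f"{level3.nunique()} merged clusters")

    adata.obs["cell_type"] = clusters.loc[adata.obs_names, "cell_type"].to_numpy()
    area_table = mk.area_markers_by_stage(adata, "cell_type",
                                          cell_types=["RG", "IPC", "neuron"])
    area_table.to_csv(f"{args.data}/area_markers.tsv", sep="\t", index=False)
    per_type = area_table.groupby("cell_type")["gene"].nunique()
    print("areal marker genes per cell type (the excitatory-lineage cascade):")
    print(per_type.to_string())

    if args.tf_list:
        tfs = mk.read_tf_list(args.tf_list)
    else:
        # stand-in TF list for the synthetic gene universe: the planted
        # area markers of RG (synthetic; real runs pass an AnimalTFDB file)
        genes = pd.read_csv(f"{args.data}/atlas/genes.tsv", sep="\t", index_col=0)
        tfs = set(genes.index[(genes["truth_role"] == "area_marker")
                              & (genes["truth_owner_type"] == "RG")])
    tf_marks = mk.annotate_tfs(area_table, tfs)
    tf_marks.to_csv(f"{args.data}/area_markers_tf.tsv", sep="\t", index=False)
    print(f"{tf_marks['gene'].nunique()} areal markers annotated as transcription factors")

    sigs = {
        f"{t}|{a}|{s}": sorted(grp["gene"])
        for (t, a, s), grp in area_table.groupby(["cell_type", "area", "stage"])
    }
    with open(f"{args.data}/signatures.json", "w") as fh:
        json.dump(sigs, fh, indent=1)

    top = (area_table[area_table["cell_type"] == "neuron"]
           .sort_values("gene_score", ascending=False)["gene"].unique()[:12])
    if len(top) >= 1:
        z, fracs, flags = mk.group_scaled_means(adata[adata.obs["cell_type"] == "neuron"],
                                                top, "area")
        z.to_csv(f"{args.data}/dotplot_z.tsv", sep="\t")
        fracs.to_csv(f"{args.data}/dotplot_frac.tsv", sep="\t")


if __name__ == "__main__":
    main()
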