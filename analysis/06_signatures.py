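#!/usr/bin/env python
"""Signature-overlap quantification: row-normalized overlap between the
(cell type, area, stage) marker signatures, hierarchical clustering of the
signature nodes, and the Sankey link table between consecutive stages."""

import argparse
import json

from arealize import io
from arealize import signatures as sg


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data")
    args = ap.parse_args()

    with open(f"{args.data}/signatures.json") as fh:
        sigs = json.load(fh)
    nodes = []
    for nid, genes in sigs.items():
        t, a, s = nid.split("|")
        nodes.append(sg.SignatureNode(id=nid, genes=frozenset(genes),
                                      cell_type=t, area=a, stage=s))
    if len(nodes) < 2:
        raise SystemExit("need at least two signature nodes; run 04_markers.py first")

    overlap = sg.signature_overlap(nodes)
    overlap.to_csv(f"{args.data}/overlap.tsv", sep="\t")
    Z, labels = sg.overlap_hierarchy(overlap)
    with open(f"{args.data}/overlap_tree.nwk", "w") as fh:
        fh.write(io.linkage_to_newick(Z, labels) + "\n")
    links = sg.sankey_links(nodes)
    links.to_csv(f"{args.data}/links.tsv", sep="\t", index=False)

    off = overlap.to_numpy()[~(overlap.to_numpy() == 1.0)]
    print(f"{len(nodes)} signature nodes; mean off-diagonal shared proportion "
          f"{off.mean():.3f}")
    if len(links):
        print(f"{len(links)} stage-adjacent links; mean shared genes "
              f"{links['shared_genes'].mean():.1f}")
    else:
        print("single stage present: no Sankey links")


if __name__ == "__main__":
    main()
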