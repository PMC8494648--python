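#!/usr/bin/env python
"""Filter the simulated atlas: per-lane doublet scoring, then the 750-gene
and 10%-mito thresholds.  Writes the filtered atlas and qc_report.tsv."""

import argparse

from arealize import io, qc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--min-genes", type=int, default=750)
    ap.add_argument("--max-mito", type=float, default=0.10)
    ap.add_argument("--data", default="results/data")
    args = ap.parse_args()

    adata = io.read_atlas(f"{args.data}/atlas")
    config = qc.QCConfig(min_genes_per_cell=args.min_genes,
                         max_mito_fraction=args.max_mito, seed=args.seed)
    filtered, report = qc.filter_cells(adata, config)
    io.write_atlas(filtered, f"{args.data}/atlas_qc")
    report.per_cell.to_csv(f"{args.data}/qc_report.tsv", sep="\t")
    s = report.summary
    print(f"retained {s['n_retained']}/{s['n_input']} cells "
          f"({100 * s['n_retained'] / s['n_input']:.1f}%)")
    print(f"removed: {s['fail_doublet']} doublet-flagged, "
          f"{s['fail_low_genes']} under {args.min_genes} genes, "
          f"{s['fail_high_mito']} over {100 * args.max_mito:.0f}% mito")


if __name__ == "__main__":
    main()
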