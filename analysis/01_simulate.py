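#!/usr/bin/env python
"""Simulate the synthetic arealization atlas and the laminar smFISH scene.

Writes the atlas as Matrix Market counts + cells.tsv/genes.tsv (planted
truth riding along as truth_* columns) and the spatial scene as
nuclei.csv/spots.csv, then prints what was planted.
"""

import argparse

from arealize import io
from arealize.synthdata import (
    AtlasConfig,
    SpatialConfig,
    SpatialGene,
    generate_atlas,
    generate_spatial,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cells-per-individual", type=int, default=3000)
    ap.add_argument("--genes", type=int, default=2000)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    cfg = AtlasConfig(seed=args.seed, n_cells_per_individual=args.cells_per_individual,
                      n_genes=args.genes)
    adata, truth = generate_atlas(cfg)
    io.write_atlas(adata, f"{args.out}/atlas", truth=truth)
    roles = truth.genes["role"].value_counts().to_dict()
    print(f"atlas: {adata.n_obs} cells ({int(truth.cells['doublet'].sum())} doublets) "
          f"x {adata.n_vars} genes across {cfg.n_individuals} individuals")
    print(f"planted gene roles: {roles}")

    flat = {"VZ": 1, "SVZ": 1, "IZ": 1, "SP": 1, "CP": 1}
    genes = (
        SpatialGene("SOX2", {"VZ": 1.0, "SVZ": 0.5, "IZ": 0, "SP": 0, "CP": 0}),
        SpatialGene("SATB2", {"VZ": 0, "SVZ": 0, "IZ": 0.1, "SP": 0.3, "CP": 1.0}),
        SpatialGene("BCL11B", {"VZ": 0, "SVZ": 0, "IZ": 0.2, "SP": 0.6, "CP": 0.8}),
        SpatialGene("NEFL", {"VZ": 0, "SVZ": 0, "IZ": 0, "SP": 1.0, "CP": 0.2}, coexpr_group="sp"),
        SpatialGene("SERPINI1", {"VZ": 0, "SVZ": 0, "IZ": 0, "SP": 1.0, "CP": 0.2}, coexpr_group="sp"),
        SpatialGene("POLR2A", flat),
    )
    scfg = SpatialConfig(genes=genes, n_nuclei=1500, spots_per_cell_mean=8.0,
                         background_spot_rate=2e-5, seed=args.seed)
    scene, struth = generate_spatial(scfg)
    io.write_spatial(scene, f"{args.out}/spatial", truth=struth)
    print(f"smFISH scene: {len(scene.nuclei)} nuclei, {len(scene.spots)} spots, "
          f"{scene.spots['gene'].nunique()} genes")


if __name__ == "__main__":
    main()
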