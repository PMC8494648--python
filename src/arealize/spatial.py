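"""smFISH quantification: spot-to-cell assignment by maximum boundary
distance, low-count cell filtering, laminar KDE profiles, and the gene-gene
co-expression network.

Nuclei are circles (centroid + radius); a spot's distance to a nucleus is
its Euclidean distance to the centroid minus the radius, floored at zero, so
spots inside a nucleus are at distance 0.  Each spot goes to the nearest
nucleus by that measure iff the distance is within ``max_dist`` (inclusive);
equidistant ties break to the lower nucleus id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

DEFAULT_EXCLUDE = ("POLR2A", "SOX2", "EOMES", "DLX6")


def assign_spots(
    spots: pd.DataFrame,
    nuclei: pd.DataFrame,
    max_dist: float = 15.0,
    chunk: int = 2048,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Assign each spot to its nearest nucleus within ``max_dist``.

    Returns (cell x gene count matrix with per-cell location and nuclear
    size, the unassigned spots, and the per-spot assigned nucleus id with -1
    for unassigned).
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    n_spots = len(spots)
    if len(nuclei) == 0:
        import warnings

        warnings.warn("empty nuclei table: all spots unassigned")
        assigned = np.full(n_spots, -1, dtype=int)
        empty = pd.DataFrame()
        return empty, spots.copy(), assigned
    if nuclei["id"].duplicated().any():
        raise ValueError("nucleus ids must be unique")
    # sort by id so the argmin tie-break lands on the lower id
    nuc = nuclei.sort_values("id").reset_index(drop=True)
    cx = nuc["x"].to_numpy(float)
    cy = nuc["y"].to_numpy(float)
    cr = nuc["radius"].to_numpy(float)
    ids = nuc["id"].to_numpy()
    sx = spots["x"].to_numpy(float)
    sy = spots["y"].to_numpy(float)
    assigned = np.full(n_spots, -1, dtype=int)
    for start in range(0, n_spots, chunk):
        stop = min(start + chunk, n_spots)
        d = np.hypot(sx[start:stop, None] - cx[None, :], sy[start:stop, None] - cy[None, :])
        d = np.maximum(d - cr[None, :], 0.0)
        j = np.argmin(d, axis=1)  # first minimum = lowest id after sort
        dmin = d[np.arange(stop - start), j]
        ok = dmin <= max_dist
        assigned[start:stop][ok] = ids[j[ok]]
    genes = sorted(spots["gene"].astype(str).unique())
    counts = pd.DataFrame(0, index=ids, columns=genes, dtype=int)
    mask = assigned >= 0
    tab = (
        pd.DataFrame({"nucleus": assigned[mask], "gene": spots["gene"].astype(str)[mask]})
        .groupby(["nucleus", "gene"])
        .size()
    )
    for (nid, g), c in tab.items():
        counts.loc[nid, g] = c
    matrix = counts.copy()
    matrix.insert(0, "nuclear_size", cr)
    matrix.insert(0, "y", cy)
    matrix.insert(0, "x", cx)
    matrix.index.name = "cell_id"
    unassigned = spots[~mask].copy()
    return matrix, unassigned, assigned


def gene_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in ("x", "y", "nuclear_size")]


def filter_spatial_cells(matrix: pd.DataFrame, min_counts: int = 10) -> pd.DataFrame:
    """Drop cells whose total assigned spot count is below ``min_counts``
    (a cell at exactly the threshold is retained)."""
    if len(matrix) == 0:
        raise ValueError("empty cell x gene matrix")
    totals = matrix[gene_columns(matrix)].sum(axis=1)
    keep = totals >= min_counts
    if not keep.any():
        raise ValueError("all cells removed by the minimum-count filter")
    return matrix[keep].copy()


def laminar_kde(
    spots: pd.DataFrame,
    bandwidth: float | None = None,
    y_range: tuple[float, float] | None = None,
    n_grid: int = 512,
) -> tuple[pd.DataFrame, float | None]:
    """Laminar (1-D over y) Gaussian KDE of one gene's spots, plus the
    intensity-per-spot quantification scalar.

    Returns (profile frame with columns y, density; quantification =
    total intensity / spot count).  Zero spots yields (empty, None); a single
    spot or zero-variance y falls back to a fixed minimum bandwidth.
    """
    n = len(spots)
    if n == 0:
        return pd.DataFrame(columns=["y", "density"]), None
    y = spots["y"].to_numpy(float)
    quant = float(spots["intensity"].sum() / n)
    lo, hi = y_range if y_range is not None else (y.min(), y.max())
    bw_min = max((hi - lo) / 100.0, 1e-6)
    if n < 2 or np.std(y) == 0:
        bw = bandwidth if bandwidth is not None else bw_min
        grid = np.linspace(lo - 5 * bw, hi + 5 * bw, n_grid)
        dens = np.zeros_like(grid)
        for yi in y:
            dens += np.exp(-0.5 * ((grid - yi) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
        dens /= n
    else:
        kde = gaussian_kde(y, bw_method=bandwidth / np.std(y) if bandwidth else "scott")
        bw = kde.factor * np.std(y)
        grid = np.linspace(lo - 5 * bw, hi + 5 * bw, n_grid)
        dens = kde(grid)
    return pd.DataFrame({"y": grid, "density": dens}), quant


def coexpression_network(
    matrix: pd.DataFrame,
    exclude=DEFAULT_EXCLUDE,
    r_min: float = 0.05,
    binarize: bool = False,
) -> pd.DataFrame:
    """Gene-gene Pearson network over the filtered cell x gene matrix.

    Excluded genes are dropped before correlation; self-edges are removed and
    undirected edges with r >= r_min (inclusive) are kept.  ``binarize``
    correlates presence/absence instead of counts.
    """
    excl = {str(g).upper() for g in exclude}
    genes = [g for g in gene_columns(matrix) if str(g).upper() not in excl]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes after exclusion")
    M = matrix[genes].to_numpy(float)
    if binarize:
        M = (M > 0).astype(float)
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(M.T)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = C[i, j]
            if np.isfinite(r) and r >= r_min:
                rows.append({"gene1": genes[i], "gene2": genes[j], "r": float(r)})
    return pd.DataFrame(rows, columns=["gene1", "gene2", "r"])
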