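"""Marker statistics: rank-sum differential expression, the gene-score
statistic, stage binning, transcription-factor annotation, module-eigengene
signature scoring, and dot-plot group scaling.

Conventions pinned here (the source analyses leave them open):

* expression is library-size normalized to 10,000 counts per cell;
  the rank-sum test runs on log1p of that; ``avg_logFC`` is the natural-log
  ratio ``ln(mean_in + 1) - ln(mean_out + 1)`` of normalized (pre-log) means;
* "expressing" means raw count > 0;
* Bonferroni over all features in the matrix; significant iff p_adj <= 0.05;
* ``enrichment_ratio = pct_in / max(pct_out, 0.001)``,
  ``gene_score = avg_logFC * enrichment_ratio``;
* exact rank-sum enumeration when both groups are small (min(n,m) <= 8 and
  C(n+m, min) <= 2e5), tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import norm, rankdata

from . import preprocess

log = logging.getLogger(__name__)

PCT_EPS = 1e-3
SIG_ALPHA = 0.05
EXACT_MAX_GROUP = 8
EXACT_MAX_COMBS = 200_000

STAGE_BINS: dict[int, str] = {
    14: "early", 16: "early", 17: "early",
    18: "middle", 19: "middle", 20: "middle",
    22: "late", 25: "late",
}

STAGE_ORDER = ("early", "middle", "late")


def stage_bin(gw: int) -> str:
    """Map a sampled gestational week to early/middle/late; no interpolation."""
    try:
        return STAGE_BINS[int(gw)]
    except KeyError:
        raise ValueError(f"gestational week {gw} is not in the sampled design") from None


def gene_score(avg_logFC: float, pct_in: float, pct_out: float, eps: float = PCT_EPS) -> float:
    """avg_logFC times the enrichment ratio pct_in / max(pct_out, eps)."""
    return avg_logFC * (pct_in / max(pct_out, eps))


def exact_ranksum_p(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration.

    p = P(|U - nm/2| >= |u_obs - nm/2|) over all equally likely assignments
    of the pooled (midrank-tied) values to the two groups.
    """
    n, m = len(x_in), len(x_out)
    pooled = np.concatenate([x_in, x_out])
    ranks = rankdata(pooled)
    small = min(n, m)
    u_obs = _u_stat(ranks[:n].sum() if n <= m else ranks[n:].sum(), small, n + m - small)
    combs = np.array(list(combinations(range(n + m), small)))
    u_all = _u_stat(ranks[combs].sum(axis=1), small, n + m - small)
    center = small * (n + m - small) / 2.0
    return float(np.mean(np.abs(u_all - center) >= np.abs(u_obs - center) - 1e-12))


def _u_stat(rank_sum, n_small: int, n_large: int):
    return rank_sum - n_small * (n_small + 1) / 2.0


def _edgeworth_two_sided_p(s_centered, T2, T4, N: int, n: int, lattice):
    """Two-sided p for a centered rank sum under sampling without replacement.

    Uses the exact finite-population variance and fourth moment of the sum of
    ``n`` midranks drawn from the pooled ``N`` (tie correction is implicit in
    the midrank power sums T2, T4) and an Edgeworth kurtosis term; the third
    cumulant vanishes only at n = N/2, but the two-sided statistic |S| is
    insensitive to skew at first order, so the symmetric expansion is used
    throughout.  ``lattice`` is the rank spacing for the continuity
    correction.  Vectorized over genes.
    """

    def P(r: int):
        num = den = 1.0
        for t in range(r):
            num *= n - t
            den *= N - t
        return num / den

    T2 = np.asarray(T2, dtype=float)
    T4 = np.asarray(T4, dtype=float)
    var = T2 * (P(1) - P(2))
    m4 = P(1) * T4 + P(2) * (3 * T2**2 - 7 * T4) + P(3) * (12 * T4 - 6 * T2**2) + P(4) * (
        3 * T2**2 - 6 * T4
    )
    s = np.abs(np.asarray(s_centered, dtype=float))
    p = np.ones_like(s)
    ok = var > 0
    sd = np.sqrt(var[ok])
    gamma2 = m4[ok] / var[ok] ** 2 - 3.0
    z = (-(s[ok]) + np.asarray(lattice, dtype=float)[ok] / 2.0) / sd
    cdf = norm.cdf(z) - norm.pdf(z) * gamma2 / 24.0 * (z**3 - 3 * z)
    p[ok] = np.clip(2.0 * cdf, 0.0, 1.0)
    return p


def approx_ranksum_p(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Two-sided Edgeworth-corrected (tie-aware) rank-sum approximation."""
    n, m = len(x_in), len(x_out)
    pooled = np.concatenate([x_in, x_out])
    ranks = rankdata(pooled)
    y = ranks - (n + m + 1) / 2.0
    s = y[:n].sum()
    uniq_vals, counts = np.unique(pooled, return_counts=True)
    lattice = 1.0 if len(uniq_vals) == len(pooled) else 0.5
    p = _edgeworth_two_sided_p(
        np.array([s]),
        np.array([(y**2).sum()]),
        np.array([(y**4).sum()]),
        n + m,
        n,
        np.array([lattice]),
    )
    return float(p[0])


def ranksum_p(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Exact enumeration when feasible, else the tie-corrected approximation."""
    n, m = len(x_in), len(x_out)
    small = min(n, m)
    if small <= EXACT_MAX_GROUP and math.comb(n + m, small) <= EXACT_MAX_COMBS:
        return exact_ranksum_p(x_in, x_out)
    return approx_ranksum_p(x_in, x_out)


def _dense(M) -> np.ndarray:
    return M.toarray() if sp.issparse(M) else np.asarray(M)


def _vectorized_approx_p(L: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Edgeworth-corrected tie-aware rank-sum p per gene (columns of L)."""
    n_cells, n_genes = L.shape
    n = int(in_mask.sum())
    ranks = rankdata(L, axis=0)
    y = ranks - (n_cells + 1) / 2.0
    s = y[in_mask].sum(axis=0)
    T2 = (y**2).sum(axis=0)
    T4 = (y**4).sum(axis=0)
    has_ties = np.array(
        [len(np.unique(L[:, j])) < n_cells for j in range(n_genes)]
    )
    lattice = np.where(has_ties, 0.5, 1.0)
    return _edgeworth_two_sided_p(s, T2, T4, n_cells, n, lattice)


def wilcoxon_de(
    adata: AnnData,
    labels: pd.Series | np.ndarray,
    group: str,
    cluster_name: str | None = None,
) -> pd.DataFrame:
    """Two-sided rank-sum DE of ``group`` vs its complement, one row per gene.

    Returns a MarkerTable-style frame with p_value, p_adj (Bonferroni over all
    features), avg_logFC, pct_in, pct_out, enrichment_ratio, gene_score and a
    ``significant`` flag (p_adj <= 0.05).
    """
    labels = np.asarray(labels).astype(str)
    in_mask = labels == str(group)
    if in_mask.sum() == 0 or in_mask.sum() == len(labels):
        raise ValueError("group and complement must both be nonempty")
    if "lognorm" not in adata.layers:
        preprocess.lognorm(adata)
    L = _dense(adata.layers["lognorm"]).astype(float)
    X = adata.X
    Xd = _dense(X)
    n_genes = adata.n_vars
    n_in = int(in_mask.sum())
    n_out = len(labels) - n_in

    norm_counts = np.expm1(L)  # back to the 10k-scaled values
    mean_in = norm_counts[in_mask].mean(axis=0)
    mean_out = norm_counts[~in_mask].mean(axis=0)
    avg_logfc = np.log(mean_in + 1.0) - np.log(mean_out + 1.0)
    pct_in = (Xd[in_mask] > 0).mean(axis=0)
    pct_out = (Xd[~in_mask] > 0).mean(axis=0)

    small = min(n_in, n_out)
    if small <= EXACT_MAX_GROUP and math.comb(n_in + n_out, small) <= EXACT_MAX_COMBS:
        p = np.array(
            [exact_ranksum_p(L[in_mask, j], L[~in_mask, j]) for j in range(n_genes)]
        )
    else:
        p = _vectorized_approx_p(L, in_mask)

    all_zero = np.asarray((Xd != 0).sum(axis=0)).ravel() == 0
    p[all_zero] = 1.0
    avg_logfc[all_zero] = 0.0

    p_adj = np.minimum(1.0, p * n_genes)
    enrich = pct_in / np.maximum(pct_out, PCT_EPS)
    out = pd.DataFrame(
        {
            "gene": adata.var_names,
            "cluster": cluster_name if cluster_name is not None else str(group),
            "p_value": p,
            "p_adj": p_adj,
            "avg_logFC": avg_logfc,
            "pct_in": pct_in,
            "pct_out": pct_out,
            "enrichment_ratio": enrich,
            "gene_score": avg_logfc * enrich,
            "significant": p_adj <= SIG_ALPHA,
        }
    )
    return out.reset_index(drop=True)


def annotate_tfs(markers: pd.DataFrame, tf_list) -> pd.DataFrame:
    """Subset marker records to transcription factors (case-normalized match)."""
    tfs = {str(t).strip().upper() for t in tf_list if str(t).strip()}
    if not tfs:
        raise ValueError("tf_list must be nonempty")
    if len(markers) == 0:
        return markers.copy()
    keep = markers["gene"].astype(str).str.upper().isin(tfs)
    if not keep.any():
        log.warning("no marker genes found in the transcription-factor list")
    return markers[keep].copy()


def read_tf_list(path: str) -> set[str]:
    """One gene symbol per line."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


@dataclass
class SignatureScore:
    """Per-cell eigengene value of a gene set (unit variance, sign oriented
    so the score correlates nonnegatively with the set's mean scaled
    expression)."""

    scores: pd.Series
    genes_used: list[str]
    cells: list[str]
    sign: int
    name: str = ""


def module_eigengene(
    adata: AnnData,
    gene_set,
    max_cells: int = 10_000,
    seed: int = 0,
    name: str = "",
) -> SignatureScore:
    """First principal component of the standardized expression of a gene set.

    Cells are randomly subsampled to ``max_cells`` when larger; the gene set
    is intersected with genes expressed (count > 0) in the scored cells.
    """
    rng = np.random.default_rng(seed)
    cells = np.arange(adata.n_obs)
    if adata.n_obs > max_cells:
        cells = np.sort(rng.choice(adata.n_obs, size=max_cells, replace=False))
    sub = adata[cells]
    if "lognorm" not in adata.layers:
        preprocess.lognorm(adata)
    L = _dense(adata.layers["lognorm"])[cells]
    X = _dense(sub.X)
    expressed = np.asarray((X > 0).sum(axis=0)).ravel() > 0
    want = set(map(str, gene_set))
    gidx = [j for j, g in enumerate(adata.var_names) if g in want and expressed[j]]
    if not gidx:
        raise ValueError(f"signature {name or '<unnamed>'}: empty intersection with expressed genes")
    M = L[:, gidx]
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (M - mean) / sd
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    score = U[:, 0]
    sd_score = score.std()
    score = score / (sd_score if sd_score > 0 else 1.0)
    ref = Z.mean(axis=1)
    sign = 1
    if np.corrcoef(score, ref)[0, 1] < 0:
        sign = -1
        score = -score
    return SignatureScore(
        scores=pd.Series(score, index=np.asarray(sub.obs_names)),
        genes_used=[str(adata.var_names[j]) for j in gidx],
        cells=list(map(str, sub.obs_names)),
        sign=sign,
        name=name,
    )


def group_scaled_means(
    adata: AnnData, genes, groupby: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Dot-plot table: per gene, mean lognorm expression over *non-zero* cells
    per group, z-scored across groups with the n-1 denominator (the R
    ``scale()`` convention); plus the fraction of expressing cells per group
    and a flag table for degenerate entries (no expressing cells in a group,
    or zero variance across groups)."""
    groups = adata.obs[groupby].astype(str)
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    if "lognorm" not in adata.layers:
        preprocess.lognorm(adata)
    L = _dense(adata.layers["lognorm"])
    X = _dense(adata.X)
    genes = [str(g) for g in genes]
    gidx = {g: adata.var_names.get_loc(g) for g in genes}
    means = pd.DataFrame(0.0, index=genes, columns=uniq)
    fracs = pd.DataFrame(0.0, index=genes, columns=uniq)
    flags = pd.DataFrame("", index=genes, columns=uniq)
    for grp in uniq:
        sel = (groups == grp).to_numpy()
        for g in genes:
            j = gidx[g]
            nz = X[sel, j] > 0
            fracs.loc[g, grp] = nz.mean()
            if nz.any():
                means.loc[g, grp] = L[sel, j][nz].mean()
            else:
                means.loc[g, grp] = 0.0
                flags.loc[g, grp] = "no_expressing_cells"
    z = means.copy()
    for g in genes:
        row = means.loc[g].to_numpy(dtype=float)
        sd = row.std(ddof=1)  # R scale() convention
        if sd == 0:
            z.loc[g] = 0.0
            flags.loc[g] = flags.loc[g].where(flags.loc[g] != "", "zero_variance")
        else:
            z.loc[g] = (row - row.mean()) / sd
    return z, fracs, flags


def area_markers_by_stage(
    adata: AnnData,
    celltype_col: str,
    area_col: str = "area",
    individual_col: str = "individual",
    gw_col: str = "gw",
    cell_types=None,
) -> pd.DataFrame:
    """Area DE run separately per (cell type, individual), then combined.

    For every cell type and every individual, each area's cells are tested
    against the other areas' cells of that type and individual; significant
    up-regulated genes are kept, annotated with the individual's stage bin,
    and unioned across individuals.  Returns one row per
    (cell_type, area, gene, stage) with the best (max) gene score observed.
    """
    obs = adata.obs
    types = cell_types if cell_types is not None else sorted(obs[celltype_col].astype(str).unique())
    frames = []
    for t in types:
        for ind in sorted(obs[individual_col].astype(str).unique()):
            sel = (obs[celltype_col].astype(str) == t) & (obs[individual_col].astype(str) == ind)
            sub = adata[sel.to_numpy()].copy()
            if sub.n_obs < 4 or sub.obs[area_col].nunique() < 2:
                continue
            stage = stage_bin(int(sub.obs[gw_col].iloc[0]))
            for a in sorted(sub.obs[area_col].astype(str).unique()):
                n_in = int((sub.obs[area_col].astype(str) == a).sum())
                if n_in < 2 or n_in == sub.n_obs:
                    continue
                de = wilcoxon_de(sub, sub.obs[area_col], a, cluster_name=f"{t}|{a}")
                de = de[(de["significant"]) & (de["avg_logFC"] > 0)].copy()
                de["cell_type"] = t
                de["area"] = a
                de["stage"] = stage
                de["individual"] = ind
                frames.append(de)
    if not frames:
        return pd.DataFrame(
            columns=["cell_type", "area", "gene", "stage", "gene_score"]
        )
    allde = pd.concat(frames, ignore_index=True)
    combined = (
        allde.groupby(["cell_type", "area", "gene", "stage"], as_index=False)
        .agg(gene_score=("gene_score", "max"), avg_logFC=("avg_logFC", "max"))
    )
    return combined
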