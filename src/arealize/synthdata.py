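"""Seeded synthetic atlases and smFISH scenes with planted ground truth.

The generators emulate the statistical structure a second-trimester cortical
arealization atlas presents to the analysis stages: negative-binomial counts
over multiple individuals and cortical areas, planted cell-type and area
marker programs, a posterior-high/anterior-low gradient gene, per-individual
batch shifts, mitochondrial genes, heterotypic doublets — and, for the
spatial stage, a laminar tissue scene with segmented nuclei, per-gene laminar
spot densities and background spots.

All randomness flows from one root seed through ``numpy.random.SeedSequence``
spawning: one child stream per concern (gene roles, per-individual counts,
doublets, ...), so outputs are bitwise reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AtlasConfig",
    "AtlasTruth",
    "SpatialGene",
    "SpatialConfig",
    "SpatialScene",
    "generate_atlas",
    "generate_spatial",
    "generate_stage_signatures",
    "DEFAULT_AREAS",
    "DEFAULT_CELL_TYPES",
]

#: Rostro-caudal area order; the gradient gene rises from PFC toward V1.
DEFAULT_AREAS = ("PFC", "motor", "somatosensory", "parietal", "temporal", "V1")

#: Broad cell classes of the excitatory-lineage-centric atlas.
DEFAULT_CELL_TYPES = ("RG", "IPC", "neuron", "inhibitory", "microglia", "vascular")


def _default_area_marker_counts() -> dict[str, int]:
    # Areal programs strengthen along the excitatory lineage RG -> IPC -> neuron;
    # non-lineage types carry none by default.
    return {"RG": 2, "IPC": 5, "neuron": 10, "inhibitory": 0, "microglia": 0, "vascular": 0}


@dataclass
class AtlasConfig:
    """Parameters of the synthetic multi-individual atlas.

    ``marker_fold_change`` is the multiplicative effect applied to a planted
    marker's mean inside its owning group. ``batch_sigma`` is the standard
    deviation of the per-individual, per-gene log-normal shift. ``dispersion``
    is the NB size parameter theta with variance = mu + mu^2/theta.
    """

    n_individuals: int = 3
    gestational_weeks: tuple[int, ...] = (14, 18, 22)
    areas: tuple[str, ...] = DEFAULT_AREAS
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_cells_per_individual: int = 3000
    n_genes: int = 2000
    marker_fold_change: float = 4.0
    n_markers_per_celltype: int = 15
    n_markers_per_area_by_celltype: dict[str, int] = field(
        default_factory=_default_area_marker_counts
    )
    gradient_gene_count: int = 5
    batch_sigma: float = 0.2
    mito_gene_fraction: float = 0.005
    doublet_rate: float = 0.05
    dispersion: float = 2.0
    baseline_mean: float = 1.5
    shared_area_signature: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_cells_per_individual < 1 or self.n_genes < 1:
            raise ValueError("all counts must be positive")
        if not self.areas or not self.cell_types:
            raise ValueError("area and cell-type lists must be nonempty")
        if not (0 <= self.doublet_rate < 0.5):
            raise ValueError("doublet_rate must lie in [0, 0.5)")
        if self.marker_fold_change <= 0 or self.dispersion <= 0:
            raise ValueError("marker_fold_change and dispersion must be positive")
        if not (0 < self.mito_gene_fraction < 1):
            raise ValueError("mito_gene_fraction must lie in (0,1)")
        if self.batch_sigma < 0:
            raise ValueError("batch_sigma must be nonnegative")
        if len(self.gestational_weeks) != self.n_individuals:
            raise ValueError("need one gestational week per individual")
        bad_gw = set(self.gestational_weeks) - {14, 16, 17, 18, 19, 20, 22, 25}
        if bad_gw:
            raise ValueError(f"gestational weeks outside the sampled design: {sorted(bad_gw)}")
        n_mito = max(1, int(round(self.mito_gene_fraction * self.n_genes)))
        n_marked = (
            self.n_markers_per_celltype * len(self.cell_types)
            + sum(self.n_markers_per_area_by_celltype.get(t, 0) for t in self.cell_types)
            * len(self.areas)
            + self.gradient_gene_count
        )
        if n_marked + n_mito > self.n_genes:
            raise ValueError(
                f"requested {n_marked} marker + {n_mito} mito genes but only "
                f"{self.n_genes} genes available"
            )


@dataclass
class AtlasTruth:
    """Planted ground truth: per-cell labels and per-gene roles.

    ``cells`` has one row per emitted column of the matrix (doublets included)
    with columns cell_type, area, doublet, parent1, parent2.  ``genes`` has one
    row per gene with columns role (celltype_marker / area_marker /
    gradient / mito / background), owner_type, owner_area.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB(mean=mu, size=theta): variance mu + mu^2/theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def generate_atlas(config: AtlasConfig) -> tuple[ad.AnnData, AtlasTruth]:
    """Generate a seeded synthetic atlas.

    Returns an AnnData with raw NB counts in ``X`` (cells x genes, CSR), cell
    metadata (individual, area, region, gw) in ``obs`` and the mitochondrial
    flag in ``var``, together with the :class:`AtlasTruth`.

    Log-mean model per (cell, gene)::

        log mu = log(baseline_g)
               + log(FC) * [g is marker of cell's type]
               + log(FC) * [g is area marker of (cell's type, cell's area)]
               + log(FC) * rank(area)/(n_areas-1) * [g is gradient gene]
               + batch_shift(individual, g)

    Doublets are appended columns equal to the elementwise sum of two distinct
    same-individual cells (no downsampling), flagged in the truth.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_roles, ss_baseline, ss_cells, ss_batch = root.spawn(4)
    rng_roles = np.random.default_rng(ss_roles)
    rng_baseline = np.random.default_rng(ss_baseline)
    rng_batch = np.random.default_rng(ss_batch)

    n_genes = cfg.n_genes
    n_mito = max(1, int(round(cfg.mito_gene_fraction * n_genes)))

    # --- gene roles -------------------------------------------------------
    roles = pd.DataFrame(
        {
            "role": np.repeat("background", n_genes),
            "owner_type": np.repeat("", n_genes),
            "owner_area": np.repeat("", n_genes),
        }
    )
    order = rng_roles.permutation(n_genes)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor : cursor + k]
        cursor += k
        return idx

    mito_idx = take(n_mito)
    roles.loc[mito_idx, "role"] = "mito"
    type_markers: dict[str, np.ndarray] = {}
    for t in cfg.cell_types:
        idx = take(cfg.n_markers_per_celltype)
        type_markers[t] = idx
        roles.loc[idx, "role"] = "celltype_marker"
        roles.loc[idx, "owner_type"] = t
    area_markers: dict[tuple[str, str], np.ndarray] = {}
    for t in cfg.cell_types:
        k = cfg.n_markers_per_area_by_celltype.get(t, 0)
        for a in cfg.areas:
            idx = take(k)
            area_markers[(t, a)] = idx
            roles.loc[idx, "role"] = "area_marker"
            roles.loc[idx, "owner_type"] = t
            roles.loc[idx, "owner_area"] = a
    gradient_idx = take(cfg.gradient_gene_count)
    roles.loc[gradient_idx, "role"] = "gradient"

    gene_names = np.array([f"G{i:04d}" for i in range(n_genes)], dtype=object)
    gene_names[mito_idx] = [f"MT-G{i:04d}" for i in mito_idx]
    roles.index = gene_names

    baseline = rng_baseline.lognormal(mean=np.log(cfg.baseline_mean), sigma=1.0, size=n_genes)
    planted = roles["role"].isin(["celltype_marker", "area_marker", "gradient"]).to_numpy()
    # planted markers emulate robustly detected genes (the kind chosen for
    # validation panels), so their baseline is floored at one count per cell
    baseline[planted] = np.maximum(baseline[planted], 1.0)
    # Mitochondrial transcripts are high-abundance; scale so they carry ~5% of
    # the expected library in an unremarkable cell.
    target_frac = 0.05
    nonmito_total = baseline[roles["role"].to_numpy() != "mito"].sum()
    mito_scale = (target_frac / (1 - target_frac)) * nonmito_total / baseline[mito_idx].sum()
    baseline[mito_idx] *= mito_scale

    log_fc = np.log(cfg.marker_fold_change)
    area_rank = {a: i for i, a in enumerate(cfg.areas)}
    n_areas = len(cfg.areas)

    # Per-gene additive log-effect for each (type, area) group, shared by all
    # individuals; assembled once then applied per cell.
    group_effect: dict[tuple[str, str], np.ndarray] = {}
    signature_donor = "neuron" if "neuron" in cfg.cell_types else cfg.cell_types[-1]
    lineage = {"RG", "IPC"}
    for t in cfg.cell_types:
        for a in cfg.areas:
            eff = np.zeros(n_genes)
            eff[type_markers[t]] += log_fc
            eff[area_markers[(t, a)]] += log_fc
            if cfg.shared_area_signature and t in lineage and t != signature_donor:
                eff[area_markers[(signature_donor, a)]] += log_fc
            if cfg.gradient_gene_count and n_areas > 1:
                eff[gradient_idx] += log_fc * area_rank[a] / (n_areas - 1)
            group_effect[(t, a)] = eff

    blocks: list[sp.csr_matrix] = []
    obs_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for i in range(cfg.n_individuals):
        ind = f"ind{i + 1}"
        ss_i = ss_cells.spawn(1)[0]
        rng_i = np.random.default_rng(ss_i)
        n = cfg.n_cells_per_individual
        types = rng_i.choice(len(cfg.cell_types), size=n)
        areas = rng_i.choice(len(cfg.areas), size=n)
        batch = rng_batch.normal(0.0, cfg.batch_sigma, size=n_genes)
        log_mu_base = np.log(baseline) + batch
        counts = np.empty((n, n_genes), dtype=np.int64)
        for (ti, ai) in {(t, a) for t, a in zip(types, areas)}:
            mask = (types == ti) & (areas == ai)
            mu = np.exp(log_mu_base + group_effect[(cfg.cell_types[ti], cfg.areas[ai])])
            counts[mask] = _nb_draw(rng_i, np.broadcast_to(mu, (mask.sum(), n_genes)), cfg.dispersion)
        n_dbl = int(round(cfg.doublet_rate * n))
        if n_dbl > 0:
            p1 = rng_i.integers(0, n, size=n_dbl)
            p2 = (p1 + rng_i.integers(1, n, size=n_dbl)) % n  # distinct partner
            dbl_counts = counts[p1] + counts[p2]
            counts = np.vstack([counts, dbl_counts])
        cell_ids = [f"{ind}_c{j:05d}" for j in range(n)] + [
            f"{ind}_dbl{j:04d}" for j in range(n_dbl)
        ]
        type_lab = [cfg.cell_types[t] for t in types]
        area_lab = [cfg.areas[a] for a in areas]
        if n_dbl > 0:
            type_lab += [cfg.cell_types[types[j]] for j in p1]
            area_lab += [cfg.areas[areas[j]] for j in p1]
        obs_frames.append(
            pd.DataFrame(
                {
                    "individual": ind,
                    "area": area_lab,
                    "region": "neocortex",
                    "gw": cfg.gestational_weeks[i],
                },
                index=cell_ids,
            )
        )
        truth_frames.append(
            pd.DataFrame(
                {
                    "cell_type": type_lab,
                    "area": area_lab,
                    "doublet": [False] * n + [True] * n_dbl,
                    "parent1": [""] * n + [cell_ids[j] for j in p1] if n_dbl else [""] * n,
                    "parent2": [""] * n + [cell_ids[j] for j in p2] if n_dbl else [""] * n,
                },
                index=cell_ids,
            )
        )
        blocks.append(sp.csr_matrix(counts))

    X = sp.vstack(blocks, format="csr")
    obs = pd.concat(obs_frames)
    obs.index.name = "cell_id"
    var = pd.DataFrame({"mito": roles["role"].to_numpy() == "mito"}, index=gene_names)
    var.index.name = "gene_id"
    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth_cells = pd.concat(truth_frames)
    truth_cells.index.name = "cell_id"
    return adata, AtlasTruth(cells=truth_cells, genes=roles)


# ---------------------------------------------------------------------------
# smFISH scene
# ---------------------------------------------------------------------------

@dataclass
class SpatialGene:
    """A probed gene: relative spot density per laminar zone, mean intensity,
    and an optional co-expression group (genes sharing a group share a
    per-cell gamma rate factor)."""

    name: str
    zone_density: dict[str, float]
    mean_intensity: float = 100.0
    coexpr_group: str | None = None


def _default_zones() -> tuple[tuple[str, float, float], ...]:
    return (
        ("VZ", 0.0, 200.0),
        ("SVZ", 200.0, 500.0),
        ("IZ", 500.0, 800.0),
        ("SP", 800.0, 1000.0),
        ("CP", 1000.0, 1400.0),
    )


@dataclass
class SpatialConfig:
    """Parameters of the synthetic laminar smFISH scene (distances in um)."""

    zones: tuple[tuple[str, float, float], ...] = field(default_factory=_default_zones)
    x_range: tuple[float, float] = (0.0, 500.0)
    n_nuclei: int = 500
    nucleus_radius: float = 5.0
    genes: tuple[SpatialGene, ...] = ()
    spots_per_cell_mean: float = 20.0
    background_spot_rate: float = 0.0
    spot_jitter: float = 2.0
    max_assign_distance: float = 15.0
    coexpr_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if self.nucleus_radius <= 0 or self.spots_per_cell_mean <= 0:
            raise ValueError("nucleus_radius and spots_per_cell_mean must be positive")
        if self.background_spot_rate < 0 or self.spot_jitter < 0:
            raise ValueError("rates and jitter must be nonnegative")
        zs = sorted(self.zones, key=lambda z: z[1])
        for (_, lo, hi) in zs:
            if hi <= lo:
                raise ValueError("zone extents must be increasing")
        for (za, zb) in zip(zs, zs[1:]):
            if abs(za[2] - zb[1]) > 1e-9:
                raise ValueError("zones must tile the y-range without gaps or overlap")
        names = {z[0] for z in self.zones}
        for g in self.genes:
            dens = [g.zone_density.get(z, 0.0) for z in names]
            if any(d < 0 for d in g.zone_density.values()):
                raise ValueError(f"negative density for gene {g.name}")
            if not any(d > 0 for d in dens):
                raise ValueError(f"gene {g.name} has zero density in every zone")


@dataclass
class SpatialScene:
    """Nuclei and spot tables of one synthetic scene."""

    nuclei: pd.DataFrame  # id, x, y, radius, zone
    spots: pd.DataFrame  # gene, x, y, intensity


def generate_spatial(config: SpatialConfig) -> tuple[SpatialScene, pd.Series]:
    """Generate a seeded laminar smFISH scene.

    Nuclei are placed uniformly over the tissue rectangle; per (cell, gene)
    spot counts are Poisson with rate ``spots_per_cell_mean * density(zone)``
    (times the cell's shared gamma factor for co-expression groups); spots are
    jittered isotropically around the owning nucleus centroid; background
    spots are uniform over the tissue with per-gene area rate
    ``background_spot_rate``.  Returns the scene and the truth map
    spot index -> owning nucleus id (-1 for background).
    """
    cfg = config
    if not cfg.genes:
        raise ValueError("need at least one gene")
    root = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(root)
    zs = sorted(cfg.zones, key=lambda z: z[1])
    y_lo, y_hi = zs[0][1], zs[-1][2]
    x_lo, x_hi = cfg.x_range

    nx = rng.uniform(x_lo, x_hi, cfg.n_nuclei)
    ny = rng.uniform(y_lo, y_hi, cfg.n_nuclei)
    zone_of = np.empty(cfg.n_nuclei, dtype=object)
    for name, lo, hi in zs:
        zone_of[(ny >= lo) & (ny < hi)] = name
    zone_of[ny >= y_hi] = zs[-1][0]
    nuclei = pd.DataFrame(
        {
            "id": np.arange(cfg.n_nuclei),
            "x": nx,
            "y": ny,
            "radius": np.full(cfg.n_nuclei, cfg.nucleus_radius),
            "zone": zone_of,
        }
    )

    groups = sorted({g.coexpr_group for g in cfg.genes if g.coexpr_group is not None})
    factors = {
        grp: rng.gamma(cfg.coexpr_shape, 1.0 / cfg.coexpr_shape, cfg.n_nuclei) for grp in groups
    }

    rows: list[pd.DataFrame] = []
    owners: list[np.ndarray] = []
    area = (x_hi - x_lo) * (y_hi - y_lo)
    for g in cfg.genes:
        dens = np.array([g.zone_density.get(z, 0.0) for z in zone_of], dtype=float)
        rate = cfg.spots_per_cell_mean * dens
        if g.coexpr_group is not None:
            rate = rate * factors[g.coexpr_group]
        counts = rng.poisson(rate)
        total = int(counts.sum())
        owner = np.repeat(np.arange(cfg.n_nuclei), counts)
        sx = nx[owner] + rng.normal(0.0, cfg.spot_jitter, total)
        sy = ny[owner] + rng.normal(0.0, cfg.spot_jitter, total)
        n_bg = rng.poisson(cfg.background_spot_rate * area)
        bx = rng.uniform(x_lo, x_hi, n_bg)
        by = rng.uniform(y_lo, y_hi, n_bg)
        inten = rng.gamma(4.0, g.mean_intensity / 4.0, total + n_bg)
        rows.append(
            pd.DataFrame(
                {
                    "gene": g.name,
                    "x": np.concatenate([sx, bx]),
                    "y": np.concatenate([sy, by]),
                    "intensity": inten,
                }
            )
        )
        owners.append(np.concatenate([owner, np.full(n_bg, -1, dtype=int)]))

    spots = pd.concat(rows, ignore_index=True)
    truth = pd.Series(np.concatenate(owners), name="truth_nucleus")
    return SpatialScene(nuclei=nuclei, spots=spots), truth


def generate_mixing_coords(
    groups: tuple[str, ...] = DEFAULT_AREAS,
    n_per_group: int = 80,
    n_dims: int = 10,
    separation: float = 8.0,
    mixing: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed synthetic PC-like coordinates with controlled between-group mixing.

    Groups sit on a line (the rostro-caudal axis) at spacing ``separation``
    with unit isotropic noise; a ``mixing`` fraction of each *intermediate*
    group's cells is displaced three-quarters of the way toward an adjacent
    group (into its territory, so neighbor fractions scale directly with the
    mixing fraction).  The two pole
    groups (first and last) never mix, so at sufficient separation their kNN
    neighborhoods are mutually exclusive by construction.  Returns
    (coords, labels); used as the constellation stage's test bed, since
    embeddings are inputs to that stage rather than computed by it.
    """
    if not (0 <= mixing < 1):
        raise ValueError("mixing must lie in [0,1)")
    rng = np.random.default_rng(seed)
    coords, labels = [], []
    k = len(groups)
    for gi, g in enumerate(groups):
        pts = rng.normal(0.0, 1.0, (n_per_group, n_dims))
        pts[:, 0] += gi * separation
        if 0 < gi < k - 1 and mixing > 0:
            n_mix = int(round(mixing * n_per_group))
            side = rng.choice((-1.0, 1.0), n_mix)
            pts[:n_mix, 0] += side * 0.75 * separation
        coords.append(pts)
        labels.extend([g] * n_per_group)
    return np.vstack(coords), np.array(labels, dtype=object)


def generate_stage_signatures(
    n_nodes: int,
    set_size: int,
    persistence: float,
    n_gene_pool: int = 2000,
    stages: tuple[str, ...] = ("early", "middle", "late"),
    seed: int = 0,
) -> dict[tuple[str, str], frozenset[str]]:
    """Synthetic stage-resolved marker signatures with controlled turnover.

    For each of ``n_nodes`` signature lineages, the stage-s+1 gene set keeps a
    Binomial(set_size, persistence) subset of the stage-s set and refills to
    ``set_size`` from the pool.  Returns {(node, stage): gene set}; used to
    exercise the signature-overlap stage at a known persistence fraction.
    """
    if not (0 <= persistence <= 1):
        raise ValueError("persistence must lie in [0,1]")
    rng = np.random.default_rng(seed)
    pool = np.array([f"S{i:05d}" for i in range(n_gene_pool)], dtype=object)
    out: dict[tuple[str, str], frozenset[str]] = {}
    for j in range(n_nodes):
        node = f"node{j}"
        current = rng.choice(pool, size=set_size, replace=False)
        out[(node, stages[0])] = frozenset(current)
        for s in stages[1:]:
            keep = current[rng.random(len(current)) < persistence]
            avail = pool[~np.isin(pool, keep)]
            fresh = rng.choice(avail, size=set_size - len(keep), replace=False)
            current = np.concatenate([keep, fresh])
            out[(node, s)] = frozenset(current)
    return out
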