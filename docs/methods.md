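# Methods

This package reimplements, as tested library code, the bespoke computations
of a developing-human-neocortex arealization analysis: stringent cell QC,
recursive per-individual clustering with cross-individual merging, marker
ranking by gene score, constellation graphs with a connectivity-index
statistic, module-eigengene signature scoring, signature-overlap
quantification, and smFISH spot-to-cell quantification. Because the full
~700,000-cell primary dataset is not required (or practical) for validating
the computations, every stage is exercised on seeded synthetic data with
planted ground truth, and correctness is framed as parameter recovery plus
exact agreement with independent oracles.

## Synthetic atlas generator

`synthdata.generate_atlas` emulates a multi-individual, multi-area scRNA-seq
atlas of the second-trimester cortex. Counts are negative binomial with
mean/dispersion parameterization (variance = mu + mu^2/theta, theta =
`dispersion`, default 2.0 — the standard scRNA-seq noise model). The
log-mean of gene g in cell c is additive:

    log mu = log(baseline_g)
           + log(FC) * [g is a marker of c's cell type]
           + log(FC) * [g is an area marker of (c's type, c's area)]
           + log(FC) * rank(area)/(n_areas - 1) * [g is a gradient gene]
           + batch(individual, g)

* **Baselines** are log-normal (median `baseline_mean` = 1.5 counts, sigma 1),
  giving ~5,000 counts and ~1,300 detected genes per cell at the 2,000-gene
  default — deliberately comfortable relative to the 750-detected-gene QC
  floor, as in real data passing upstream filters. Planted markers are
  floored at baseline 1.0: they emulate the robustly detected genes used in
  validation panels.
* **Cell-type markers**: 15 per type by default. Distinct cell classes in
  real data differ by dozens of genes; 15 keeps types separable while
  remaining far sparser than reality (a conservative condition for the
  clustering stages).
* **Area markers** increase along the excitatory lineage (RG 2, IPC 5,
  neuron 10 by default), mirroring the finding that areal signatures
  strengthen as radial glia differentiate; fully configurable.
* **Gradient gene**: multiplicative ramp over the fixed rostro-caudal area
  order PFC < motor < somatosensory < parietal < temporal < V1, high at the
  V1 end — the *NR2F1*-style posterior-high/anterior-low gradient.
* **Batch**: per-individual, per-gene normal log-shift (sigma 0.2 default;
  the merge stage is additionally tested at 0.3).
* **Doublets**: a `doublet_rate` fraction of extra columns, each the
  elementwise sum of two distinct same-individual cells (no downsampling),
  drawn without regard to type so heterotypic doublets dominate and are
  detectable. Truth records both parents.
* **Mitochondrial genes**: flagged, scaled to carry ~5% of a typical
  library so the >10% filter removes only the planted/pathological tail.
* All randomness flows from a single root `SeedSequence` which spawns one
  child stream per concern (gene roles, baselines, each individual's counts,
  batch shifts), so outputs are bitwise reproducible and stable under
  changes to unrelated stages.

The **signature-sharing scenario** (flag `shared_area_signature`) applies
the late-neuron area-marker effects to RG and IPC cells of the same area,
emulating areal programs shared along the lineage. Eigengene-recovery
checks use this scenario with 20-gene neuron area signatures: with 10-gene
signatures at fold change 4 and dispersion 2, the per-gene point-biserial
correlation with the planted area indicator is ~0.53, which caps *any*
linear score at |r| ~ 0.89 — below a meaningful recovery bar — whereas
real late-neuron areal signatures contain dozens to hundreds of genes.
The 20-gene setting yields |r| ~ 0.93.

What the generator does **not** emulate: gene-gene correlation beyond the
planted programs, ambient RNA, library-size heterogeneity between cell
types, per-gene dispersion variation, and realistic marker effect-size
distributions (unknown for true areal markers). Passing recovery tests
therefore demonstrates correctness of the computations under the stated
noise model, not performance guarantees on real tissue.

`generate_mixing_coords` provides the constellation test bed: groups on a
line at spacing `separation` with unit isotropic noise; a `mixing` fraction
of each intermediate group's cells is displaced 0.75·separation into an
adjacent group's territory, so directed neighbor fractions scale directly
with `mixing`; the two pole groups are never displaced. Embeddings are
*inputs* to the constellation stage (UMAP is stochastic and out of scope),
so fixed synthetic coordinates are the appropriate fixture.

`generate_spatial` builds a laminar scene (VZ/SVZ/IZ/SP/CP bands in µm):
nuclei uniform over the tissue rectangle, per-(cell, gene) spot counts
Poisson with rate `spots_per_cell_mean × zone density` (times a shared
per-cell gamma factor, mean 1 and shape `coexpr_shape`, for genes in the
same co-expression group), Gaussian positional jitter around the owning
nucleus, gamma-distributed intensities, and uniform background spots at an
area rate. Truth maps every spot to its generating nucleus (−1 =
background).

## QC

Filters per capture lane (= individual): simulated-doublet kNN scoring
first, then thresholds, matching the narrative order of the original
workflow (the true order is unstated; it matters only for the report's
attribution of cells failing several filters). A cell is kept iff

* detected genes ≥ 750 (boundary kept: the removal rule is "< 750"),
* mitochondrial count fraction ≤ 0.10 (boundary kept: removal is "> 10%"),
* doublet score < threshold (default 0.25).

Doublet scoring is a deliberate simplification of the published
simulated-doublet approach: one synthetic doublet per observed cell (sum of
a random cell pair), joint embedding (library-size normalize to 10,000,
log1p, up to 2,000 most-variable genes, 30 PCs), and score = fraction of a
cell's 15 nearest neighbors that are synthetic. On the default atlas at
doublet rate 0.1 this attains recall 1.0 at ~4% false-positive rate; the
residual misses are homotypic doublets, which no neighborhood method
resolves.

## Preprocessing convention

Each clustering/embedding run library-size normalizes to 10,000 counts per
cell, log1p-transforms, selects the top 2,000 variable genes, and takes
PCs of the **centered but not per-gene variance-scaled** matrix (full SVD;
deterministic sign convention). With per-gene z-scaling the ~95% of genes
carrying no planted signal dominate kNN distances and per-individual
cluster recovery degrades sharply (measured ARI 0.72 scaled vs 0.98
centered-only at default conditions); centering-only PCA on log-normalized
data is a standard scRNA-seq variant and is pinned here. Defaults: 50 PCs,
k = 15 — consistent with the constellation stage's stated conventions.

## Clustering

* **kNN-Jaccard graph**: exact k nearest neighbors (ties at the k-th
  distance broken by cell index, for determinism), then an undirected edge
  for every pair with intersecting neighbor sets, weighted
  |N(i)∩N(j)|/|N(i)∪N(j)| with self excluded.
* **Louvain**: modularity maximization on that graph (networkx, seeded;
  resolution default 1.0). Community labels are renumbered by smallest
  member index so output is bitwise stable.
* **Recursion**: level 1 per individual; clusters annotated to cell types
  by a canonical marker panel (argmax over panel genes of the cluster-mean
  expression z-scored across clusters); level 2 re-embeds and re-clusters
  each (individual, cell type) with ≥ 50 cells.
* **Merging**: each level-2 cluster gets a gene-score profile (see below)
  from cluster-vs-rest DE within its individual; round 1 single-linkage
  groups clusters of the same cell type whose profiles correlate at
  r ≥ `merge_threshold` (default 0.7 — the single most consequential free
  parameter; the original threshold is unpublished); profiles are then
  recomputed from pooled cells against the full matrix and round 2 merges
  across everything. Zero-variance profiles are unmergeable and logged.
  Lowering the threshold provably never increases the cluster count
  (single linkage is monotone in the edge set).
* **Dendrograms**: average linkage on 1 − Pearson r between gene-score
  profiles; rows pre-sorted by label for deterministic tie-breaks; constant
  profiles are an error naming the offending cluster. (Average linkage is
  a choice; the original tool's linkage is not pinned in its description.)

On the default atlas (3 individuals × 3,000 cells, 2,000 genes, fold change
4) the full stack recovers the six planted types as exactly six merged
clusters at ARI ≥ 0.97, repairing the ~75-fold oversplitting of the
per-individual stage.

## Marker statistics

* **Rank-sum test**: two-sided Wilcoxon on log-normalized values. Exact
  enumeration when min(n,m) ≤ 8 *and* C(n+m, min) ≤ 2×10⁵ (the exact path
  is infeasible when the complement is large); the two-sided exact p is
  P(|U − nm/2| ≥ |u_obs − nm/2|) under uniform relabeling, which handles
  ties through midranks and yields p = 1 for symmetric data. Otherwise an
  Edgeworth-corrected approximation: the exact finite-population variance
  and fourth moment of the rank sum are computed from the observed midrank
  power sums (tie correction is implicit and exact through order 4), a
  continuity correction of half the rank lattice spacing is applied, and
  the symmetric Edgeworth kurtosis term added. At n = m = 8 on tie-free
  draws this tracks the exact p to < 6×10⁻⁴ (plain normal approximation:
  ~0.01); accuracy degrades for heavily tied tiny samples, which the exact
  path covers in practice.
* **Fields**: avg_logFC = ln(mean_in + 1) − ln(mean_out + 1) on normalized
  (pre-log) means; pct_in/pct_out = fraction of cells with raw count > 0;
  Bonferroni over all features; significant iff p_adj ≤ 0.05;
  enrichment_ratio = pct_in / max(pct_out, 0.001) (the ε floor bounds
  scores and preserves ranking when the complement never expresses);
  gene_score = avg_logFC × enrichment_ratio.
* **Stage bins**: GW 14/16/17 → early, 18/19/20 → middle, 22/25 → late;
  unsampled weeks are an error, never interpolated.
* **Area markers** are computed separately per cell type and individual,
  then unioned with the individual's stage annotated — gene specificity is
  too dynamic across development for pooled contrasts.
* **Module eigengene**: first principal component of the per-gene
  standardized log-normalized submatrix of (gene set ∩ genes expressed in
  the scored cells), cells subsampled to 10,000 with a seed, scaled to unit
  variance and sign-oriented to correlate nonnegatively with the set's mean
  standardized expression.
* **Dot-plot scaling**: per gene, mean expression over non-zero cells per
  group, z-scored across groups with the n−1 denominator (the R `scale()`
  behavior that produced the original dot plots); groups with no expressing
  cells enter as 0 and are flagged, as are zero-variance genes.

## Constellation graphs

Directed fraction f(A→B) = share of A's pooled k-neighbor slots occupied by
B cells (k = 15 in 50-PC space). This pooled-slot definition equals the
per-cell average because every cell has exactly k neighbors; a separate
`cells` mode implements the alternative reading (fraction of A's cells with
≥ 1 neighbor in B) that the figure legends suggest. Conservation holds
exactly: Σ_B≠A f(A→B) = A's out-of-group slot fraction. An undirected edge
is drawn iff f > 0.05 strictly in at least one direction; end widths are
f divided by the maximum off-diagonal fraction over all ordered pairs
(the strongest observed mixing renders at width 1). The **connectivity
index** between two node collections is (number of edges between them) ×
(mean of the threshold-passing endpoint fractions on those edges) — the
averaging population is ambiguous in the original description; averaging
over passing endpoints is the implemented default and the alternative
(per-edge means) differs only when both ends pass.

## Signature overlap

Overlap(i, j) = |genes_i ∩ genes_j| / |genes_i| — row-normalized and
deliberately asymmetric ("for each node"); symmetric Jaccard is an option.
Overlap is computed on significant up-regulated markers. Hierarchies use
Euclidean distance between overlap rows with average linkage; Sankey links
connect only consecutive stages (early→middle→late) weighted by
intersection size, zero-weight links omitted.

## smFISH quantification

Nuclei are circles (centroid + radius — the emitted "nuclear size"
supports no more); a spot's distance to a nucleus is Euclidean distance to
the centroid minus the radius, floored at 0. Each spot is assigned to the
nearest nucleus iff that distance ≤ max_dist (default 15 µm; the platform's
value is unpublished and the parameter is exposed), equidistant ties to the
lower nucleus id. The "fewer than ten counts" elimination is read as
*cells* with total assigned counts < 10 (a single spot has no "counts");
the threshold is inclusive on retention (exactly 10 stays) and
configurable. Laminar KDE is a 1-D Gaussian KDE over y (Scott bandwidth
unless given; single-spot/zero-variance inputs fall back to a minimum
bandwidth of 1% of the y-range), with the quantification scalar total
intensity / spot count; zero spots yield an explicit null, not 0.
Co-expression is Pearson on raw assigned counts (no normalization is
described for the original), self-correlations dropped, the positive
control and non-excitatory markers (POLR2A, SOX2, EOMES, DLX6) excluded,
and edges kept at r ≥ 0.05 **inclusive**; a binarized
(presence/absence) mode implements the alternative "frequency of two genes
expressed by the same cell" reading.

## Problem sizes and determinism

Default test-time problem sizes are the generator defaults: 9,000-cell
atlases for end-to-end recovery, 500 cells for exhaustive-oracle
comparisons, 1,000 draws for the rank-sum approximation band, 2,000 nuclei
for Poisson calibration — sizes at which every sampling-based assertion has
comfortable margin. Every seeded stage is bitwise reproducible run-to-run;
tests assert this on the generators, Louvain, doublet scoring and eigengene
subsampling.

## Known limitations

* The annotation step assumes the canonical marker panel distinguishes all
  planted types; ambiguous panels fall back to "unknown" only when a type's
  panel is entirely absent from the matrix.
* The Edgeworth approximation is weak for heavily tied, very small samples
  outside the exact path's reach (an uncommon regime for DE, where groups
  are large).
* Polygonal nucleus boundaries, ambient-RNA correction, adaptive QC
  thresholds, embedding-based batch integration, and RNA-velocity internals
  are intentionally out of scope.
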