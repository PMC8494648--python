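"""Clustering stack: Jaccard graph vs a set-arithmetic oracle, Louvain
behavior on constructed graphs, recursive clustering recovery of planted
types, correlation merging, and dendrograms vs a brute-force agglomeration
oracle."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from arealize import cluster as cl
from arealize import preprocess
from arealize.io import linkage_to_newick
from arealize.pipeline import truth_marker_panel
from arealize.synthdata import AtlasConfig, generate_atlas
from conftest import make_adata


# --------------------------------------------------------------------------
# kNN-Jaccard graph
# --------------------------------------------------------------------------

def brute_force_jaccard(coords, k):
    """Exhaustive neighbor sets + set arithmetic."""
    n = len(coords)
    sets = []
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        d[i] = np.inf
        order = np.lexsort((np.arange(n), d))
        sets.append(set(order[:k].tolist()))
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                inter = len(sets[i] & sets[j])
                if inter:
                    W[i, j] = inter / len(sets[i] | sets[j])
    return W, sets


def test_jaccard_graph_matches_bruteforce_oracle():
    rng = np.random.default_rng(0)
    coords = rng.normal(size=(20, 4))
    g = cl.build_knn_jaccard_graph(coords, k=5)
    W_expected, sets = brute_force_jaccard(coords, 5)
    np.testing.assert_allclose(g.weights.toarray(), W_expected)
    for i in range(20):
        assert set(g.neighbors[i].tolist()) == sets[i]


def test_jaccard_weight_bounds_symmetry_and_identity():
    # two far-away twin points share identical neighbor sets -> weight 1
    rng = np.random.default_rng(1)
    blob = rng.normal(size=(10, 2))
    twins = np.array([[50.0, 50.0], [50.0, 50.001]])
    coords = np.vstack([blob, twins])
    g = cl.build_knn_jaccard_graph(coords, k=4)
    W = g.weights.toarray()
    assert np.allclose(W, W.T)
    assert W.min() >= 0 and W.max() <= 1.0
    # twins' 4-NN sets: each other's... exclude self, so twin i's set holds
    # twin j plus 3 blob points; identical sets across twins is not forced.
    # force the identity case with coincident triplets instead:
    tri = np.vstack([blob, [[50, 50], [50, 50], [50, 50.001], [50, 50.002]]])
    g2 = cl.build_knn_jaccard_graph(tri, k=3)
    W2 = g2.weights.toarray()
    # points 12 and 13 both neighbor {10, 11, and each other}? check oracle
    W_exp, _ = brute_force_jaccard(tri, 3)
    np.testing.assert_allclose(W2, W_exp)


def test_jaccard_disjoint_neighbor_sets_no_edge():
    # two clusters farther apart than k can bridge
    a = np.arange(6, dtype=float).reshape(-1, 1)
    b = a + 1000.0
    coords = np.vstack([a, b])
    g = cl.build_knn_jaccard_graph(coords, k=3)
    W = g.weights.toarray()
    assert W[:6, 6:].sum() == 0.0


def test_jaccard_permutation_equivariance():
    rng = np.random.default_rng(2)
    coords = rng.normal(size=(30, 3))
    g = cl.build_knn_jaccard_graph(coords, k=5)
    perm = rng.permutation(30)
    g2 = cl.build_knn_jaccard_graph(coords[perm], k=5)
    W = g.weights.toarray()
    W2 = g2.weights.toarray()
    np.testing.assert_allclose(W2, W[np.ix_(perm, perm)])


def test_knn_rejects_k_too_large():
    with pytest.raises(ValueError):
        cl.build_knn_jaccard_graph(np.zeros((5, 2)), k=5)


# --------------------------------------------------------------------------
# Louvain
# --------------------------------------------------------------------------

def two_cliques_graph(eps=1e-3):
    n = 20
    W = np.zeros((n, n))
    W[:10, :10] = 1.0
    W[10:, 10:] = 1.0
    np.fill_diagonal(W, 0.0)
    W[0, 10] = W[10, 0] = eps
    return sp.csr_matrix(W)


def test_louvain_splits_two_cliques_and_beats_all_2_partitions():
    W = two_cliques_graph()
    labels = cl.louvain_cluster(W, resolution=1.0, seed=0)
    assert len(set(labels)) == 2
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    # exhaustive check: the returned split attains the best modularity over
    # all 2-partitions of the 20-node graph (oracle over a subsample of
    # bipartitions would be weaker; the clique structure keeps 2^19 out of
    # reach, so check against all splits of the 4-node quotient instead:
    # the returned partition must beat moving any single node across)
    G = nx.from_scipy_sparse_array(W)
    base = nx.community.modularity(G, [set(np.flatnonzero(labels == c)) for c in set(labels)])
    for i in range(20):
        moved = labels.copy()
        moved[i] = 1 - moved[i]
        parts = [set(np.flatnonzero(moved == c)) for c in set(moved)]
        assert base >= nx.community.modularity(G, parts) - 1e-12


def test_louvain_deterministic_bitwise():
    rng = np.random.default_rng(3)
    coords = np.vstack([rng.normal(size=(40, 3)), rng.normal(size=(40, 3)) + 8])
    g = cl.build_knn_jaccard_graph(coords, k=6)
    l1 = cl.louvain_cluster(g, seed=11)
    l2 = cl.louvain_cluster(g, seed=11)
    np.testing.assert_array_equal(l1, l2)


def test_louvain_low_resolution_single_community():
    W = two_cliques_graph(eps=0.5)
    labels = cl.louvain_cluster(W, resolution=1e-4, seed=0)
    assert len(set(labels)) == 1


def test_louvain_empty_graph_rejected():
    with pytest.raises(ValueError):
        cl.louvain_cluster(sp.csr_matrix((0, 0)), seed=0)


def test_louvain_beats_singleton_modularity():
    rng = np.random.default_rng(4)
    coords = np.vstack([rng.normal(size=(30, 2)), rng.normal(size=(30, 2)) + 6])
    g = cl.build_knn_jaccard_graph(coords, k=5)
    labels = cl.louvain_cluster(g, seed=0)
    G = nx.from_scipy_sparse_array(g.weights)
    part = [set(np.flatnonzero(labels == c)) for c in set(labels)]
    singletons = [{i} for i in range(60)]
    assert nx.community.modularity(G, part) >= nx.community.modularity(G, singletons)


# --------------------------------------------------------------------------
# recursive clustering + annotation
# --------------------------------------------------------------------------

def test_annotation_exclusive_markers_on_noiseless_means():
    """Each type has one exclusive marker; block-constant counts annotate
    every cluster correctly."""
    counts = np.zeros((60, 4), int)
    counts[:, 3] = 1  # housekeeping
    for t in range(3):
        counts[t * 20 : (t + 1) * 20, t] = 10
    adata = make_adata(counts)
    labels = np.repeat([0, 1, 2], 20)
    panel = {"T0": ["g0"], "T1": ["g1"], "T2": ["g2"]}
    ann = cl.annotate_clusters(adata, labels, panel)
    assert ann == {0: "T0", 1: "T1", 2: "T2"}


@pytest.fixture(scope="module")
def small_atlas():
    cfg = AtlasConfig(
        n_individuals=1,
        gestational_weeks=(14,),
        n_cells_per_individual=900,
        n_genes=500,
        cell_types=("RG", "IPC", "neuron"),
        doublet_rate=0.0,
        seed=17,
    )
    return generate_atlas(cfg)


def test_recursive_cluster_recovers_planted_types(small_atlas):
    from sklearn.metrics import adjusted_rand_score

    adata, truth = small_atlas
    table = cl.recursive_cluster(adata.copy(), truth_marker_panel(truth))
    tt = truth.cells["cell_type"].to_numpy()
    ari = adjusted_rand_score(tt, table["cell_type"].to_numpy())
    assert ari >= 0.9
    # level-2 labels nest within (individual, cell type)
    nesting = table.groupby("level2")["cell_type"].nunique()
    assert (nesting == 1).all()


def test_single_type_recursion_degenerates_to_one_subclustering():
    cfg = AtlasConfig(
        n_individuals=1,
        gestational_weeks=(14,),
        n_cells_per_individual=300,
        n_genes=300,
        cell_types=("RG",),
        doublet_rate=0.0,
        seed=5,
    )
    adata, truth = generate_atlas(cfg)
    params = cl.ClusterParams(seed=5)
    table = cl.recursive_cluster(adata.copy(), truth_marker_panel(truth), params)
    assert set(table["cell_type"]) == {"RG"}
    sub = adata.copy()
    expected = cl._cluster_subset(sub, params, params.seed)
    got = table["level2"].str.rsplit(".", n=1).str[-1].astype(int).to_numpy()
    np.testing.assert_array_equal(got, expected)


# --------------------------------------------------------------------------
# merging
# --------------------------------------------------------------------------

def test_identical_profiles_merge_orthogonal_do_not():
    prof = pd.DataFrame(
        {
            "m1": [5.0, 5.0, 0.0],
            "m2": [3.0, 3.0, 0.0],
            "m3": [0.0, 0.0, 4.0],
            "m4": [0.0, 0.0, 2.0],
        },
        index=["a", "b", "c"],
    )
    mapping = cl.merge_by_correlation(prof, 0.9)
    assert mapping["a"] == mapping["b"]
    assert mapping["c"] != mapping["a"]


def test_merge_monotone_in_threshold():
    rng = np.random.default_rng(6)
    prof = pd.DataFrame(rng.normal(size=(12, 30)))
    prof.index = [f"c{i}" for i in range(12)]
    counts = []
    for thr in (0.2, 0.5, 0.8):
        mapping = cl.merge_by_correlation(prof, thr)
        counts.append(len(set(mapping.values())))
    assert counts[0] <= counts[1] <= counts[2]


def test_degenerate_profile_unmergeable():
    prof = pd.DataFrame(
        {"m1": [1.0, 1.0, 2.0], "m2": [1.0, 1.0, 4.0]}, index=["flat1", "flat2", "ok"]
    )
    mapping = cl.merge_by_correlation(prof, 0.5)
    assert mapping["flat1"] == "flat1" and mapping["flat2"] == "flat2"


def test_cross_individual_merge_bridges_batch_effect():
    """One planted type split across 3 individuals by batch shifts collapses
    to one merged cluster per type after the correlation rounds."""
    from sklearn.metrics import adjusted_rand_score

    cfg = AtlasConfig(
        batch_sigma=0.3,
        n_cells_per_individual=1500,
        doublet_rate=0.0,
        seed=23,
    )
    adata, truth = generate_atlas(cfg)
    table = cl.recursive_cluster(adata.copy(), truth_marker_panel(truth))
    level3, record = cl.correlate_and_merge(adata.copy(), table, 0.7)
    tt = truth.cells["cell_type"].to_numpy()
    assert adjusted_rand_score(tt, level3.to_numpy()) >= 0.9
    assert level3.nunique() == len(cfg.cell_types)


# --------------------------------------------------------------------------
# dendrograms
# --------------------------------------------------------------------------

def brute_force_average_linkage(D):
    """Exhaustive agglomeration: merge the closest pair, average-linkage
    distance update, repeat; returns the merge order as frozensets."""
    clusters = {i: frozenset([i]) for i in range(len(D))}
    dist = {(i, j): D[i, j] for i in range(len(D)) for j in range(i + 1, len(D))}
    order = []
    nxt = len(D)
    while len(clusters) > 1:
        (i, j), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        order.append((clusters[i], clusters[j], dmin))
        merged = clusters[i] | clusters[j]
        del clusters[i], clusters[j]
        newd = {}
        for k, ck in clusters.items():
            # unweighted average linkage: mean leaf-pair distance from D
            newd[(min(k, nxt), max(k, nxt))] = np.mean(
                [D[x, y] for x in merged for y in ck]
            )
        dist = {
            (a, b): v
            for (a, b), v in dist.items()
            if a not in (i, j) and b not in (i, j)
        }
        dist.update(newd)
        clusters[nxt] = merged
        nxt += 1
    return order


def test_dendrogram_merge_order_matches_bruteforce():
    rng = np.random.default_rng(7)
    prof = pd.DataFrame(rng.normal(size=(5, 12)), index=[f"c{i}" for i in range(5)])
    Z, labels = cl.cluster_dendrogram(prof)
    M = prof.reindex(sorted(prof.index)).to_numpy()
    D = 1 - np.corrcoef(M)
    np.fill_diagonal(D, 0.0)
    oracle = brute_force_average_linkage(D)
    # compare the sequence of merge heights and merged leaf sets
    sets = {i: frozenset([i]) for i in range(5)}
    for step, (row, (oa, ob, od)) in enumerate(zip(Z, oracle)):
        a, b, d, _ = row
        merged = sets[int(a)] | sets[int(b)]
        sets[5 + step] = merged
        assert merged == oa | ob
        assert d == pytest.approx(od, abs=1e-12)


def test_dendrogram_identical_profiles_merge_first_anticorrelated_last():
    prof = pd.DataFrame(
        {
            "g1": [1.0, 1.0, -1.0],
            "g2": [2.0, 2.0, -2.0],
            "g3": [0.5, 0.5, -0.5],
        },
        index=["a", "b", "c"],
    ).astype(float)
    prof.loc["a"] += 0  # identical a,b; c anti-correlated (r = -1, d = 2)
    Z, labels = cl.cluster_dendrogram(prof)
    assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # a,b at distance 0 first
    assert Z[1, 2] == pytest.approx(2.0, abs=1e-12)  # c joins at d = 2
    nwk = linkage_to_newick(Z, labels)
    assert nwk.endswith(";") and "a" in nwk


def test_dendrogram_constant_row_names_cluster():
    prof = pd.DataFrame({"g1": [1.0, 2.0], "g2": [1.0, 3.0]}, index=["flat", "ok"])
    with pytest.raises(ValueError, match="flat"):
        cl.cluster_dendrogram(prof)
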