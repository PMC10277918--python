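"""kNN-Louvain phenotyping, MEM scores, meta-clustering, tumor groups."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from imcrecur import phenotype as ph
from imcrecur.markers import ASINH_PREFIX


def cells_from_matrix(x, markers=None, patient_id=None):
    markers = markers or [f"m{j}" for j in range(x.shape[1])]
    df = pd.DataFrame(np.asarray(x, float), columns=[ASINH_PREFIX + m for m in markers])
    if patient_id is not None:
        df["patient_id"] = patient_id
    return df, markers


def modularity_oracle(g, labels, resolution=1.0):
    """Direct modularity formula over all node pairs."""
    m2 = sum(d for _, d in g.degree(weight="weight"))
    q = 0.0
    for u, v in itertools.combinations_with_replacement(g.nodes, 2):
        if labels[u] != labels[v]:
            continue
        a = g[u][v]["weight"] if g.has_edge(u, v) else 0.0
        ku = g.degree(u, weight="weight")
        kv = g.degree(v, weight="weight")
        term = a - resolution * ku * kv / m2
        q += term if u == v else 2 * term
    return q / m2


class TestKnnGraph:
    def test_three_equidistant_points_complete_with_unit_jaccard(self):
        x = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        cells, markers = cells_from_matrix(x)
        params = ph.ClusterParams(k_neighbors=2, markers=markers, zscore=False)
        g = ph.build_knn_graph(cells, params)
        assert g.number_of_edges() == 3
        assert all(d["weight"] == pytest.approx(1.0) for _, _, d in g.edges(data=True))

    def test_weights_symmetric_and_in_unit_interval(self):
        rng = np.random.default_rng(0)
        cells, markers = cells_from_matrix(rng.normal(size=(60, 4)))
        g = ph.build_knn_graph(cells, ph.ClusterParams(k_neighbors=6, markers=markers))
        for u, v, d in g.edges(data=True):
            assert 0 < d["weight"] <= 1
            assert g[v][u]["weight"] == d["weight"]

    def test_separated_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(1)
        x = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(10, 0.1, (20, 3))])
        cells, markers = cells_from_matrix(x)
        g = ph.build_knn_graph(
            cells, ph.ClusterParams(k_neighbors=5, markers=markers, zscore=False)
        )
        cross = [(u, v) for u, v in g.edges if (u < 20) != (v < 20)]
        assert cross == []

    def test_knn_sets_match_bruteforce(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 3))
        cells, markers = cells_from_matrix(x)
        params = ph.ClusterParams(k_neighbors=4, markers=markers, zscore=False)
        g = ph.build_knn_graph(cells, params)
        d = np.linalg.norm(x[:, None] - x[None], axis=2)
        np.fill_diagonal(d, np.inf)
        for u in range(30):
            nbrs = set(np.argsort(d[u], kind="stable")[:4])
            for v in nbrs:
                assert g.has_edge(u, int(v))

    def test_k_too_large_rejected(self):
        cells, markers = cells_from_matrix(np.eye(4))
        with pytest.raises(ValueError):
            ph.build_knn_graph(cells, ph.ClusterParams(k_neighbors=4, markers=markers))


class TestLouvain:
    def test_two_disjoint_cliques_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        res = ph.louvain_communities(g, seed=0)
        assert res.n_clusters == 2
        labels = res.labels
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_modularity_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(25, 0.2, seed=4)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
        res = ph.louvain_communities(g, seed=1)
        assert res.modularity == pytest.approx(modularity_oracle(g, res.labels))

    def test_modularity_beats_singleton_partition(self):
        g = nx.karate_club_graph()
        nx.set_edge_attributes(g, 1.0, "weight")
        res = ph.louvain_communities(g, seed=0)
        singletons = [{u} for u in g.nodes]
        q0 = nx.community.modularity(g, singletons, weight="weight")
        assert res.modularity >= q0

    def test_singleton_graph(self):
        g = nx.Graph()
        g.add_node(0)
        res = ph.louvain_communities(g)
        assert res.n_clusters == 1
        assert res.modularity == 0.0

    def test_deterministic_under_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        nx.set_edge_attributes(g, 1.0, "weight")
        a = ph.louvain_communities(g, seed=7)
        b = ph.louvain_communities(g, seed=7)
        assert np.array_equal(a.labels, b.labels)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ph.louvain_communities(nx.Graph())

    def test_partition_sizes_sum_to_n(self):
        g = nx.gnp_random_graph(30, 0.2, seed=6)
        nx.set_edge_attributes(g, 1.0, "weight")
        res = ph.louvain_communities(g, seed=0)
        assert res.sizes.sum() == 30
        assert sorted(res.sizes.index) == list(range(1, res.n_clusters + 1))


class TestMEM:
    def test_null_clusters_score_near_zero(self):
        rng = np.random.default_rng(0)
        cells, markers = cells_from_matrix(rng.normal(0, 1, size=(1000, 3)))
        labels = np.repeat([1, 2], 500)
        prof = ph.mem_scores(cells, labels, markers)
        assert np.abs(prof.raw.to_numpy()).max() < 0.5

    def test_hand_computed_enrichment(self):
        """Cluster median 8, reference median 2, equal IQRs -> raw +6."""
        a = np.linspace(7.5, 8.5, 501)  # median 8, IQR 0.5
        b = np.linspace(1.5, 2.5, 501)  # median 2, IQR 0.5
        cells, markers = cells_from_matrix(np.r_[a, b][:, None])
        labels = np.repeat([1, 2], 501)
        prof = ph.mem_scores(cells, labels, markers)
        assert prof.raw.loc[1, "m0"] == pytest.approx(6.0)
        assert prof.raw.loc[1, "m0"] > 0

    def test_scaled_scores_bounded_by_ten(self):
        rng = np.random.default_rng(2)
        x = np.vstack([rng.normal(0, 1, (300, 4)), rng.normal(5, 2, (300, 4))])
        cells, markers = cells_from_matrix(x)
        prof = ph.mem_scores(cells, np.repeat([1, 2], 300), markers)
        assert np.abs(prof.scores.to_numpy()).max() == pytest.approx(10.0)
        assert (np.abs(prof.scores.to_numpy()) <= 10 + 1e-12).all()

    def test_single_cluster_rejected(self):
        cells, markers = cells_from_matrix(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            ph.mem_scores(cells, np.ones(10), markers)


def average_linkage_oracle(profiles):
    """Naive O(n^3) average-linkage agglomeration; returns merge heights."""
    clusters = {i: [i] for i in range(len(profiles))}
    d = np.linalg.norm(profiles[:, None] - profiles[None], axis=2)
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


class TestMetaCluster:
    def test_identity_when_n_meta_equals_n_clusters(self):
        profiles = pd.DataFrame(np.eye(4), index=[1, 2, 3, 4])
        mm = ph.meta_cluster(profiles, n_meta=4)
        assert mm.mapping.nunique() == 4

    def test_two_tight_groups_recovered(self):
        profiles = pd.DataFrame(
            np.vstack([np.zeros((3, 2)), np.full((3, 2), 10.0)]),
            index=range(1, 7),
        )
        mm = ph.meta_cluster(profiles, n_meta=2)
        assert mm.mapping.loc[[1, 2, 3]].nunique() == 1
        assert mm.mapping.loc[[4, 5, 6]].nunique() == 1
        assert mm.mapping.loc[1] != mm.mapping.loc[4]

    def test_average_linkage_heights_match_oracle(self):
        rng = np.random.default_rng(4)
        profiles = rng.normal(size=(5, 3))
        mm = ph.meta_cluster(pd.DataFrame(profiles, index=range(1, 6)), n_meta=2)
        got = sorted(mm.linkage[:, 2])
        assert np.allclose(got, average_linkage_oracle(profiles))

    def test_cell_counts_conserved_under_mapping(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 6, size=200)
        profiles = pd.DataFrame(rng.normal(size=(5, 3)), index=range(1, 6))
        mm = ph.meta_cluster(profiles, n_meta=3)
        meta = mm.apply(labels)
        assert len(meta) == len(labels)
        assert pd.Series(meta).value_counts().sum() == 200

    def test_n_meta_too_large_rejected(self):
        profiles = pd.DataFrame(np.eye(3), index=[1, 2, 3])
        with pytest.raises(ValueError):
            ph.meta_cluster(profiles, n_meta=4)


class TestClusterTumors:
    def _cohort(self, sep):
        rng = np.random.default_rng(6)
        frames = []
        for i in range(8):
            mu = 0.0 if i < 4 else sep
            x = rng.normal(mu, 0.3, size=(150, 3))
            df, markers = cells_from_matrix(x, patient_id=f"P{i}")
            frames.append(df)
        return pd.concat(frames, ignore_index=True), markers

    def test_two_composition_profiles_recovered(self):
        cells, markers = self._cohort(sep=5.0)
        res = ph.cluster_tumors(cells, n_groups=2, markers=markers, min_cells=10)
        truth = [0] * 4 + [1] * 4
        assert adjusted_rand_score(truth, res.groups.sort_index().to_numpy()) == 1.0

    def test_singleton_groups_when_n_groups_equals_n_patients(self):
        cells, markers = self._cohort(sep=5.0)
        res = ph.cluster_tumors(cells, n_groups=8, markers=markers, min_cells=10)
        assert res.groups.nunique() == 8

    def test_features_invariant_to_row_order(self):
        cells, markers = self._cohort(sep=2.0)
        shuffled = cells.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = ph.cluster_tumors(cells, n_groups=2, markers=markers, min_cells=10)
        b = ph.cluster_tumors(shuffled, n_groups=2, markers=markers, min_cells=10)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_low_count_patients_excluded_with_warning(self):
        cells, markers = self._cohort(sep=5.0)
        tiny, _ = cells_from_matrix(
            np.random.default_rng(8).normal(size=(20, 3)), patient_id="P_tiny"
        )
        cells = pd.concat([cells, tiny], ignore_index=True)
        with pytest.warns(UserWarning, match="excluding"):
            res = ph.cluster_tumors(cells, n_groups=2, markers=markers, min_cells=100)
        assert "P_tiny" not in res.groups.index


class TestCompareAbundance:
    def test_identical_groups_give_p_one(self):
        frac = pd.DataFrame(
            {"c1": [0.5] * 8, "c2": [0.5] * 8}, index=[f"P{i}" for i in range(8)]
        )
        frac.iloc[:, 0] = [0.1, 0.2, 0.3, 0.4] * 2
        frac.iloc[:, 1] = 1 - frac.iloc[:, 0]
        rec = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=frac.index)
        out = ph.compare_abundance(frac, rec)
        assert np.allclose(out["p_value"], 1.0)

    def test_extreme_separation_exact_p(self):
        frac = pd.DataFrame(
            {"c1": [0.9, 0.8, 0.7, 0.1, 0.2, 0.3]},
            index=[f"P{i}" for i in range(6)],
        )
        rec = pd.Series([0, 0, 0, 1, 1, 1], index=frac.index)
        out = ph.compare_abundance(frac, rec)
        assert out["U"].iloc[0] == 9
        assert out["p_value"].iloc[0] == pytest.approx(0.1)

    def test_planted_cluster_has_smallest_p(self, small_cohort):
        _, truth = small_cohort
        frac = ph.per_patient_fractions(truth.cells["patient_id"], truth.cells["phenotype"])
        rec = truth.patients.set_index("patient_id")["recurrent"]
        out = ph.compare_abundance(frac, rec).set_index("cluster")
        assert out["p_value"].idxmin() in ("epi_vim_high", "epi_vim_low")

    def test_fraction_rows_sum_to_one(self, small_cohort):
        _, truth = small_cohort
        frac = ph.per_patient_fractions(truth.cells["patient_id"], truth.cells["phenotype"])
        assert np.allclose(frac.sum(axis=1), 1.0)

    def test_single_patient_group_rejected(self):
        frac = pd.DataFrame({"c1": [0.1, 0.2, 0.3]}, index=list("abc"))
        rec = pd.Series([0, 0, 1], index=frac.index)
        with pytest.raises(ValueError):
            ph.compare_abundance(frac, rec)


class TestEndToEndPhenotyping:
    def test_pipeline_recovers_planted_phenotypes(self, small_cells_proc, small_cohort):
        """kNN-Louvain on the synthetic cohort followed by meta-clustering
        to the planted phenotype count aligns well with ground truth."""
        _, truth = small_cohort
        sub = small_cells_proc.sample(2500, random_state=0)
        res = ph.phenograph(sub, ph.ClusterParams(seed=0))
        key = list(zip(sub["image_id"], sub["cell_id"]))
        truth_labels = (
            truth.cells.set_index(["image_id", "cell_id"]).loc[key, "phenotype"].to_numpy()
        )
        ari_fine = adjusted_rand_score(truth_labels, res.labels)
        assert ari_fine > 0.5
        prof = ph.cluster_profiles(sub, res.labels)
        mm = ph.meta_cluster(prof, n_meta=8)
        meta = mm.apply(res.labels)
        assert adjusted_rand_score(truth_labels, meta) > 0.5
        assert len(meta) == len(sub)

    def test_subset_rerun_touches_only_subset_rows(self, small_cells_proc):
        epi = small_cells_proc.sample(1200, random_state=1)
        res = ph.phenograph(epi, ph.ClusterParams(k_neighbors=15, seed=0))
        assert len(res.labels) == len(epi)
        assert res.sizes.sum() == len(epi)
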