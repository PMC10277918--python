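"""Unsupervised cell phenotyping and differential abundance.

PhenoGraph-style clustering: a k-nearest-neighbor graph on scaled
arcsinh marker expression, edges reweighted by the Jaccard similarity
of neighbor sets, partitioned by Louvain modularity optimization.
Clusters are annotated with marker-enrichment-model (MEM) scores and
merged into meta clusters by hierarchical clustering of their profiles;
tumors are grouped by hierarchical clustering of patient-level
features; per-cluster abundance is compared between recurrence groups
with two-sided Mann-Whitney tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.neighbors import NearestNeighbors

from imcrecur.markers import CLUSTERING_MARKERS, asinh_cols
from imcrecur.stats_survival import mann_whitney_u

__all__ = [
    "ClusterParams",
    "ClusterResult",
    "MEMProfile",
    "MetaClusterMap",
    "TumorGroupResult",
    "build_knn_graph",
    "louvain_communities",
    "phenograph",
    "cluster_profiles",
    "mem_scores",
    "meta_cluster",
    "cluster_tumors",
    "per_patient_fractions",
    "compare_abundance",
]


@dataclass
class ClusterParams:
    k_neighbors: int = 30
    metric: str = "euclidean"
    weighting: str = "jaccard"  # or "unweighted"
    resolution: float = 1.0
    seed: int = 0
    markers: list[str] = field(default_factory=lambda: list(CLUSTERING_MARKERS))
    zscore: bool = True


def _feature_matrix(cells: pd.DataFrame, params: ClusterParams) -> np.ndarray:
    cols = asinh_cols(params.markers)
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise ValueError(f"missing transformed columns: {missing}")
    x = cells[cols].to_numpy(dtype=float)
    if params.zscore:
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    return x


def build_knn_graph(cells: pd.DataFrame, params: ClusterParams) -> nx.Graph:
    """Symmetrized kNN graph over cells (nodes = row positions).

    Neighbor sets include the cell itself; with Jaccard weighting,
    weight(u, v) = |N(u) & N(v)| / |N(u) | N(v)| over those sets, so
    weights lie in (0, 1]. Zero-weight candidate edges cannot occur
    because an edge implies a shared member.
    """
    x = _feature_matrix(cells, params)
    n = len(x)
    k = params.k_neighbors
    if k >= n:
        raise ValueError(f"k_neighbors={k} must be < number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k, metric=params.metric).fit(x)
    idx = nn.kneighbors(return_distance=False)  # self excluded by sklearn
    sets = [set(row) | {i} for i, row in enumerate(idx)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for u, row in enumerate(idx):
        for v in row:
            u_, v_ = (u, int(v)) if u < v else (int(v), u)
            if g.has_edge(u_, v_):
                continue
            if params.weighting == "jaccard":
                inter = len(sets[u_] & sets[v_])
                union = len(sets[u_] | sets[v_])
                g.add_edge(u_, v_, weight=inter / union)
            else:
                g.add_edge(u_, v_, weight=1.0)
    return g


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-cell cluster id, 1..C
    modularity: float
    sizes: pd.Series  # cluster id -> n cells

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)


def louvain_communities(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> ClusterResult:
    """Louvain partition of the weighted graph; cluster ids are assigned
    in decreasing size order (ties by smallest member node). Modularity
    of an edgeless graph is defined as 0."""
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(graph.number_of_nodes(), dtype=int)
    nodes = list(graph.nodes)
    pos = {u: i for i, u in enumerate(nodes)}
    for cid, comm in enumerate(comms, start=1):
        for u in comm:
            labels[pos[u]] = cid
    if graph.number_of_edges() == 0:
        q = 0.0
    else:
        q = nx.community.modularity(graph, comms, weight="weight", resolution=resolution)
    sizes = pd.Series({cid: len(c) for cid, c in enumerate(comms, start=1)}, name="size")
    return ClusterResult(labels=labels, modularity=float(q), sizes=sizes)


def phenograph(cells: pd.DataFrame, params: ClusterParams | None = None) -> ClusterResult:
    """kNN graph construction + Louvain in one call."""
    params = params or ClusterParams()
    g = build_knn_graph(cells, params)
    return louvain_communities(g, resolution=params.resolution, seed=params.seed)


def cluster_profiles(
    cells: pd.DataFrame, labels: np.ndarray, markers: list[str] | None = None
) -> pd.DataFrame:
    """Per-cluster median arcsinh expression (clusters x markers)."""
    markers = markers or list(CLUSTERING_MARKERS)
    df = cells[asinh_cols(markers)].copy()
    df.columns = markers
    df["cluster"] = np.asarray(labels)
    return df.groupby("cluster").median()


@dataclass
class MEMProfile:
    scores: pd.DataFrame  # clusters x markers, scaled to [-10, 10]
    raw: pd.DataFrame
    components: pd.DataFrame  # long table: MAG/IQR for population and reference


def mem_scores(
    cells: pd.DataFrame, labels: np.ndarray, markers: list[str] | None = None
) -> MEMProfile:
    """Marker enrichment model score per (cluster, marker).

    raw = sign(med_pop - med_ref) * (|med_pop - med_ref| + IQR_ref/IQR_pop - 1)
    with the reference being all cells outside the cluster; scores are
    scaled per run so the largest |raw| maps to 10. Zero IQRs are
    replaced by the smallest positive IQR observed.
    """
    markers = markers or list(CLUSTERING_MARKERS)
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size < 2:
        raise ValueError("MEM needs at least 2 clusters")
    x = cells[asinh_cols(markers)].to_numpy(dtype=float)
    raw = pd.DataFrame(index=ids, columns=markers, dtype=float)
    comp_rows = []
    iqrs = []
    stats = {}
    for cid in ids:
        pop = x[labels == cid]
        ref = x[labels != cid]
        if len(pop) < 2:
            raise ValueError(f"cluster {cid} has fewer than 2 cells")
        med_p, med_r = np.median(pop, axis=0), np.median(ref, axis=0)
        iqr_p = np.subtract(*np.percentile(pop, [75, 25], axis=0))
        iqr_r = np.subtract(*np.percentile(ref, [75, 25], axis=0))
        stats[cid] = (med_p, med_r, iqr_p, iqr_r)
        iqrs.extend([iqr_p, iqr_r])
    all_iqr = np.concatenate(iqrs)
    pos = all_iqr[all_iqr > 0]
    floor = pos.min() if pos.size else 1.0
    for cid in ids:
        med_p, med_r, iqr_p, iqr_r = stats[cid]
        if np.any(iqr_p == 0) or np.any(iqr_r == 0):
            warnings.warn(f"cluster {cid}: zero IQR replaced by {floor:g}")
        iqr_p = np.where(iqr_p == 0, floor, iqr_p)
        iqr_r = np.where(iqr_r == 0, floor, iqr_r)
        diff = med_p - med_r
        raw.loc[cid] = np.sign(diff) * (np.abs(diff) + iqr_r / iqr_p - 1.0)
        for j, m in enumerate(markers):
            comp_rows.append(
                {"cluster": cid, "marker": m, "MAG_pop": med_p[j], "MAG_ref": med_r[j],
                 "IQR_pop": iqr_p[j], "IQR_ref": iqr_r[j]}
            )
    peak = np.abs(raw.to_numpy()).max()
    scores = raw * (10.0 / peak) if peak > 0 else raw * 0.0
    return MEMProfile(scores=scores, raw=raw, components=pd.DataFrame(comp_rows))


@dataclass
class MetaClusterMap:
    mapping: pd.Series  # cluster id -> meta cluster id
    linkage: np.ndarray
    n_meta: int

    def apply(self, labels: np.ndarray) -> np.ndarray:
        return self.mapping.reindex(np.asarray(labels)).to_numpy()


def meta_cluster(
    profiles: pd.DataFrame, n_meta: int, linkage: str = "average"
) -> MetaClusterMap:
    """Merge fine clusters into meta clusters by hierarchical clustering
    of their profile vectors (Euclidean distance, given linkage)."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 clusters")
    if n_meta > len(profiles):
        raise ValueError("n_meta exceeds number of clusters")
    z = sch.linkage(profiles.to_numpy(dtype=float), method=linkage, metric="euclidean")
    flat = sch.fcluster(z, t=n_meta, criterion="maxclust")
    mapping = pd.Series(flat, index=profiles.index, name="meta_cluster")
    return MetaClusterMap(mapping=mapping, linkage=z, n_meta=int(mapping.nunique()))


@dataclass
class TumorGroupResult:
    features: pd.DataFrame  # patients x features
    groups: pd.Series  # patient -> group id (1..G, dendrogram leaf order)
    linkage: np.ndarray


def cluster_tumors(
    cells: pd.DataFrame,
    n_groups: int,
    markers: list[str] | None = None,
    meta_labels: np.ndarray | None = None,
    feature: str = "median",  # median | fractions | both
    linkage: str = "average",
    min_cells: int = 100,
) -> TumorGroupResult:
    """Group tumors by hierarchical clustering of patient-level features:
    per-marker medians of single-cell expression, meta-cluster fraction
    vectors, or both concatenated. Patients under *min_cells* cells are
    excluded with a warning. Group ids follow dendrogram leaf order."""
    markers = markers or list(CLUSTERING_MARKERS)
    counts = cells.groupby("patient_id").size()
    keep = counts[counts >= min_cells].index
    dropped = counts.index.difference(keep)
    if len(dropped):
        warnings.warn(f"excluding patients with < {min_cells} cells: {list(dropped)}")
    sub = cells[cells["patient_id"].isin(keep)]
    if sub["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    parts = []
    if feature in ("median", "both"):
        med = sub.groupby("patient_id")[asinh_cols(markers)].median()
        med.columns = [f"median_{m}" for m in markers]
        parts.append(med)
    if feature in ("fractions", "both"):
        if meta_labels is None:
            raise ValueError("fractions feature needs meta_labels")
        lab = pd.Series(np.asarray(meta_labels), index=cells.index).loc[sub.index]
        frac = per_patient_fractions(sub["patient_id"], lab)
        frac.columns = [f"frac_{c}" for c in frac.columns]
        parts.append(frac)
    if not parts:
        raise ValueError(f"unknown feature spec {feature!r}")
    feats = pd.concat(parts, axis=1).sort_index()
    z = sch.linkage(feats.to_numpy(dtype=float), method=linkage, metric="euclidean")
    flat = sch.fcluster(z, t=n_groups, criterion="maxclust")
    # relabel groups by first appearance in dendrogram leaf order
    leaf_order = sch.leaves_list(z)
    seen: dict[int, int] = {}
    for leaf in leaf_order:
        seen.setdefault(flat[leaf], len(seen) + 1)
    groups = pd.Series([seen[f] for f in flat], index=feats.index, name="tumor_group")
    return TumorGroupResult(features=feats, groups=groups, linkage=z)


def per_patient_fractions(patient_id: pd.Series, labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Patients x clusters table of composition fractions (rows sum to 1)."""
    tab = pd.crosstab(np.asarray(patient_id), np.asarray(labels))
    tab.index.name = "patient_id"
    return tab.div(tab.sum(axis=1), axis=0)


def compare_abundance(
    fractions: pd.DataFrame, recurrent: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney comparison of per-patient cluster fractions
    between non-recurrent and recurrent patients.

    *fractions*: patients x clusters; *recurrent*: 0/1 per patient.
    Returns one row per cluster with group medians, U and p. Raw
    p-values are reported (no multiple-testing correction by default,
    following common practice for per-cluster abundance screens).
    """
    recurrent = pd.Series(recurrent).reindex(fractions.index)
    if recurrent.isna().any():
        raise ValueError("recurrence status missing for some patients")
    rec = recurrent.astype(int) == 1
    if rec.sum() < 2 or (~rec).sum() < 2:
        raise ValueError("each group needs at least 2 patients")
    rows = []
    for cl in fractions.columns:
        a = fractions.loc[~rec, cl].to_numpy()  # non-recurrent
        b = fractions.loc[rec, cl].to_numpy()
        u, p = mann_whitney_u(a, b)
        rows.append(
            {
                "cluster": cl,
                "median_nonrecurrent": float(np.median(a)),
                "median_recurrent": float(np.median(b)),
                "U": u,
                "p_value": p,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
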