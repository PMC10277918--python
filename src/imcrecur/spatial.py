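"""Cell-contact neighbor graphs and neighborhood enrichment.

Two cells are neighbors when dilating one cell's pixel set by
``expansion_px`` (Euclidean disk) touches the other's pixels — the
mask-expansion rule used by single-cell image analysis toolkits.
Neighbors of a query population (e.g. epithelial cells or CD8 T cells)
are extracted per image, re-clustered PhenoGraph-style, and their
per-patient cluster fractions compared between recurrence groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import disk as disk_footprint

from imcrecur.phenotype import (
    ClusterParams,
    ClusterResult,
    compare_abundance,
    per_patient_fractions,
    phenograph,
)

__all__ = [
    "NeighborGraph",
    "NeighborhoodResult",
    "build_neighbor_graph",
    "extract_neighbors",
    "neighborhood_enrichment",
]


@dataclass
class NeighborGraph:
    """Symmetric, irreflexive cell-contact adjacency for one image."""

    edges: set  # of (a, b) tuples with a < b
    labels: set  # labels present in the mask
    expansion_px: int

    def neighbors_of(self, label: int) -> set:
        out = set()
        for a, b in self.edges:
            if a == label:
                out.add(b)
            elif b == label:
                out.add(a)
        return out

    def to_frame(self, image_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(sorted(self.edges), columns=["cell_a", "cell_b"])
        if image_id is not None:
            df.insert(0, "image_id", image_id)
        return df


def build_neighbor_graph(mask: np.ndarray, expansion_px: int = 4) -> NeighborGraph:
    """Contact adjacency: u ~ v iff some pixel of v lies within Euclidean
    distance ``expansion_px`` of a pixel of u (disk dilation)."""
    if expansion_px < 1:
        raise ValueError("expansion_px must be >= 1")
    mask = np.asarray(mask)
    foot = disk_footprint(expansion_px)
    pad = expansion_px
    edges: set[tuple[int, int]] = set()
    labels = set()
    for prop in regionprops(mask.astype(np.int64)):
        lab = prop.label
        labels.add(lab)
        r0, c0, r1, c1 = prop.bbox
        r0p, c0p = max(r0 - pad, 0), max(c0 - pad, 0)
        r1p, c1p = min(r1 + pad, mask.shape[0]), min(c1 + pad, mask.shape[1])
        crop = mask[r0p:r1p, c0p:c1p]
        dil = ndi.binary_dilation(crop == lab, structure=foot)
        touched = np.unique(crop[dil])
        for other in touched:
            if other == 0 or other == lab:
                continue
            edges.add((min(lab, int(other)), max(lab, int(other))))
    return NeighborGraph(edges=edges, labels=labels, expansion_px=expansion_px)


def extract_neighbors(
    graph: NeighborGraph, query: set, include_query: bool = False
) -> set:
    """Union of cells adjacent to any query cell; query cells themselves
    are excluded unless *include_query*."""
    query = set(query)
    if not query <= graph.labels:
        raise ValueError("query contains labels absent from the mask")
    if not query:
        warnings.warn("empty query population")
        return set()
    out: set = set()
    for a, b in graph.edges:
        if a in query:
            out.add(b)
        if b in query:
            out.add(a)
    return out if include_query else out - query


@dataclass
class NeighborhoodResult:
    query: str
    neighbor_index: pd.Index  # rows of the cell table that are neighbors
    clusters: ClusterResult
    fractions: pd.DataFrame  # patients x neighbor clusters
    tests: pd.DataFrame  # compare_abundance output


def neighborhood_enrichment(
    cells: pd.DataFrame,
    graphs: dict,  # image_id -> NeighborGraph
    query_mask: pd.Series,  # boolean per cell row: is a query cell
    recurrent: pd.Series,  # 0/1 per patient
    params: ClusterParams | None = None,
    query_name: str = "query",
) -> NeighborhoodResult:
    """Cluster the cells directly adjacent to a query population and test
    each neighbor cluster's per-patient abundance between recurrence
    groups (two-sided Mann-Whitney, flag at p < 0.05)."""
    params = params or ClusterParams()
    neighbor_rows = []
    for image_id, img in cells.groupby("image_id", sort=True):
        g = graphs.get(image_id)
        if g is None:
            continue
        q = set(img.loc[query_mask.loc[img.index], "cell_id"].astype(int))
        if not q:
            continue
        nbrs = extract_neighbors(g, q)
        sel = img[img["cell_id"].isin(nbrs)]
        neighbor_rows.append(sel.index)
    if not neighbor_rows:
        raise ValueError("no neighbor cells found for the query population")
    idx = neighbor_rows[0]
    for more in neighbor_rows[1:]:
        idx = idx.union(more)
    sub = cells.loc[idx]
    if sub["patient_id"].nunique() < 2:
        raise ValueError("all neighbor cells belong to one patient")
    res = phenograph(sub, params)
    fractions = per_patient_fractions(sub["patient_id"], res.labels)
    tests = compare_abundance(fractions, recurrent.reindex(fractions.index))
    return NeighborhoodResult(
        query=query_name,
        neighbor_index=idx,
        clusters=res,
        fractions=fractions,
        tests=tests,
    )
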