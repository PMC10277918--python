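"""Spatial neighborhoods: build mask-contact graphs, extract the cells
directly adjacent to epithelial cells and to CD8 T cells, re-cluster
each neighbor set, and test neighbor-cluster abundance between
recurrence groups.

Finds: among neighbors of CD8 T cells, the cluster matching the planted
vimentin+/ER+/PR+ epithelial phenotype differs between groups.
"""

import sys
from pathlib import Path

import pandas as pd
import tifffile

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import RESULTS, SCRATCH, SEED

from imcrecur import phenotype as ph
from imcrecur import spatial
from imcrecur.gate import apply_gates


def main():
    cells = pd.read_csv(SCRATCH / "cells_proc.csv")
    clinical = pd.read_csv(SCRATCH / "clinical.csv")
    rec = clinical.drop_duplicates("patient_id").set_index("patient_id")["recurrent"]
    graphs = {
        row.image_id: spatial.build_neighbor_graph(
            tifffile.imread(SCRATCH / "masks" / f"{row.image_id}_mask.tiff"), 4
        )
        for row in clinical.itertuples()
    }
    n_edges = sum(len(g.edges) for g in graphs.values())
    print(f"neighbor graphs: {len(graphs)} images, {n_edges} contact edges")

    labels = apply_gates(cells)
    params = ph.ClusterParams(k_neighbors=15, seed=SEED % 2**31)
    for query_name in ("epithelial", "cd8_t"):
        res = spatial.neighborhood_enrichment(
            cells, graphs, labels[query_name], rec, params, query_name=query_name
        )
        res.tests.to_csv(RESULTS / f"neighborhood_{query_name}_tests.csv", index=False)
        flagged = res.tests[res.tests["significant"]]
        print(f"\nneighbors of {query_name}: {len(res.neighbor_index)} cells, "
              f"{res.clusters.n_clusters} clusters, "
              f"{len(flagged)} flagged at p < 0.05")
        print(res.tests.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
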