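# imcrecur

A single-cell imaging-mass-cytometry (IMC) analysis pipeline for linking
epithelial cell phenotypes — in particular vimentin expression — to
recurrence in low-stage endometrial cancer. It is written for
computational biologists who have segmented multiplexed tissue images
(one intensity channel per antibody, plus an integer cell mask) and want
to go from pixels to phenotype abundance, spatial neighborhoods and
recurrence-free survival in a reproducible way.

## What the pipeline computes

Given multi-channel images, label masks, a marker panel and a clinical
table, the stages are:

1. **Quantification** (`imcrecur.quantify`) — per-cell mean intensity of
   each channel over the cell's pixels, centroid and area.
2. **Preprocessing** (`imcrecur.preprocess`) — "range" batch correction
   (per marker and acquisition batch, an affine map sends the batch's
   trimmed 1st–99th percentile intensity range onto the pooled
   reference range), then `asinh(x / 5)` transformation.
3. **Gating** (`imcrecur.gate`) — rule-based populations with per-image
   Otsu thresholds (epithelial = E-cadherin+ cytokeratin+ aSMA−;
   non-epithelial = aSMA+ E-cadherin−; CD8 T = CD8a+ CD3+; …) and the
   compartment arithmetic: immune-in-epithelium = immune total − immune
   counted in the non-epithelial compartment; stromal = non-epithelial −
   immune.
4. **Phenotyping** (`imcrecur.phenotype`) — PhenoGraph-style clustering:
   k-nearest-neighbor graph (k = 30, Euclidean, z-scaled arcsinh
   features), Jaccard edge reweighting over neighbor sets, Louvain
   modularity optimization; marker-enrichment-model (MEM) scores
   `sign(Δmed)·(|med_pop − med_ref| + IQR_ref/IQR_pop − 1)` scaled to
   ±10; hierarchical meta-clustering of cluster profiles; tumor grouping
   by hierarchical clustering of patient-level features; per-cluster
   abundance tests (two-sided Mann–Whitney) between recurrence groups.
5. **Spatial neighborhoods** (`imcrecur.spatial`) — cells are neighbors
   when their pixel sets lie within a 4-px Euclidean dilation of each
   other; the cells directly adjacent to a query population (epithelial
   cells, CD8 T cells) are extracted, re-clustered and tested for
   differential abundance.
6. **Statistics & survival** (`imcrecur.stats_survival`) — Mann–Whitney U
   (exact for small tie-free samples), Spearman, Fisher's exact,
   Kaplan–Meier with Mantel–Cox log-rank, dichotomization rules
   (median / lowest quartile / zero-vs-positive), the IHC staining index
   SI = intensity score (0–3) × positive-area score (1–3), and
   purity-based sample selection (lowest third of an infiltration
   score).

A synthetic-cohort generator (`imcrecur.synthetic_cohort`) emulates the
study design — 36 patients (17 recurrent), 1–3 images each in two
acquisition batches with a ×1.5 intensity shift, eight cell phenotypes
with log-normal 21-marker profiles, a vimentin-high epithelial phenotype
depleted by 0.15 in recurrent patients, and survival times tied to
recurrence — so every stage is testable against planted ground truth.

## Worked example

The numbered drivers under `analysis/` run the full chain on a
desk-scale synthetic cohort (36 patients, ~13,000 cells) and write their
tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # images, masks, clinical, truth
python analysis/02_quantify_cells.py
python analysis/03_preprocess.py
python analysis/04_gate_compartments.py
python analysis/05_phenotype_clusters.py
python analysis/06_spatial_neighbors.py
python analysis/07_survival_analysis.py
```

Representative output (driver 05 and 07):

```
11 fine clusters, modularity 0.840
abundance tests (non-recurrent vs recurrent):
 cluster  median_nonrecurrent  median_recurrent     U  p_value  significant
       1               0.3245            0.1562 323.0   0.0000         True
       2               0.2262            0.3875   5.0   0.0000         True
       ...
median epithelial vimentin, non-recurrent vs recurrent: U = 323, p = 3.366e-07
log-rank vimentin-low vs -high: chi2 = 31.69, p = 1.812e-08; groups {'low': '18 (17)', 'high': '18 (0)'}
```

Meta cluster 1 is the planted vimentin-high epithelial phenotype: its
per-patient fraction is higher in non-recurrent tumors (median 0.32 vs
0.16), epithelial vimentin is lower in recurrent tumors, and patients
dichotomized at the median epithelial vimentin split into a vimentin-low
group carrying essentially all recurrences — the statistical structure
the generator plants and the pipeline is designed to detect.

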