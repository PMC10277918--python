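# Methods

## Problem setting

Imaging mass cytometry measures ~20–40 antibody channels per tissue
section at ~1 µm resolution. After pixel classification and
segmentation (out of scope here — the pipeline consumes label masks),
each cell is summarized by its mean channel intensities. The analyses
this package implements ask whether the phenotype composition of a
tumor — especially vimentin expression in the epithelial compartment —
differs between patients whose low-stage endometrial tumors later
recurred and those whose did not, and whether that difference carries
over to recurrence-free survival.

## Quantification

Per-cell intensity is the *mean* of a channel over the cell's pixels
(area-invariant; the summation alternative would confound intensity
with cell size). Centroids are unweighted pixel means in 0-based
(x = column, y = row) coordinates; those conventions are used everywhere
including the spatial module. Labels need not be consecutive; every
positive label yields exactly one row.

## Batch correction and transformation

Acquisition batches (tissue cores ablated months apart) shift raw
intensities approximately multiplicatively. Correction is
quantile-anchored affine rescaling ("range" correction): per marker and
batch, the affine map that sends the batch's (q_low, q_high) = (0.01,
0.99) intensity quantiles onto the reference quantiles is applied to
all cells of the batch, with results clipped at 0. The reference is the
pooled data by default (no batch is privileged); a named reference
batch is configurable. The trimming quantiles are configurable because
no canonical values exist; 1%/99% trims outliers while anchoring the
bulk of the distribution. Correction acts on raw intensities *before*
the arcsinh transform, matching the order in which such corrections are
applied ahead of downstream tooling. A degenerate batch (equal
anchors) is left unchanged with a warning rather than dividing by zero.

The variance-stabilizing transform is `asinh(x / c)` with cofactor
c = 5, the mass-cytometry convention: linear near zero, logarithmic for
large signals.

## Gating and compartment arithmetic

Populations are defined by required-positive / required-negative marker
rules. Thresholds are resolved per image — the reproducible analogue of
setting cut-offs by eye per image — with Otsu's method on the arcsinh
values as the default policy and fixed-value or quantile policies as
overrides; a constant channel falls back to a quantile threshold with a
warning. Cells gated neither epithelial nor non-epithelial stay
unassigned (the two gates are not exhaustive by design), and the
unassigned fraction is reported.

Compartment bookkeeping follows subtraction arithmetic: immune and
proliferative cells are counted inside the non-epithelial compartment,
and the epithelial-compartment count is the population total minus that
value; stromal cells are the non-epithelial cells minus immune cells.
Threshold noise can drive derived counts negative; they are floored at
0 with a warning.

## Phenotyping

PhenoGraph-style clustering with canonical defaults: k = 30 Euclidean
nearest neighbors on per-marker z-scaled arcsinh expression (scaling
prevents high-dynamic-range markers from dominating; it can be
disabled), neighbor sets including the cell itself, Jaccard reweighting
w(u,v) = |N(u)∩N(v)| / |N(u)∪N(v)| (weights in (0,1]; an edge always
shares a member), and Louvain modularity optimization at resolution 1.0
with a fixed seed. Cluster ids are assigned in decreasing size order;
kNN ties resolve by stable row order, so reruns are bit-identical.

MEM scores annotate clusters: for cluster c and marker m, with the
reference being all cells outside c,
`raw = sign(med_c − med_ref)·(|med_c − med_ref| + IQR_ref/IQR_c − 1)`,
scaled per run so max |raw| → 10. A zero IQR is replaced by the
smallest positive IQR observed in the run (logged).

Meta clusters merge fine clusters by average-linkage hierarchical
clustering of their median arcsinh profiles, cut to a user-set count;
the number of meta clusters in any given dataset is an outcome, not a
contract. Tumor groups come from average-linkage clustering of
patient-level features — per-marker medians of single-cell expression,
meta-cluster fraction vectors, or both concatenated (all three variants
are implemented because published analyses are often ambiguous on this
point); group labels follow dendrogram leaf order, and patients under
100 cells (configurable) are excluded with a warning.

Abundance comparisons are two-sided Mann–Whitney tests on per-patient
cluster fractions between recurrence groups, reported as raw p-values;
per-cluster abundance screens conventionally report uncorrected
p-values, and a Benjamini–Hochberg option can be applied downstream by
the caller.

## Spatial neighborhoods

Two cells in an image are neighbors when dilating one cell's pixel set
by a Euclidean disk of 4 px (configurable) intersects the other's
pixels — the mask-expansion rule of interactive IMC toolkits. The
relation is symmetric, irreflexive, computed within images only, and
monotone in the expansion radius. Neighbors of a query population are
the union of adjacent cells minus the query itself (configurable), and
the neighbor set is re-clustered and tested exactly like the global
phenotyping.

## Statistics and survival

- Mann–Whitney U: exact two-sided p by enumerating the U null
  distribution when n+m ≤ 12 without ties (2·min(P(U≤u), P(U≥u)),
  capped at 1); tie-corrected normal approximation otherwise.
- Spearman correlation with average ranks; Fisher's exact test for 2×2
  tables (sum of hypergeometric probabilities ≤ the observed table's).
- Kaplan–Meier product-limit curves per group with the Mantel–Cox
  log-rank test (χ² with k−1 df); entry is primary treatment, deaths
  from other causes are censored. Group summaries follow the
  "patients (events)" legend convention.
- Dichotomization: median (the median value itself goes to the low
  group — the convention is stated because it is not universal),
  lowest quartile, or zero-vs-positive for staining-index loss.
- Staining index: SI = intensity score {0,1,2,3} × area score {1,2,3},
  codomain {0,1,2,3,4,6,9}.
- Purity selection keeps the floor(fraction·n) samples with the lowest
  stromal/immune infiltration score (lower = purer), ties broken by
  sample id; with fraction 0.33 of 254 samples this selects 83.

## Synthetic cohort generator

The generator plants the statistical structure the analysis assumes and
nothing more:

- **Design**: 36 patients, 17 recurrent; image counts 1–3 per patient
  drawn with weights 6:29:1 (matching a cohort with six single-image,
  twenty-nine two-image and one three-image tumor); the first image of
  each patient belongs to batch B1, later images to B2.
- **Phenotypes**: eight specs spanning epithelial (vimentin-high and
  vimentin-low), stromal, endothelial and four immune types, each a
  log-normal intensity profile over the 21-marker panel (positive
  markers ~30 counts, moderate ~8, background ~1.5, σ_log = 0.35).
  Log-normality is an assumption recorded in the config, not a claim
  about real data.
- **Composition**: group-level fractions are the baseline plus a
  recurrent-group shift (default −0.15 on vimentin-high epithelial,
  +0.15 on vimentin-low epithelial), renormalized; per-patient
  compositions are Dirichlet draws around the group composition with
  concentration 150, giving realistic patient-to-patient variability
  (sd ≈ 0.03–0.04 on a fraction of 0.3).
- **Batch effect**: multiplicative per marker (default ×1.5 on B2) —
  exactly the distortion a range correction can remove, which makes the
  batch-correction invariant testable.
- **Geometry**: cells are rasterized as disks (radius 3–5 px) on a
  jittered grid whose spacing guarantees disjointness and keeps
  non-contact cells > 4 px apart; a configurable fraction of cells is
  placed as surface-contact pairs (center distance r1+r2+u, u < 1 px),
  and the planted contact list is stored as ground truth. Requests that
  exceed the grid capacity raise an infeasible-geometry error. Disks
  are painted with the cell's true mean intensity, so quantification
  recovers the stored truth up to float rounding; per-pixel texture is
  deliberately absent (segmentation quality is out of scope).
- **Survival**: exponential event times for recurrent patients (median
  18 months), uniform censoring (24–120 months) for non-recurrent;
  a separate helper draws proportional-hazards times tied to a binary
  marker status for power studies (default hazard ratio 4, baseline
  median 60 months, censoring 36–96 months).
- **Determinism**: all draws derive from `SeedSequence(seed, stream
  keys)`, so identical configs give byte-identical tables and each
  patient/image stream is independent of cohort size.

What the generator does **not** emulate: tissue architecture and
texture, nuclear/membrane sub-compartments, segmentation errors,
spillover between channels, and marker correlations beyond the
phenotype means. Passing tests therefore demonstrate correctness of the
pipeline's computations and its ability to recover planted effects of
realistic size — not robustness to segmentation noise or staining
artifacts.

## Problem sizes

The default generator configuration (36 patients, 1200–2000 cells per
1024×1024 px image) is used for the statistical acceptance checks via
the fast table path (~100k cells per cohort, 50 seeds). The imaged
drivers under `analysis/` use 384×384 px images with 150–230 cells each
(~13k cells per cohort), a scale at which the whole chain — simulation,
quantification, correction, gating, clustering, neighborhoods,
survival — completes in a few minutes on one CPU; round-trip and
neighbor-oracle tests use single images at the sizes stated in the
tests.

## Known limitations

- Louvain is seed-deterministic but partition counts vary with data
  scale and k; published cluster counts are not reproduction targets.
- The exact Mann–Whitney branch requires tie-free data; fraction data
  with many zeros falls back to the asymptotic approximation.
- Otsu thresholds assume a bimodal marker distribution per image;
  markers expressed in nearly all or nearly no cells of an image can
  gate poorly, which is why fixed/quantile policies exist.
- The range correction removes multiplicative batch distortions; it
  cannot correct batch effects that change distribution shape.
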