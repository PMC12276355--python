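# routescape

Glioblastoma kills by local invasion rather than metastasis, and it invades
along distinct anatomical routes: some tumors grow as a consolidated bulk with
cells crawling along blood vessels (perivascular invasion), others infiltrate
the parenchyma and white matter as single elongated cells (diffuse invasion),
with leptomeningeal spread as a third pattern. `routescape` is a Python
library for the computational chain that links these invasion routes to
transcriptional cell states in patient-derived xenograft models:

1. **Spatial proteomics** (`routescape.imaging`) — multiplex
   immunofluorescence slides are treated as 8-channel pixel grids (DAPI,
   autofluorescence, a tumor marker, an endothelial marker, four proteins of
   interest). Channels are corrected by per-channel L2-regularized regression
   on the other channels, segmented into tumor (T) and vascular (V) masks by
   k-means (k = 5), stratified into up to nine compartments (tumor density
   classes, circle aggregates, perivascular tumor, elongated diffuse cells, a
   white-matter band class, vessels, parenchyma), and scored per protein *i*
   and compartment *j* with cellularity correction:

   score(i, j) = (1/|S_j|) · Σ_{(x,y)∈S_j} z_i(x,y) / z_DAPI(x,y)

   plus relative compartment areas, per-(protein, compartment) Welch t-tests
   between route groups, and knockout-vs-control area shifts with 90%
   t-intervals.

2. **Single-cell states** (`routescape.scstates`) — QC filters (≥ 500 genes
   per cell, genes in ≥ 10 cells, kit-specific doublet ceilings of 7200/5100
   detected genes, ≤ 30% mitochondrial counts, removal of flagged
   ribosomal/mitochondrial/hemoglobin genes), expression-bin-matched signature
   scoring, cell-cycle (S − G2M) score regression, Louvain graph clustering,
   the four-state quadrant embedding with vertical coordinate
   D = max(SC_OPC, SC_NPC) − max(SC_AC, SC_MES) and horizontal coordinate
   sign(·)·log2(|Δ|+1) of the within-half score difference, a Pearson
   chi-square test of state × route independence with standardized residuals,
   Wilcoxon differential expression with Benjamini–Hochberg adjustment, and
   shortlisting of route regulators at padj < 0.01 and |log2FC| > 0.5.

3. **Regulatory landscape** (`routescape.landscape`) — per-sample regulator ×
   gene-module coefficient tables (the output shape of a regulatory-clustering
   method) are merged over the union of regulators, z-transformed per
   regulator row, and the module columns clustered by complete-linkage
   hierarchical clustering with Euclidean distance. Cutting the dendrogram
   yields metamodules; each metamodule's gene signature keeps genes shared by
   at least four member modules; overlap with state/route signatures is
   quantified by the Jaccard index; regulator selectivity for growth
   condition, patient, or invasion route is ranked by one-way ANOVA.

4. **Motility tracking** (`routescape.tracking`) — Laplacian-of-Gaussian blob
   detection per frame, frame-to-frame linking with a constant-velocity Kalman
   filter and gated Hungarian assignment, per-track mean speeds (µm/h),
   vessel association via a morphologically dilated endothelial mask, and a
   within-replicate bootstrap for proportions.

5. **Survival statistics** (`routescape.survival`) — Kaplan–Meier curves with
   the logrank test for mouse cohorts; for patient tissue microarrays, fixed
   per-marker intensity thresholds give per-core positive-cell fractions
   (positive cells / total nuclei) that enter a multivariate Cox
   proportional-hazards model with age, sex, and transcriptional subtype
   (classical baseline) as covariates and cluster-robust variance over
   patient id.

6. **Synthetic data** (`routescape.synthetic`) — seeded generators that plant
   the exact structure each stage assumes (spatial compartments with channel
   bleed-through, four-state expression with QC violators, metamodule block
   structure, constant-velocity particles over a vessel mask, survival times
   with planted log-hazards) and emit the ground truth next to the data, so
   every stage is testable without downloads.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```bash
python examples/05_survival.py
```

prints (for the shipped seed):

```
logrank test between the two groups: chi2 = 12.32 (df = 1), p = 0.000449
positive-cell fractions across 240 cores: mean 0.30
Cox hazard ratio per percentage point positive: 1.021 (95% CI [1.007, 1.036], p = 0.00377)
```

The cohort was generated with a planted log-hazard of 0.02 per percentage
point of marker-positive cells (HR 1.020) and a group effect on survival; the
logrank test detects the group split and the cluster-robust Cox model
recovers the planted marker hazard from the thresholded core fractions.
Likewise `examples/01_imaging_compartments.py` shows the planted perivascular
marker scoring highest in the perivascular compartment (score 2.16 vs ≤ 0.22
elsewhere), and `examples/02_cell_states.py` shows the planted MES/OPC ↔
perivascular, AC/NPC ↔ diffuse association (χ² = 284.4, df = 6).

A thin CLI wraps the same stages:

```bash
routescape run --seed 1 --out runs/demo        # all stages, synthetic inputs
routescape tracking --seed 2 --out runs/trk    # one stage
```

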