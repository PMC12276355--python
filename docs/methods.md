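# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations behind `routescape`, in the order of the pipeline stages.

## Spatial compartment analysis

**Channel correction.** Each channel is replaced by its residual after
no-intercept ridge regression on the remaining channels, pixels as
observations: β = (XᵀX/N + λI)⁻¹ Xᵀz/N, residual clipped at zero. The penalty
λ is 0 for the DAPI and autofluorescence channels and a tuning constant for
the others; scaling the Gram matrix by the pixel count N makes λ's effect
independent of image size. The no-intercept form has two exact limits that an
intercept model lacks: λ → ∞ returns the raw channel (no correction), and an
exact duplicate of another channel is annihilated at λ = 0. A protein channel
that is *perfectly collinear* with the tumor channel is likewise annihilated
at λ = 0 — that is what the tuning constant is for; the pipeline default is
λ = 5 on the per-pixel scale, which preserves tumor/vessel contrast while
flattening shared background.

**Base segmentation.** k-means (k = 5, k-means++ init, 10 restarts, fixed
seed) on the (DAPI, AF, tumor, vessel) pixel vectors. The tumor mask T and
vascular mask V are built from the clusters dominated by the tumor and vessel
channels. Because k is fixed while the number of natural pixel populations
varies, k-means can split a homogeneous population across near-duplicate
centroids; masks therefore absorb every cluster whose centroid reaches at
least 50% of the maximal tumor (resp. vessel) centroid, assigned to whichever
relative value is larger. With well-separated clusters this reduces to taking
the single arg-max centroid. T ∩ V pixels resolve to the vessel class (the
endothelial signal is host-derived and morphologically distinct).

**Compartment labeling.** Local tumor density is the uniform box filter
(window w, default 31 px) of T. Two thresholds split T into high/medium/low
density; by default they are the 0.5 and 0.85 quantiles of the filtered
density over tumor pixels, with an absolute mode for calibrated synthetic
scenes. Elongated, diffusely invading cells are connected components *within
the low-density region* with eccentricity ≥ 0.9 and area ≥ 15 px (the area
floor keeps 2–3-pixel speckles, which have eccentricity 1 by construction,
out of the class); components mostly inside an optional anatomical band mask
get the dedicated white-matter class, giving the 9-class schema (8 classes
without a band mask). Circle-shaped aggregates are connected components with
circularity 4πA/P² ≥ 0.8 and area between 100 and 2000 px. Perivascular
tumor is any T pixel within d_pv = 10 px of V. Precedence, low to high:
density classes → elongated/band (carved out of low density only) →
aggregates → perivascular → vessel; everything else is parenchyma. All
morphology parameters are exposed in `CompartmentParams`; they are defaults,
not asserted reconstructions of any particular dataset.

**Scoring.** score(i, j) averages z_i/z_DAPI over the pixels of class j, with
z_DAPI floored at eps = 1 intensity unit so empty-DAPI pixels cannot dominate
(the formula is otherwise undefined there). Empty classes return NaN. Group
comparisons per (protein, compartment) use the two-sided Welch t-test with no
multiplicity adjustment; knockout-vs-control area shifts report the mean
difference across mouse replicates with a 90% two-sided t interval (Welch
degrees of freedom).

## Single-cell states

Counts live in an `AnnData`. QC applies, in order: ≥ 500 genes per cell,
≥ 10 cells per gene, kit-specific detected-gene ceilings (7200 for v3, 5100
for v2) against doublets, ≤ 30% mitochondrial counts, and removal of flagged
ribosomal/mitochondrial/hemoglobin genes. The order matters (the prevalence
filter changes later per-cell counts) and the report is audited against an
independently coded brute-force recount in the tests. Normalization is
library-size scaling to 10,000 counts + log1p.

Signature scores follow the expression-bin-matched control convention:
genes are ranked by mean expression into 24 bins; for each signature gene,
100 control genes are drawn from its bin (union over signature genes), and
the score is mean(signature) − mean(controls), deterministic given the seed.
Cell-cycle correction computes S and G2M scores this way and regresses every
gene (with intercept) on the difference S − G2M, keeping residuals plus gene
means; a constant difference skips the regression. Clustering is PCA → kNN
graph → Louvain community detection with multilevel refinement
(igraph `community_multilevel`), resolution exposed.

The quadrant embedding takes the four state scores per cell:
D = max(SC_OPC, SC_NPC) − max(SC_AC, SC_MES) is the vertical coordinate; the
horizontal coordinate is sign(SC_NPC − SC_OPC)·log2(|SC_NPC − SC_OPC|+1) in
the upper half and the MES/AC analogue in the lower half. Quadrants:
upper-left OPC, upper-right NPC, lower-left AC, lower-right MES. Exact ties
(x = 0 or y = 0) break toward the lower-left and are flagged; the embedding
is invariant under adding a constant to all four scores of a cell.

State-route association is the Pearson chi-square test of independence on the
state × route contingency table (df = (r−1)(c−1); a 4-state × 3-route table
has df = 6), with standardized residuals
(O − E)/√(E(1 − p_row)(1 − p_col)) for mosaic shading. Differential
expression is the two-sided Wilcoxon rank-sum per gene with log2 fold change
of group means (pseudocount 1) and Benjamini–Hochberg adjustment; MA
coordinates are (log2 total gene count, log2FC). Route-regulator shortlists
intersect a regulator list with rows at padj < 0.01 and |log2FC| > 0.5.

## Regulatory landscape

The merge takes the union of regulators over samples (absent entries 0),
concatenates module columns with sample-prefixed ids, and z-transforms each
regulator row to mean 0 / unit population SD across modules (constant rows
stay 0). Row-wise z-transformation was chosen to make regulators comparable
across samples before column clustering; one-way ANOVA F statistics are
invariant to it, so the raw-vs-z ambiguity has no effect on selectivity
rankings. Modules are clustered by complete linkage with Euclidean distance;
the dendrogram is cut either at a height or to a target metamodule count
(both exposed — the height of 36 that yields 13 metamodules in the motivating
dataset is data-specific, not a constant). Metamodule signatures keep genes
present in ≥ 4 member modules. Route signatures, where needed, are fitted by
one-vs-rest differential expression (top 50 genes by log2FC at padj < 0.01);
this recipe is a reconstruction and is exposed as parameters. Regulator
selectivity per factor is a per-regulator one-way ANOVA of module
coefficients across factor levels, two-sided and unadjusted; constant
regulators are reported as missing.

## Motility tracking

Detection is Laplacian-of-Gaussian blob detection on the tumor channel.
Linking runs a constant-velocity Kalman filter per track (state x, y, vx,
vy; velocity initialized at 0 with large variance) with measurement noise R =
σ_m²I (σ_m² = 1 px²) and process noise Q = q·diag(0.25, 0.25, 1, 1)
(q = 0.01); per frame, predictions and detections are matched by
minimum-total-distance bipartite (Hungarian) assignment gated at 15 px,
unmatched detections seed new tracks, and tracks unmatched for more than
`max_gap` frames terminate. Stored positions are the measured, not filtered,
coordinates, so noiseless scenes are recovered exactly. Track speed is the
mean over consecutive-detection displacements × pixel size / elapsed time
(µm/h); single-detection tracks are undefined. The original slice-assay
classifier for vessel association is a neural network; this package instead
applies the co-culture rule everywhere — a cell is vessel-associated iff its
center lies in the endothelial mask dilated by a disk of radius 5 px
(configurable) — a deliberate substitution that keeps the readout fully
specified. Proportions are bootstrapped by resampling cells with replacement
within replicates; the difference p-value uses the sign-flipped centered
bootstrap difference distribution.

## Survival statistics

Kaplan–Meier estimates and the standard logrank test (ties by the aggregated
risk-set formula) compare groups; df = groups − 1, and the implementation is
checked against a hand-tabulated risk-set oracle. TMA scoring counts nuclei
at or above a fixed per-marker threshold, one threshold per marker across the
whole set; the per-core fraction is positives / total nuclei. The Cox model
uses the fraction on the *percentage* scale (0–100) so hazard ratios are per
percentage point — consistent with HRs of ≈ 1.01–1.02 per unit; per-proportion
scaling would imply implausible magnitudes. Covariates are age, sex, and
transcriptional subtype (classical baseline); variance is cluster-robust over
patient id since each patient contributes several cores. Phenotype
concordance is defined as modal agreement: per phenotype, the fraction of
replicates matching the line's modal call, averaged over lines — a
reconstruction, since no formula is published for this summary.

## Synthetic generators

All generators are deterministic given their spec (including the seed) and
emit ground truth beside the data; recovery tests consume only the data and
compare only against the ground truth.

* **Slides** (`ImageScenario`, default 512×512): a dense bulk disk (density
  1.0 core to 0.6 R, 0.65 annulus to 0.85 R, 0.35 rim to R, stippled), gently
  curved vessel polylines (185 unit steps, stroke width 5 px, one per
  horizontal sub-band so perivascular collars do not overlap), perivascular
  tumor stippled at density 0.8 within 10 px of vessels, 12 circle aggregates
  (r = 8 px), 40 elongated ellipses (9 × 2.5 px) plus scattered round cells
  in free parenchyma, and 25 horizontal ellipses in a white-matter band.
  Channels: DAPI cellularity, a horizontal AF gradient, tumor 1.8·T, vessel
  2.0·V, and four marker channels concentrated in perivascular / diffuse /
  bulk / all tumor pixels. Observed = mixing matrix (identity + 0.04 bleed)
  × signals + clipped N(0, 0.05). Ground-truth labels come from the labeling
  rule engine applied to the clean masks with thresholds set midway between
  the planted densities (so box-filter transitions cross at the geometric
  boundaries); the analytic area budget is plain shape geometry and matches
  the labels to well under 2% of the frame. Not modeled: optics (PSF,
  spectral autofluorescence), staining artifacts.
* **Cells** (`StatePopulationSpec`, default 1000 cells / 2000 genes):
  negative-binomial counts (dispersion 2) around log-normal per-gene baselines
  (median 0.6), the four disjoint 50-gene state signatures upshifted 4-fold in
  their state's cells; `noise="none"` emits rounded expected counts for
  pure-state tests. QC violators each break exactly one rule: low-coverage
  cells (5% library scale), doublets (detected-gene count forced just above
  the kit ceiling), mitochondrial outliers (mito counts set 1.5× above the
  30% boundary); five always-absent genes violate the prevalence rule. Routes
  are drawn per cell from state-conditional profiles (MES/OPC → perivascular,
  AC/NPC → diffuse, uniform leptomeningeal). Not modeled: batch effects,
  ambient RNA, realistic transcriptome-wide correlation.
* **Landscapes** (`LandscapeSpec`, 6 samples × 20 modules, 40 regulators,
  3 metamodules): modules cycle through metamodules; each metamodule has 8
  driver regulators elevated by 2.5 over N(0, 0.3) noise — strong enough that
  the planted partition, not the selectivity shifts, dominates the column
  clustering — and a 60-gene pool from which each member module samples 30
  genes (so pool genes recur in ≥ 4 members). Route-selective regulators are
  shifted by 0.8 in perivascular-route modules. The null calibration scenario
  sets *all* planted effects (drivers and selectivity) to zero, leaving pure
  Gaussian noise where the F test is exact.
* **Movies** (`MotionSpec`, 20 particles × 50 frames, 256² px, 0.5 h/frame,
  2 µm/px): straight constant-velocity paths with speeds uniform in 5–18 µm/h,
  placed by rejection so the whole path stays in frame and (for free cells)
  off the dilated vessel mask; vessel-bound cells start on the mask and move
  along it. Optional jitter and detection dropout.
* **Cohorts** (`SurvivalSpec`, 60 subjects × 2 cores): exponential event
  times with hazard λ₀·exp(β_g·group + β_m·fraction_pct), per-subject marker
  fractions uniform in 10–50%, exact planted positive counts per core with
  bimodal nucleus intensities (modes 1.0/4.0, SD 0.4 — >4 SD apart, so the
  midpoint threshold misclassifies essentially nothing), optional uniform
  censoring.

## Problem sizes and what the tests show

The test suite and the acceptance script run the recovery checks at desk
scale: one 512×512 slide, 400–1200 cells × 500–2000 genes, 120 modules,
200-seed calibration loops, 300-subject Cox cohorts. Passing them shows the
algorithms implement their stated contracts and recover planted structure
under the generators' assumptions (linear bleed, NB counts, constant
velocity, exponential hazards); it does not certify performance on real
microscopy or sequencing data, where the unmodeled features above dominate
the difficulty.

## Known limitations

* The compartment morphology parameters (box window, density quantiles,
  d_pv, circularity/eccentricity/area cut-offs) are exposed defaults chosen
  for plausibility, not published values.
* Reciprocal-PCA batch integration, UMAP layouts and atlas projection are out
  of scope (visualization/reference mapping); clustering operates on the
  unintegrated matrix.
* The regulatory-clustering fit that produces the per-sample tables is
  consumed, not reimplemented.
* The Kalman linker assumes near-constant velocity between frames; highly
  erratic motion would need a larger gate or process noise.
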