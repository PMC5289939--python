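# Methods

This note documents the models, conventions and design choices behind
`yapscreen`, in the order the pipeline runs them.

## Image geometry and segmentation

All areas are in px² and intensities in camera counts; the nominal pixel
size is 0.64 µm at 20× and is carried through as metadata only (no
feature is expressed in physical units).

**Nuclei** are detected on the DNA channel by Gaussian smoothing
(`smooth_sigma_nuclei`, default 2 px), Otsu thresholding, and a
distance-transform watershed to split touching nuclei. Every final
nucleus is eroded by one pixel with a 3×3 (8-connected) structuring
element — the stored "nucleus region" — and objects under
`min_nucleus_area` (default 40 px²) are dropped. An all-flat image yields
an empty labeling, not an error.

**Cell bodies** are segmented in two watershed steps: bright "cell cores"
on the smoothed YAP channel seeded by the nuclei, then a second watershed
over the full foreground on the actin channel (cell boundaries are actin
ridges) seeded by the cores. The foreground is an Otsu mask of the summed
smoothed YAP+actin channels, with a guard for near-confluent fields: if
the would-be background class is not genuinely dark (mean above 30% of
the foreground mean) the whole frame is treated as foreground, since an
Otsu split then lies within the cell intensities rather than between
background and signal. A nucleus falling entirely outside the intensity
foreground keeps its eroded nucleus region as its "cell" and is flagged.

**The perinuclear ring** is the set of pixels whose Chebyshev distance
from the stored (post-erosion) nucleus region lies in [2, 7], clipped to
the cell and excluding all nuclei. Chebyshev was chosen because the band
is then exactly what 2–7 iterations of 1-px dilation with a 3×3 square
sweep out, which keeps the brute-force oracle used in the tests simple
and exact. Whether the band should instead be measured from the
pre-erosion border is genuinely open; the post-erosion convention is the
default and the band limits are configurable. Cells whose ring comes out
empty are flagged and excluded downstream.

**Protrusions**: per cell, the cytoplasm (cell minus nucleus) is split at
0.75× its mean YAP intensity. The core is the union of at-or-above-
threshold components adjacent to the nucleus (all adjacent components are
kept, so no core is orphaned; if none touches the nucleus the largest
component is used). Everything else in the cytoplasm is protrusive.
`proA` is the protrusion pixel count; `proX` is the fraction of the
core's outer border (4-connected, excluding the nucleus-facing side) in
contact with protrusion pixels. Cells with under 10 cytoplasm pixels are
degenerate: `proA = proX = 0`, flagged.

Connectivity conventions throughout: 8-connected objects, 4-connected
borders, 0-based indexing.

## Features

* `yap_ratio = log10(nuc_mean / ring_mean)`; antisymmetric under swapping
  the compartments and invariant to a common intensity scale. Undefined
  (error carrying the cell id) when either mean is non-positive.
* `NF`: border pixels of a cell are those with a 4-neighbour of a
  different value (background and out-of-frame count as different); `NF`
  is the fraction of them with a 4-neighbour in another cell. Shared
  borders are counted consistently for both neighbours.
* `LCD = 1e5 / (Voronoi area in px²)`. The Voronoi tessellation of the
  nucleus centroids is clipped to the frame exactly by reflecting every
  seed across the four frame edges before tessellating (with a
  pixel-counting fallback for degenerate seed sets). The 1e5 scale is a
  package constant chosen so confluent monolayers of the synthetic
  default geometry land in the tens, keeping thresholds like "LCD < 50"
  meaningful; only ratios of LCD matter to the model. Cells whose
  centroid is within 30 px of the frame border are flagged `border`
  (their free area is frame-truncated) and excluded from model fitting.
* "Percent protrusion", used in QC, is `proA / cellA`.
* Missing or undefined features propagate as absent values and exclude
  the cell from fitting; they are never silently zeroed.

**QC** assigns flags (`mitotic`, `dead_or_missegmented`, `border`,
`empty_ring`) and never deletes rows. The screen this design follows
tuned its thresholds per plate and did not publish them; the defaults
here are package constants sized for the synthetic monolayers (e.g.
interphase nuclei under 250 px² are flagged mitotic/condensed) and every
rule is disabled by setting its threshold to ±∞. A missing threshold key
is a configuration error naming the key.

**Live-imaging double normalization**: each trace is divided by its own
t = 0 value, then by the time-matched mean of the t0-normalized control
traces, cancelling intensity drifts shared by both groups (e.g. dimming
as cells flatten). Traces with non-positive t0 are rejected by id.

## The shape model

`ShapeNormalizationModel` fits `yap_ratio` on the six features (or the
four-feature variant without the protrusion terms) by OLS via
statsmodels. Features are deliberately **not** rescaled before fitting;
standardized betas are computed post hoc as
`β_j = x_j · sd(feature_j) / sd(yap_ratio)`, so they are scale-invariant
and share the sign of their raw coefficient by construction. Rank
deficiency raises an error naming constant/collinear columns. Models are
intended to be fitted per plate (cells inherit their plate's model);
pooled fitting is a caller choice. QC- or border-flagged cells are
excluded from fitting but still receive predictions.

`subsample_stability` refits on seeded subsamples (default 10 iterations
of 500 cells per plate, without replacement) and reports per-coefficient
mean and SD. `pc1_score` z-scores the feature matrix, takes the first
singular vector's scores, and fixes the sign so PC1 correlates positively
with cell area.

The packaged `reference_mlr6()` stores a published coefficient table
verbatim for worked examples. That table pairs a negative `nucA`
coefficient with a positive standardized beta — impossible within one OLS
fit, so the beta is presumed a typo; both printed values are stored
unchanged and the object carries a note saying so. The reference model is
never used to score synthetic screens; those are always scored by a model
fitted to their own control cells.

## Screening statistics

Well summaries are means over QC-passing cells. The hit threshold is
`k_sd` (default 2) times the SD of the **control well means** of
`yap_diff`, computed across all control wells of the screen (per-plate is
possible by passing per-plate summaries). A target is called in a
direction only if the replicate rule's required count of wells (2 of 2,
or 3 of 4) exceeds the threshold strictly — ties are non-hits — and those
wells pass the corresponding total-intensity gate. The gates are
directional: wells below the −2 SD control total cannot support activator
calls (low-total cells confound low ratios), wells above +2 SD cannot
support inhibitor calls.

Standard curves regress a well-mean feature on `log(n_cells)` over
control wells (plain-linear optional); log-linear mirrors the saturating
density trends of epithelial monolayers. The normalized value is the
observed well mean minus the curve's expectation at that well's count.

Synergy: per target, the drug effect is Δ = mean `yap_diff` (drug) −
mean `yap_diff` (vehicle), with the well count covariate taken as the
mean of the paired conditions. Wild-type pairs (≥3) define a least-squares
line of Δ versus cell number; a target's synergy is its signed vertical
residual from that line.

## Synthetic data

The generator is the package's study condition, not a tuning knob.

*Feature tables* (`generate_cells`): the six features are truncated
normals tied by a per-cell latent "crowding" factor with loadings
(cellA −0.6, nucA −0.2, NF +0.6, LCD +0.7, proA −0.4, proX −0.5), which
reproduces the observed wild-type correlation signs (YAP up with area and
protrusiveness, down with contact, crowding and the nuclear/cell area
ratio). Out-of-range draws redraw their idiosyncratic part (up to 20
rounds) before clipping. Default means and dispersions describe an
MCF10A-like monolayer at 0.64 µm/px at a reference density of 500
cells/well: cellA 3000 ± 700 px², nucA 500 ± 90 px², NF 0.35 ± 0.18,
LCD 30 ± 9, proA 250 ± 140 px², proX 0.18 ± 0.10. Density coupling is a
power law per feature (exponents: cellA −0.5, nucA −0.1, NF +0.5,
LCD +1.0, proA −0.3, proX −0.3), strictly monotone in seeding density.
The YAP ratio is the supplied linear model's predictor plus a direct
offset δ and Gaussian noise (default SD 0.1054, the published residual
scale); nuclear and ring mean intensities are back-derived (ring fixed at
1000 counts — arbitrary, only ratios matter) so `log10(nuc/ring)` equals
the ratio exactly.

Because the published coefficient table's units do not reconcile with
px²-scale features (its `nucA` and `LCD` terms would each contribute
whole log units at realistic means), screens are simulated under
`default_generative_model()`: the same sign structure and residual scale,
with `nucA` and `LCD` coefficients sized to the package's feature scales
so wild-type ratios land near 0.1–0.3 log units. The published table
remains packaged verbatim for worked examples and for the coefficient-
recovery experiment, where only the regression algebra matters, not the
plausibility of the resulting ratios.

*Screens* (`generate_screen`): ≥12 control wells per plate over a ≥4-fold
density span (enforced), controls with δ = 0, "indirect" treatments
shifting feature means only, "direct" treatments carrying δ ≠ 0; ground
truth (δ, shifts) is returned for scoring tests. Replicate counts must
match the replicate rule. Per-well seeds derive deterministically from
the screen seed; identical specs are bit-reproducible.

*Rendered fields* (`render_field`): piecewise-constant plateaus — the
simplest intensity model with analytic ground truth. Cell territories are
nearest-center regions clipped to per-cell radii (abutting neighbours
meet on Voronoi boundaries), nuclei are ellipses, protrusion fixtures are
dim rectangles at a configurable fraction of the cytoplasm plateau.
Optional Gaussian blur and seeded Poisson noise are off by default, so
the ground-truth ratio identity holds to 10⁻⁶. What the renderer does
*not* emulate — texture, shading, focus drift, overlapping/3D cells,
mitotic figures — bounds what passing tests show about real images:
they validate the operators' geometry and statistics, not robustness to
real-world image artifacts.

## Problem sizes and numerics

Test and acceptance runs use desk-scale sizes chosen as the package's own
defaults: 25,000 cells for coefficient recovery (the low end of the
per-plate training sizes the design contemplates), 12 control wells of
125–500 cells for screens, 20 seeds for operating-characteristic
estimates, and rendered fields up to 448² px with ≤50 cells. OLS is
solved by statsmodels' QR path and cross-checked in tests against an
explicit normal-equations solve at 10⁻⁸; the ring construction is checked
against a brute-force Chebyshev distance oracle; Voronoi areas come from
qhull with exact frame clipping by reflection. Known limitations: no
regularized or nonlinear models (linearity is a stated assumption), no
multiple-testing control beyond the 2 SD + replicate rule, no 3D or
learned segmentation, and LCD uses nucleus centroids (not regions) as
Voronoi seeds.
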