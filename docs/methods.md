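# Methods

## Overview

`gliaquant` is organised as five computational stages — synthetic culture
generation, segmentation, morphometry, marker assays, statistics — joined
by a per-field pipeline, a CLI and numbered analysis drivers.  The
simulator is first-class code: it defines the conditions under which the
pipeline is validated, and every test that claims "recovery" compares a
measurement to the simulator's exact per-cell ground truth.

## The synthetic culture model

A field is a set of co-registered 16-bit channels over one 448×448 px
plane (one z-plane, no chromatic shift).  Cells are placed by rejection
sampling with an occupancy bitmap so that footprints keep a ≥ 3 px
clearance; geometry is sampled first and bodies are placed largest-first,
which keeps realistic densities feasible without changing any sampled
shape.  Placement fails loudly (with the attempted density) when the
grown footprints would cover more than ~55% of the field or the retry
budget is exhausted.

* **Nuclei** — disks of radius 5 ± 0.7 px, one per cell, rendered in the
  Hoechst-like channel for all cells.
* **Microglia** (a configurable fraction of cells; 25% basally) also get a
  **body**: a rotated super-ellipse `|u/a|^n + |v/b|^n ≤ 1` with n = 2.5,
  area 700 ± 150 px² and axis ratio `q = a/b` drawn from the condition's
  elongation distribution.  `q` is recorded as the cell's true elongation;
  because the super-ellipse is symmetric in both axes, the
  moment-equivalent-ellipse axis ratio of the rendered body equals `q`
  analytically, giving a closed-form target for morphometry recovery.
  Non-microglial cells (astrocytes, leptomeningeal cells) contribute
  nuclei only; an optional faint "decoy" surface texture exists for
  robustness experiments.
* **Markers** are bimodal: positive cells render the channel's foreground
  level in their compartment (nucleus disk or whole body), negative cells
  leave background — mirroring binary expressing/not-expressing readouts.
  PU.1 and the surface marker are constitutive for microglia; Ki67,
  C/EBPβ and HLA are present in configurable fractions; DAP12, CSF-1R and
  IGF-1R are constitutive with condition-dependent intensity.  Cargo is
  painted as 1.5–2.5 px puncta inside the body until ~8% of its area is
  covered, for the configured phagocytic fraction of microglia.
* **Noise**, applied last: a zero-mean multiplicative tilted-plane
  illumination gradient (±8% by default), Poisson shot noise
  (`poisson_scale` = 0.05 counts/AU) and Gaussian read noise (sd 30 AU).
  Background is 400 AU; foregrounds are 2 500–6 000 AU depending on the
  channel, i.e. single-cell SNR ≈ 10–16 at default noise.  A "high-SNR"
  preset (scale 0.5, sd 5, gradient 5%) defines the validation regime.

**Marker assignment is stratified, not binomial**: exactly
`round(f · n_microglia)` cells are positive per field.  The realized
fraction therefore equals the configured one, so fraction-recovery error
measures the assay, not sampling noise; biological spread between donors
comes from the experiment layer below.

**Determinism**: one `numpy` Generator seeded from `CultureParams.seed`
drives everything; identical parameters and seed give bit-identical pixel
arrays and ground-truth tables.

### The two presets

`vehicle` and `mcsf` encode the endpoint of a 96-hour, 25 ng/ml M-CSF
treatment.  The dividing fractions (4.2% vs 12.6%) are the reported
percentages and are used verbatim as ground-truth defaults.  All other
deltas are direction-only choices with configurable magnitudes, because no
fold-changes are printed for them: microglia fraction 0.25 → 0.40 at equal
total cell count, phagocytic fraction 0.20 → 0.50, HLA-positive fraction
0.50 → 0.25, C/EBPβ-positive fraction 0.30 → 0.60, elongation
1.6 ± 0.4 → 2.6 ± 0.6, and PU.1 / C/EBPβ / DAP12 / CSF-1R / IGF-1R
foregrounds raised ~1.5×.  The surface (CD45) channel is deliberately
unchanged between conditions.

### The experiment layer

`generate_experiment` simulates n donor cases (default 6) with both
conditions per case.  Case-level random effects are shared between a
case's two arms (cultures from one donor are split), acting on the logit
of fractions (sd 0.5, roughly matching the reported between-case SEM of
the dividing percentage), the log of intensities (sd 0.12), the log of
elongation−1 (sd 0.15) and the log of the cell count (sd 0.06); field
cell counts are Poisson around the case mean.  Wells are one per
case × condition with 4 fields each (fields-per-well is not a claim about
any particular experiment; it is configurable).  A `render=False` path
reproduces the identical cell draws without painting pixels, which is
what the 100-replicate power study uses.

## Segmentation

Thresholding is Otsu's method on the illumination-flattened channel
(division by a Gaussian-smoothed copy at σ = max(min(h,w)/8, 32) px).
Flattening makes the threshold invariant to multiplying the channel by any
positive constant.  Because Otsu always splits a histogram, an explicit
contrast guard declares the channel empty when the split separates the
classes by < 4 robust background SDs — otherwise a signal-free channel
would segment into percolating noise speckle.

Nuclei: threshold → fill holes → Euclidean distance transform (smoothed,
σ = 1) → peak seeds with minimum separation of one nuclear radius (5 px)
→ watershed → area filter [25, 500] px².  Microglia: threshold → fill
holes → 8-connected components → area filter ≥ 80 px².  Components
without an assigned nucleus are dropped at the assignment step, not
during segmentation.  Labels are relabeled 1..n in raster order, so
identical input gives identical labeling.  Coordinates are row/column,
0-based, pixel centers.

Nucleus→cell assignment is by maximal pixel overlap of the nucleus; ties
break toward the smaller cell label; zero-overlap nuclei are "unassigned"
(the non-microglial nuclei), and nucleus-free cells are flagged and
excluded from per-cell assays.

Background estimation is median / 1.4826·MAD over pixels outside the
(3 px dilated) union of all foreground masks, or over the lowest-intensity
half of pixels when no mask is supplied.

## Morphometry

Area is the pixel count.  Central second moments are accumulated as exact
integer raw moments with a single final division, so they match a
brute-force rational-arithmetic oracle bit-for-bit; the tests check this
exhaustively on all connected 4×4 masks and on random 16×16 masks.

**EFF (moment definition, default)** is the axis ratio of the
moment-equivalent ellipse after adding the 1/12 unit-pixel variance to
the diagonal — with that correction a w×h rectangle yields exactly w/h,
and a 1 px line stays finite.  A 1 px floor on the minor axis guards
degenerate masks (flagged).  The max-Feret variant (max caliper length
over the caliper breadth perpendicular to it, computed on pixel-corner
convex hulls) is available per config; each record carries the
definition used.

**Perimeter** defaults to a subpixel estimator: the 0.5-level contour of
the σ = 0.7 Gaussian-smoothed mask, simplified with Douglas–Peucker
tolerance 0.8 px.  Staircase artifacts cancel, so digitized disks of
radius 20–100 px give SF within 0.5% of 1.  The classical 4-direction
Crofton estimate underestimates square perimeters by ~5% (SF error
12–15%) and overestimates small-disk ones, which is why it is not the
default; it and a raw boundary-walk contour are retained behind
`perimeter_method` for sensitivity analysis.  Known limitation: each
sharp corner costs the subpixel estimator a fixed ≈ 0.85 px deficit, so
corner-dominated shapes below ~120 px perimeter bias SF upward by > 3%;
smooth-boundary cells in this assay's size range (areas ≥ 120 px²,
super-elliptical outlines) are unaffected, and SF values > 1 from
discretization are reported as-is and flagged, never clamped.

Border-touching labels are excluded from morphometry (truncated shapes
bias A and P) but still counted.

## Marker assays

Positivity score = (compartment mean − bg mean) / bg sd; positive iff
score > k = 3 (configurable per marker).  At default noise a true
positive sits > 20 SDs above background and a true negative's score has
spread ≈ n_px^{-1/2}, so the calls are essentially error-free — which is
what lets fraction recovery track the configured fractions to the
rounding limit.  Phagocytosis uses the cargo-area-fraction rule
(≥ 2% of the footprint above bg + 3 sd) rather than puncta counting:
simpler, robust to puncta merging, and a puncta count remains available
from the per-cell cargo table.  Intensity summaries are
background-subtracted compartment means, averaged over positive cells
for inducible markers (Ki67, C/EBPβ, HLA) and over all microglia for
constitutive ones (PU.1, DAP12, CSF-1R, IGF-1R) — expression level among
expressing cells vs population expression.  Fields with zero microglia
yield missing (not zero) fractions and drop out of aggregation.

Both microglia counts are reported: PU.1-positive nuclei and nucleated
surface-positive cells.  The HLA readout is emitted both as a count and
as a fraction of microglia; the fraction is used for condition testing
because the denominator itself rises under treatment.

## Statistics

Case value = unweighted mean over the case's fields; condition summary =
mean ± SEM (sd/√n over case means, n = cases); comparison = two-sided
Welch t-test by default, α = 0.05.  A paired test is provided because the
two arms of a case share donor-level effects, making pairing strictly
more powerful here; Welch remains the default as the more conservative
assumption-free choice.  No multiple-testing correction is applied; the
report states the number of comparisons and echoes every configurable
decision (threshold method, k, shape definitions, test type).

## What the simulation does and does not show

The generator reproduces the features the pipeline's correctness depends
on — sparse touching-free cells, bimodal marker expression, realistic
shot/read noise and shading, donor-level variability — but not ramified
processes, overlapping or border-truncated cells, debris,
autofluorescence, uneven focus, or graded (non-bimodal) marker
expression.  Passing recovery tests therefore demonstrates that the
measurement chain is unbiased and well-calibrated in the regime it
assumes, not that segmentation would be this clean on real cultures;
the thresholds (k, area filters, cargo fraction) are all exposed in the
config for tuning on real data.

## Problem sizes

Validation uses 20 high-SNR fields for segmentation recovery, ~550
pooled microglia per setting for fraction recovery, one 6 × 4 × 2
rendered experiment (≈ 4 800 nuclei) for the direction-of-effect check,
and 100 unrendered replicate experiments for the power/type-I study —
sizes chosen to put Monte-Carlo error well below every tolerance tested.
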