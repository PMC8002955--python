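# Methods

## Scope and conventions

`hemoflow` analyses grayscale time-lapse stacks (8- or 16-bit, multi-page
TIFF or lexicographically ordered single-frame files) of blood flowing in
microchannels. Coordinates are 0-based image convention: `x` = column
(rightward), `y` = row (downward); the centroid of the single pixel at
(row r, col c) is (x=c, y=r). Frame indices are 0-based in files and API.
Calibration (µm/px, s/frame) travels with the `ImageStack` and is applied
only at export, so every intermediate quantity is in pixels and frames.

Two imaging modes are handled. Fluorescence: labeled cells are bright on a
dark background. Brightfield: cells are dark on a bright background with a
bright cell-free margin at the walls. `normalize_polarity` inverts
brightfield frames so segmentation always sees bright objects.

## Preprocessing

* ROI crop restricts analysis to the channel interior.
* Median filtering uses a square odd mask (5×5 default for tracking, 3×3
  for the CFL pipeline) — it smooths the background while preserving cell
  edges. Border handling is edge replication by default; zero padding
  darkens fluorescence borders and manufactures phantom edges, but a
  `pad="zero"` switch is kept for bit-compatibility with tools that
  zero-pad. Even kernels are rejected rather than offset, keeping the
  operator symmetric.
* No illumination/flat-field correction is implemented: the synthetic
  scenes carry no illumination drift, and no standard procedure was
  adopted for real data. This is a known limitation for strongly vignetted
  recordings.

## Automatic threshold

The automatic level is the iterative intermeans fixed point: starting from
the global mean, `t <- (mean{I<=t} + mean{I>t})/2` until the update falls
below `tol` (default 0.5 intensity levels) or `max_iter` (100; `max_iter=1`
gives the single-pass variant). At convergence the level is the midpoint of
the background and object mean intensities. Boundary pixels (`I == t`)
belong to background, so binarization is strictly-greater-than; this
tie-break is part of the contract and makes results reproducible. The level
depends only on the intensity histogram. A constant image raises: no
background/object split exists. A manual level can always override the
iteration.

Sobel gradient magnitude (`sqrt(Gx^2+Gy^2)`, standard unnormalized 3×3
kernels, edge-replicated border) is computed for edge display; object
extraction operates on the binarized image because centroids of filled
components are better defined than centroids of edge rings.

## Detection and linking

Connected components are labelled at 8-connectivity by default (diagonal
touches merge, appropriate for compact cell images; 4 is available) and
measured for area, centroid (arithmetic mean of member pixels) and bounding
box. The area filter is inclusive on both bounds. The default area window
(10–500 px²) is sized for RBCs of ≈6–10 µm imaged at ≈0.5 µm/px; platelets
fall below it and white blood cells above it. Filtering is by area only —
no intensity criterion.

Linking is greedy globally-nearest-pair per frame transition: among all
(active track, current blob) pairs within the displacement gate, the
closest pair is matched first, repeatedly; distance ties break by lower
track id, then lower blob label, which makes the result invariant to the
per-frame ordering of detections. Unmatched blobs start new tracks;
unmatched tracks terminate — no gap closing, matching the philosophy of
eliminating short fragments rather than repairing them. Greedy matching is
deterministic and adequate at the low cell densities (≈12 % hematocrit)
these experiments use precisely to keep tracking unambiguous; it is not a
minimum-total-cost assignment and can differ from one in adversarial
configurations. Tracks shorter than `min_track_length` (default 10,
inclusive) are discarded.

## Trajectory statistics

MSD is the standard time-averaged form: for lag τ (frames), the mean of
squared displacements over all point pairs τ apart, scaled by pixel_size².
Dyy is the lateral dispersion coefficient convention
`Dyy(t) = <(y(t)-y(0))²> · pixel_size² / (2 t)`, averaged over tracks, with
t counted in frames from each track's start and reported in seconds.
MSD(0)=0 and all values are non-negative by construction.

## Z-projections and tonality profile

The six temporal projections (average, sum, std, median, min, max) are
per-pixel reductions along time, returned real-valued — conversion to
8-bit for display is an explicit separate rescale. Standard deviation uses
the sample (n−1) denominator to match the common ImageJ baseline, with a
population switch. Median of an even frame count is the mean of the two
central values. All six are invariant to frame order. The Z-axis profile
reports the mean ROI intensity per frame; in brightfield, high tonality
means low local hematocrit.

## Cell-free layer measurement

The pipeline: 3×3 median per frame → cell-occupancy projection →
binarization → wall-referenced scan.

The occupancy projection is the pixelwise temporal extreme in the cell
direction: minimum for brightfield (dark cells), maximum for fluorescence.
A pixel traversed by a cell in *any* frame takes the cell tonality; the
cell-free layer, never traversed, keeps the background value and shows as
the bright band along the walls. (A literal pixelwise maximum of a
brightfield stack would instead erase any core pixel left uncovered in a
single frame; the extreme-toward-cells form is the one that yields the
intended image.)

Binarization marks pixels at or below the level (brightfield) as cell
core; the level defaults to the intermeans threshold of the projection.
Wall geometry is supplied by the user as a polyline (per the workflow where
the operator selects the wall), interpolated linearly per column; automatic
wall detection is deliberately excluded. Thickness at column x is the row
distance from the wall to the first core pixel scanning inward
(downward from an upper wall, upward from a lower one). Columns with no
core pixel are reported missing (NaN), never clamped to 0 — clamping would
silently bias region means. Because the scan works on whole pixel rows the
measurement quantizes to ≈1 px; on noise-free synthetic straight channels
the recovered mean is within 1 px of truth.

Thickness is measured along image columns — a perpendicular-to-flow
approximation valid for horizontally oriented channels; near a bifurcation
apex the scan axis remains the column, a documented simplification since no
canonical scan direction exists there.

Region summaries take mean and std (n−1) of the per-column thickness over
labelled, non-overlapping column windows (the packaged `example_regions`
layout labels six equal windows A–F). `compare_methods` reports per-region
differences of means and the Spearman rank correlation over columns where
both an automatic and a manual/reference profile are measured.

## Synthetic scenes

The generators define the conditions under which the pipelines are
validated; both are bit-deterministic under a fixed seed.

**Capillary scene** (fluorescence): 640×480 px, 50 frames, 20 cells by
default, emulating a ≈100 µm capillary imaged at 100 frames/s (defaults:
0.5 µm/px, 10 ms/frame, channel between rows 140 and 340). Cells are
anisotropic Gaussian spots (σ = radius/2, radius default 8 px ≈ a RBC at
this magnification) advected by a plug or Poiseuille profile
`v(y) = v_max (1 − (2(y−y_c)/W)²)`, v_max default 4 px/frame. Gaussian
rendering produces genuine sub-pixel centroids and soft edges — exactly
what exercises the threshold and centroid estimators. Initial positions
are rejection-sampled so that no two cells approach within a merge
distance at any time during the sequence and every cell stays in frame;
each ground-truth trajectory is therefore recoverable as exactly one
full-length track, and failures indicate pipeline defects rather than
scene ambiguity. Additive Gaussian noise (σ in intensity units) is applied
after rendering, then values are clipped and quantized to 8 bits.

**CFL scene** (brightfield): 800×600 px, 200 frames, 60 cells by default,
emulating a microchannel chip imaged at 200 frames/s; walls default to
rows 150 and 450, and the true layer `cfl_true(x)` may be a constant, an
array, or a function of column. Cells here are anti-aliased opaque disks,
not Gaussians: a disk's binarized rim falls on its true geometric boundary,
so the occupancy projection reproduces the prescribed layer edge sharply,
whereas a truncated Gaussian crosses the threshold well inside its nominal
radius and would bias the recovered thickness by a sizeable fraction of
the cell radius. Each cell keeps a fixed normalized lateral coordinate
u ∈ [0,1] mapped between the column-wise layer boundaries — it follows the
boundary as a streamline would — and advects at constant speed with
wrap-around, so over 200 frames every cell sweeps every column. The u
values are stratified, with a contingent (n/10 per wall, minimum 2) pinned
at u = 0 and u = 1 at random flow phases: this guarantees the core is
filled with no bright gaps and the true layer edge is attained at every
column, making the ground truth sharp. Plug flow is the default here so
that boundary cells traverse the full span.

What the scenes do **not** emulate: cell deformation, optical point-spread
and defocus, hematocrit-dependent rheology, illumination drift, cell
overlap/occlusion (capillary scene) and a true Y-bifurcation lumen — wall
polylines can diverge and converge, but the island between branches is not
rendered. Passing recovery tests therefore demonstrates correctness of the
measurement chain under controlled conditions, not robustness to every
artefact of real microscopy.

## Validation conditions and tolerances

* Tracking recovery runs at the default scene (20 cells, 50 frames,
  640×480, Poiseuille), gate = 2× the maximum inter-frame displacement.
  Noise-free: every ground-truth position must be recovered in exactly one
  track per cell with centroid error ≤ 0.5 px. With noise σ = 5 % of the
  dynamic range: ≥ 95 % of positions with correct identity, matched within
  a 2.0 px radius (half the link gate, about a quarter cell diameter — no
  canonical radius exists for "recovered", so this package fixes one).
* CFL recovery runs at the default scene (200 frames, 800×600):
  constant 15 px truth recovered within 1 px of mean; sinusoidal truth
  10 + 5 sin(2πx/200) px with per-column RMSE ≤ 1.5 px.
* Primitive operations (projections, intermeans threshold, Sobel,
  connected components, wand selection, MSD) are checked against
  independent brute-force oracles (explicit per-pixel loops, pure-Python
  iteration, BFS flood fill, exhaustive assignment enumeration) on random
  small inputs.

Problem sizes were chosen so the whole suite runs in well under five
minutes on a single CPU with no external data.
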