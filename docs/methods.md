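# Methods

This note documents the models, numerical conventions and design
choices behind `holocyte`, and what the synthetic-data tests do and do
not demonstrate about real instrument data.

## Optical model and geometry

Frames are stored (rows, cols) = (96, 4096): rows are the short flow
axis *y*, columns the long lateral axis *x*, 0-based throughout.
Defaults describe the instrument this pipeline targets: λ = 0.640 µm,
detector pixel 0.203 µm, NA 0.4, 300 fps.  The lateral resolution uses
the Rayleigh criterion 0.61 λ/NA = 0.976 µm (the only standard
criterion consistent with the quoted value), i.e. a ~5 px spot on the
detector.

## Demodulation

The carrier is located once per acquisition, on the first frame, as the
argmax of FFT magnitude over the positive-fx half-plane with a centred
DC exclusion zone of ±8 rows × ±64 columns.  The half-plane restriction
picks one of the two conjugate sidebands deterministically; argmax ties
resolve to the lowest (row, col).  A carrier is only accepted if the
peak exceeds 10× the median spectral magnitude, otherwise the
acquisition is rejected ("no off-axis carrier found").

The 20 × 874 spectral crop is embedded so that the *peak bin* lands
exactly at the centre of the output spectrum (this removes the carrier
ramp), then inverse transformed at 48 × 2048 and 96 × 4096.  The
inverse transform is scaled by (N_out/N_in) per axis so zero-padding
preserves mean field amplitude: a unit-modulation fringe pattern
demodulates to a field of amplitude ≈ 1.  Any global scale would cancel
in the later complex division; fixing it keeps tests deterministic.

## Phase unwrapping

Wrapping maps to the half-open interval (−π, π], with −π remapped to
+π.  Residues are the sign of the closed-loop sum of wrapped
differences around each 2 × 2 plaquette, traversed counter-clockwise in
display coordinates (x right, y down): a → down → right → up → back.
A consistent orientation is essential — with mixed directions the sum
is not a loop integral and the residue theorem fails.  Note that
residue antisymmetry under ψ → −ψ holds except when a difference sits
exactly on the ±π boundary, where the half-open interval breaks the
symmetry; this is inherent to any single-interval convention.

Branch cuts use Goldstein's growing-box search with a maximum box
radius of 8 px: each unbalanced residue connects to the nearest
opposite-charge unbalanced residue within the box (Euclidean distance,
lexicographic tie-break) or to the nearest image edge, whichever the
growing box reaches first; segments are rasterized with Bresenham
lines.  The search always terminates because the edge connection is
always available.

Flood fill is breadth-first with 4-connectivity and a fixed neighbour
order (up, down, left, right) for bit-reproducibility; the seed is the
first non-cut pixel in row-major order, kept at its wrapped value.
Pixels on cuts are assigned last from an already-unwrapped neighbour
and never serve as references — except inside cut regions thicker than
one pixel, where values chain along the cut so that every pixel gets a
defined output (errors there are expected and removed downstream as
static background).  The inner loop is compiled with numba; the
algorithm is authored here, numba only compiles it.

Tiling: residues and cuts are computed on the *whole* half-resolution
frame before splitting, otherwise cut topology would differ between
neighbouring blocks and the merge would be inconsistent.  Columns are
split into 20-wide blocks starting every 16 columns (4-column
overlaps); for a 2048-column frame that is exactly 128 blocks, with the
final block clipped at the frame edge.  Blocks merge left to right: the
offset added to the right block is the mode of the 2π-rounded
difference over the overlap's non-cut pixels (ties favour the smallest
|offset|), falling back to the median over all overlap pixels, then to
0 with a logged warning.  For residue-free fields the tiled result
equals a single whole-frame flood fill up to one global 2π multiple —
this is the oracle the test suite checks against, alongside an
independent cross-check with a reliability-sorting unwrapper.

Channel walls with steps > π produce systematic unwrapping errors at
the wall columns.  These are deliberately *not* special-cased in the
unwrapper; they are persistent in time and fall to the static
background step.

## Background removal

Batches of 40 frames (trailing remnants below 5 frames merge into the
previous batch).  Three steps, in order:

1. **Temporal 2π correction**: per pixel, values deviating from the
   batch median by more than 2π are shifted by the nearest integer
   multiple of 2π.  The median is the reference because transient cells
   occupy any one pixel in only a minority of 40 frames.
2. **Row-wise cubic**: each row of each frame is fitted with a
   third-order polynomial and the fit subtracted.  One robust re-fit
   excludes pixels whose first-pass residual exceeds 0.5 rad, so cells
   do not raise the curve (the artifact this guards against — side
   lobes flanking cells — can be reproduced by disabling
   `row_fit_robust`).  Rows left with fewer than 4 usable pixels fall
   back to the all-pixel fit.
3. **Static background**: the pixel-wise temporal median of the batch
   is subtracted from every frame.  The median is used as the estimator
   of the persistent component: it keeps transient cells and removes
   walls, dust and any surviving 2π-offset regions.

## Cell detection

The cleaned half-resolution video is thresholded at 0.3 rad.  The
detection kernel is full frame height (48 px) by 24 px wide: a +1 disk
of diameter 20 px (≈ one RBC at half resolution) centred in the kernel,
and −8 bands over the 4 top and bottom edge rows.  The exact published
kernel is known only as a rendered figure; these values reproduce its
described behaviour — a centred cell scores the disk overlap, a
y-clipped cell is driven far below threshold — and all are
configurable.  The default peak threshold is half the kernel's positive
mass (a cell must cover at least half the disk).

Correlation along x is computed by FFT with zero padding (no circular
wrap) and equals the brute-force sliding dot product to 1e−6; 80-frame
batches give an 80 × 2048 correlation map.  Detections are
8-neighbourhood local maxima above threshold, accepted greedily in
descending score with a rectangular exclusion window of 5 frames ×
24 columns, which absorbs the repeated appearances of one flowing cell
without any motion tracking.  Detections near batch boundaries are
deduplicated against the previous batch's accepted peaks.

Frames whose maximum correlation *magnitude* stays below 10% of the
peak threshold are empty backgrounds.  The magnitude matters: a cell
sliver entering at the frame edge scores strongly negative and must not
qualify as a background (using the signed maximum lets partially
visible cells contaminate background crops, which imprints inverted
cell ghosts after complex division).  Each detection is assigned the
temporally nearest background frame; the pipeline also keeps the most
recent background field across batch boundaries.  Cells with no
background anywhere are skipped with a warning.

## Refocusing

Angular-spectrum propagation uses the transfer function in piston-free
(reduced) form, H = exp(i 2π d (√(1/λ² − fx² − fy²) − 1/λ)), zero on
the evanescent domain.  Subtracting the constant 1/λ removes the
plane-wave phase advance exp(i2πd/λ), which carries no imaging
information but would rotate the global phase of every refocused image
with distance; the choice is invisible to amplitude variance, round
trips, energy conservation and offset-subtracted image comparisons, and
it lets the simulator composite propagated cell fields seamlessly into
frames.

Sign convention: the stored refocus distance is the distance passed to
the propagator that *restores* focus — a cell defocused by +d carries
refocus distance −d.

The background is removed by complex division of the 96 × 96 cell crop
by the background crop.  The quotient's phase is taken on the thin-
object branch (−π/2, 3π/2]: delays below 2π need no unwrapping, and the
branch choice keeps nonnegative cell delays (up to ~4.7 rad) intact
while preserving small negative excursions from noise and diffraction
ringing.  By default the quotient is propagated once; propagating cell
and background separately and then dividing (one more FFT) is available
behind `propagate_before_divide` and agrees to < 1e−3 rad.

Autofocus minimises the population variance of |U| over 32 uniform
distances in [−24, 24] µm (grid step 48/31 ≈ 1.55 µm); in focus, a pure
phase object has minimal amplitude contrast.  Ties resolve to the
smaller |d|.  The first 128 cells of an acquisition are refocused this
way and give (x, d*) pairs for a quadratic least-squares calibration
d(x) = ax² + bx + c, with the population standard deviation of the
residuals as the spread σ.  Every subsequent cell is refocused at only
{d(x) − σ, d(x), d(x) + σ} as continuous (un-regridded) distances, and
the minimum-amplitude-variance candidate is selected — the selection
criterion is read as amplitude *variance*, the metric everything else
in the method uses.  Acquisitions that end with fewer than 128 cells
calibrate with whatever is available (minimum 3, warning below 8); the
calibration-phase cells themselves keep their exhaustive-autofocus
result.

## Morphology

Refocused images are offset-corrected by the mean of the four 8 × 8
corner blocks, thresholded (0.3 rad by default, reusing the detection
threshold since no separate value is fixed), opened with a disk
structuring element of radius 1, and reduced to the largest
4-connected component.  Measurements: A = n·dA with dA = pixel², OPL =
φλ/2π, OV = dA·Σ_mask OPL, mean OPL over the mask, eccentricity from
the eigenvalues of the second central moment matrix
(e = √(1 − λ_minor/λ_major)), and circularity 4πA/C² with C the
4-direction Crofton perimeter (robust to rasterization).  The inverted
ratio 4πC²/A — which evaluates to ≈ 158 for a perfect circle and is
not a bounded circularity — is available behind
`circularity_printed_form` for literal reproduction.  Single-pixel
masks are degenerate: eccentricity 0, circularity undefined, never
accepted.

The RBC filter bounds (area 20–90 µm², OV 10–150 µm³, eccentricity
≤ 0.8, circularity ≥ 0.7, closed intervals) are configuration defaults
bracketing healthy-RBC ranges generously, not measured values.

## Evaluation harness

The "traditional" oracle refocuses each cell exhaustively on a 0.1 µm
grid over [−24, 24] µm.  For every cell, three images are compared —
the unrefocused background-divided crop, the three-depth result, and
the fine oracle — via OV, area and mean-OPL percent errors (denominator
= the fine-refocused value), eccentricity and circularity absolute
differences, RMSE on the OPL scale (rad × λ/2π), and SSIM.  SSIM is the
*global* single-window form with population statistics, computed on
offset-subtracted phase images, with stabilising constants c₁ =
2.22 × 10⁻³ and c₂ = 2.00 × 10⁻².  (SSIM ≤ 1 always, equality iff
identical; it can be negative for anti-correlated images.)  The
population report gives mean and linear-interpolation 95th percentile
per metric, with before/after improvement factors (undefined for SSIM,
and reported as null when the after-error is exactly zero).

## Synthetic data: what it emulates, and what it does not

Frames are I = |r + s|², with reference r = A·exp(−i2π(f_y y + f_x x))
and sample s = exp(iφ).  The default carrier (0.25, 600/4096)
cycles/px places the sideband at bins (+24, +600), inside the crop
window and outside the DC exclusion zone.  φ contains: a low-order
cubic-in-x background (~1 rad) with a mild y tilt; channel-wall steps
of 4 rad (> π, deliberately triggering the unwrapping-error pathway
that the static background step must clean) at columns 150 and 3950;
and flowing cells.  Cells move 12 rows/frame along y and are vertically
centred at their `center_frame`.  Defocus follows a quadratic
focal-plane tilt d(x) = 10⁻⁶x² − 8·10⁻⁴x + 2 µm, spanning ≈ 2–15 µm
across the field of view (a tilted focal plane with the far side more
defocused); it is applied per cell by propagating the cell's 96 × 96
sub-field by d(x_center) before compositing — O(cells), not O(pixels²),
and exactly the inverse of the correction the pipeline applies.  Noise
is additive Gaussian on intensity (σ = 0.02 of the ~4-unit fringe
amplitude), clipped at 0, seeded; ground truth is recorded before
noise.

The default cell phantom is a biconcave disc of radius 4.0 µm with peak
phase 3.6 rad — the thick/high-refractive-index end of the RBC range,
chosen once so that the default phantom's optical volume (~12 µm³)
falls inside the default RBC filter window; it remains well below the
2π thin-object bound.  Profiles: uniform disk, biconcave
(φ₀(1 − 0.5 e^(−r²/0.25R²)) with a cosine taper over the outer 20% of
the radius), and spherical-cap bead.

The evaluation population generator (`make_defocused_population`)
builds 96 × 96 crops directly: cells with seeded radius/phase spread,
true defocus = tilt curve + 0.5 µm Gaussian jitter (defocus spans
≈ 2–15 µm over the field of view, consistent with the quadratic model
the calibration assumes), and a shared smooth background phase so the
complex division has something to remove.

Not emulated: camera radiometry (shot noise scaling, fixed-pattern
noise), partial coherence, optical aberrations beyond defocus, cell
tumbling or deformation in flow, overlapping cells, and refractive-
index heterogeneity inside cells.  Passing tests therefore demonstrate
the correctness of the processing chain under its stated model, not
robustness to every artifact of real acquisitions.  Band-limiting by
the 20 × 874 spectral crop is shared by simulator and pipeline, so
round-trip tests do not measure the information lost to that crop;
phantom-versus-recovered comparisons are made over cell interiors,
away from rim ringing.

## Problem sizes

The test suite uses 48 × 2048 wrapped fields (100 for the unwrapping
suite), a 150-frame/20-cell acquisition for detection, 50 cells for
autofocus recovery, 100 Monte-Carlo seeds for calibration, and 200
cells for the refocusing benchmark; `scripts/acceptance.py` uses 25
wrapped fields, a 122-frame/16-cell acquisition, and the 200-cell
benchmark.  These sizes give stable statistics (binomial noise on
recall < 1 cell; SSIM means stable to ±0.01 across seeds) while keeping
a full run on one CPU to a few minutes.

## Known limitations

* Cut-enclosed regions thicker than one pixel receive chained values
  (see unwrapping); their phases are not trustworthy and rely on the
  static background step for cleanup.
* The three-depth refinement cannot correct cells whose true defocus
  deviates from the calibrated curve by much more than one regression
  standard deviation.
* The detector of the correlation map assumes one cell per exclusion
  window; two cells closer than 24 half-resolution columns within 5
  frames merge into one detection.
* Background frames must exist within the acquisition; a continuous
  stream of cells in every frame leaves nothing to divide by, and those
  cells are skipped.
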