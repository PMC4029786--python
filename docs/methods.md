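# Methods

## Scope and coordinate conventions

`phenogrow` estimates whole-rosette area from single top-view grayscale
frames (8–16-bit PNG/TIFF; 12-bit fluorescence data in 16-bit containers)
and models the resulting area series. All rasters are `(row, col)`, 0-based,
with pixel centers at integer coordinates; a pixel belongs to a polygon when
its center lies inside it. Angles are `atan2(drow, dcol)` in degrees on
`[0, 360)`. These conventions are used identically by the synthetic
generator, the polar profile and the evaluation harness.

## Foreground mask

The mask is built from edges, not intensities: Sobel gradient magnitude,
thresholded (Otsu on the gradient by default; a relative cutoff can be
configured), dilated with a disk of radius `dilation_radius` (default 2 px),
then everything 4-connected to an image corner through non-edge pixels is
background and the rest — edge band, interior, enclosed holes — is
foreground. A global intensity threshold is deliberately avoided because
fluorescence level drifts between frames; only the corner-seed guard
consults intensities (a corner brighter than the whole-image Otsu level, or
carrying edge activity, is not a valid background seed; if some corners
remain the darkest one is used with a warning, and if none do the frame is
rejected).

Because the Sobel stencil responds one pixel beyond a step edge, the filled
region overshoots the true boundary by `dilation_radius + 1`; the mask is
eroded back by that disk (`erode_back=True`). On a noiseless disk of radius
50 px the recovered area is then within ~1% of πR² (without the erosion the
bias is ~12%). The erode-back step can be disabled, which restores the
strictly monotone growth of the mask with `dilation_radius`.

## Plant center

Rosette leaves radiate from the growing point, so the axes of a few isolated
leaves nearly intersect there. Candidate regions come from removing a
dilated edge map (raw-image Sobel+Otsu united with Canny on the σ=2
Gaussian-smoothed image) from the mask, keeping only tissue brighter than
the whole-image Otsu level, and opening with a disk of radius 2 to sever
petiole-junction spines. A region is accepted as a *simple leaf* when it has
a single closed outer contour (no holes), solidity ≥ 0.85, area within
`[100 px², 0.5 × plant area]`, and a median intensity of at least 0.93 of
the brightest candidate region — overlap zones are dimmer than single-leaf
tissue (mutual shading), so markedly dim regions are leaf complexes, not
leaves. Regions rounder than a 1.2 max/min chord ratio are kept as regions
but skipped as orientation sources, since a near-circular blade has no
stable axis.

Each accepted leaf contributes an orientation line: the boundary point pair
at maximal distance (searched on the convex hull; ties broken by the
lexicographically smallest first endpoint). The center is the closed-form
minimizer of the summed *squared* perpendicular distances to the lines. The
plain sum of distances (an L1 objective) has no closed form; an iteratively
reweighted mode (`method="l1"`) is provided, and the two coincide when the
lines are near-concurrent, which is the working regime. With fewer than two
usable leaves, or parallel lines, the center of mass is used instead. The
center is computed once per plant — by default on the frame of median
observed area — and reused for all frames, since a plant's center does not
move during a growth experiment.

## Polar profile and leaf tips

For every angular bin (default width 1°) the profile records the distance
from the center to the outermost foreground pixel, treating pixels as unit
squares (centers and corners are binned) so that wedges whose arc is
narrower than one pixel still see the boundary; empty bins are filled by
circular linear interpolation and flagged. The profile is smoothed by an
unweighted circular moving average over `k` bins (default 9, odd).

Leaf tips are the *raw* radii at local maxima of the smoothed profile —
smoothing always underestimates a tip, so the raw value is kept. Plateau
maxima yield their central bin (lower-middle for even plateaus). Maxima with
raw radius below `T_r` are discarded; the default is relative,
`T_r = 0.15 × max r`, which tracks plant size across ages and suppresses the
scalloped central region of the rosette (fused petioles and hole-filling
produce spurious small-radius maxima there), with an absolute override in
the configuration. The curvature ratio `cr = (r − r_s)/r` is computed at the
same smoothing window.

Inner leaves whose tips never reach the outer boundary are invisible to this
construction by design; the overlap correction below is what compensates for
them.

## Leaf area and overlap correction

Leaf length is defined center-to-tip, petiole included, so the tip radius is
the length. The piecewise length-to-area law (linear below the cr cutoff,
exponential at or above it; boundary values take the exponential branch)
ships with coefficients 32.9, −769.9, 513.8 px², 0.0146 px⁻¹ and cutoff
0.07. These are specific to the original imaging setup and genotype; they
are configuration values, and both the cutoff (two-component Gaussian
mixture on cr, equal-responsibility crossing, with a degenerate-fit fallback
to 0.07) and the branch coefficients (OLS for the linear branch;
log-linearized then nonlinearly refined least squares for the exponential
branch, with per-branch R² on the original scale and 95% CIs) can be refit
from training leaves. Negative linear-branch predictions clamp to zero with
a warning.

The corrected plant area is `a = a_l (1 + p_overlap)` with
`p_overlap = |a_t − a_l| / max(a_t, a_l)`; algebraically `a = 2a_l − a_t`
when `a_l > a_t` and `a = 2a_l − a_l²/a_t` otherwise, and `a` is continuous
across `a_l = a_t`. The correction strictly beats the raw top-view count
when some leaf area is hidden (missed inner tips) while the detected leaves'
areas are estimated well; when every tip is found and overlap is mutual, the
corrected and naive estimates err symmetrically in opposite directions.

## Growth model and functional analysis

The area series is fit with `A(t) = A0·Aa / (A0 + (Aa − A0)e^(−γt))` by
nonlinear least squares (initialization: A0 = first positive observation,
Aa = 1.2 × max, γ from the slope of the logit-transformed series; bounds
keep all parameters positive). 95% CIs are first-order (Jacobian) t
intervals, the standard reporting for nonlinear least squares;
non-convergence and degenerate optima raise, net-decreasing series warn and
are flagged. γ is reported in the reciprocal of whatever unit the input
time column uses (days by default). The model satisfies
`dA/dt = γA(1 − A/Aa)`, giving closed forms used throughout:

- velocity `v = γA(1 − A/Aa)`, maximal at `A = Aa/2` with value `γAa/4`;
- acceleration `a = γv(1 − 2A/Aa)`, zero at the inflection, extremal at
  `A/Aa = (3 ∓ √3)/6` with values `±γ²Aa/(6√3)` and velocity `γAa/6` there;
- phase-plane loop area `∮ a dv = ∫ a² dt = γ³Aa²/30`.

AGR and RGR are backward finite differences of the fitted curve and its log
at Δt = 0.35 days (configurable). Phase-plane features are extracted from a
dense trajectory (default 20001 points spanning A/Aa from 0.1% to 99.9%,
sampling validated so no velocity step exceeds 1% of the maximum); the loop
area is a trapezoid integral of acceleration with respect to velocity and is
cross-checked in tests against the closed form to 0.5%. Velocity is
reported non-negative everywhere, as the model implies; a sign convention
that mirrors the descending branch below zero exists in some published
phase-plane plots but is not adopted.

Replicates are screened by a two-tailed Welch t-test of each replicate's
per-timepoint areas against the pooled areas of the rest (flag at p < 0.05).
With very few replicates an extreme outlier also contaminates the
leave-one-out pool of its neighbours, so flags should be reviewed rather
than applied blindly. Genotype summaries average per-replicate phase-plane
extrema by default (`mode="per_replicate"`); averaging the curves first and
then extracting features is available (`mode="curve_first"`) and agrees
within ~10% for replicates with similar parameters.

## Synthetic rosettes

The generator builds leaves as polygons: teardrop blades are two circular
arcs from the petiole base to the tip (valid while width/2 is below the
blade chord), ellipse blades span from `petiole_fraction × length` to the
tip, and a thin petiole strip connects each blade to the center so the
rendered plant is connected. Ground truth — per-leaf areas, union area,
overlap fraction, tip points — is computed by exact polygon geometry
(shapely), never by pixel counting. Rendering is pixel-center-in-polygon at
a constant foreground level over background, with additive Gaussian noise
(default sd 2% of a 12-bit range) and deterministic output for a given
seed. Where two or more leaves overlap, the tissue is rendered at 0.85 of
the foreground level: mutual shading attenuates fluorescence, and this is
the intensity cue that lets edge detectors see leaf complexes in real
images; without it two overlapping radial blades form a quasi-convex union
that no shape screen can reject.

Growth series follow the logistic law per leaf: at each frame the leaf
length is the inverse of the configured length-to-area branch at the target
area, and the width is solved by bisection so the exact polygon area equals
the target. Ground-truth areas therefore follow the logistic exactly *and*
detected tips map back through the length-to-area model. When all leaves
share the A0/Aa ratio and γ, the summed series is itself an exact logistic,
which is how the round-trip recovery tests define their truth.

### What the generator does and does not emulate

It emulates radial leaf arrangement, controllable overlap, petioles, sensor
noise, overlap shading, and logistic growth with exact truth. It does not
emulate leaf texture or venation, twisting/curling, circadian movement,
illumination gradients, or soil/moss background clutter. Passing tests
therefore demonstrate the algorithmic correctness of each stage under known
geometry, not field robustness.

One scale choice matters: tip detection needs leaves large enough that one
pixel of boundary jaggedness is a small fraction of the tip curvature. The
simulated series render leaves with tip radii ≳120 px on 512×512 frames
(equivalently: adequate optical magnification). Below roughly 40 px the
polar profile of a rasterized blade fragments into multiple maxima and the
curvature ratio inflates across the branch cutoff; real imaging at adequate
resolution avoids this regime, and so do the defaults here.

## Numerical and testing choices

- Problem sizes: the test suite renders ~50 synthetic frames at 512×512 and
  the end-to-end series uses 15–30 frames; the Monte-Carlo calibration of
  the growth fit uses 100 repetitions of 900-point series at 2% noise
  (each parameter recovered within 5% and covered by its own 95% CI in at
  least 90 of 100 seeded repetitions).
- Determinism: all stochastic steps (noise, mixtures, Monte-Carlo) take
  explicit seeds; the same configuration and seed reproduce outputs exactly.
- Ties and degeneracies: plateau maxima take the central bin; longest-chord
  ties take the lexicographically smallest endpoint; all-parallel
  orientation lines, empty masks, constant series and flat curves raise or
  return flagged null features rather than guessing.
- The evaluation harness matches predicted to true tips greedily within ±5°
  and ±10% relative radius, and reports tip true-positive rate, mean
  relative area error (corrected and naive), and center distance.

## Known limitations

- The length-to-area coefficients are imaging-setup- and genotype-specific;
  using the shipped defaults on a new setup without recalibration gives
  areas in the wrong scale even if tips are perfect.
- Tips of fully occluded inner leaves are invisible by construction; the
  overlap correction compensates in aggregate but cannot recover per-leaf
  information.
- The simple-leaf screen assumes overlap zones are distinguishable (shape or
  intensity); heavily fused young rosettes fall back to the center of mass.
- One plant per frame; multi-plant trays must be cropped upstream.
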