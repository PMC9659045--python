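# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and
the known limitations.

## Coordinate and calibration conventions

Pixel coordinates are 0-based `(row, col) = (y, x)`; subpixel positions
are real-valued in the same frame. Every physical quantity derives from
two user-supplied calibration constants: the pixel size (µm/pixel;
0.64 µm is the default of the imaging geometry this package targets)
and the frame interval (seconds). Neither is ever inferred from file
metadata — camera frame rates vary by acquisition mode, and a wrong
interval silently rescales every velocity.

## Motion correction

Whole-frame body motion is modeled as a per-frame integer translation.
Each frame is matched to the first frame (the target) by maximizing
zero-mean normalized cross-correlation over a `(2r+1)²` integer search
window; ties break toward the smallest shift magnitude, then smallest
dy, then dx, so results are reproducible. Integer shifts keep
intensities unresampled; the sub-pixel residual (< 0.5 px) is absorbed
by the sparse component downstream. Matching runs on the green channel,
where vessels contrast most strongly. A best match on the window
boundary is flagged: true motion may have exceeded the search radius.
Exactness on noise-free synthetic jitter holds when static structure
(tissue texture, vessel walls) dominates moving content in the
template; a template consisting mostly of a densely perfused vessel
can track the cell train instead — the same failure mode a real
recording would show — which is why the default template is the whole
frame.

## Vessel segmentation

The default segmenter is a multiscale Hessian vesselness filter for
dark tubular structures: at each scale σ the γ-normalized Hessian
eigenvalues (|λ₁| ≤ λ₂, λ₂ > 0 for a dark ridge) are combined as
`exp(−(λ₁/λ₂)²/2β²) · (1 − exp(−S²/2γ²))`, S = √(λ₁²+λ₂²), β = 0.5.
One deliberate departure from per-call adaptive normalization: γ is
half the strongest S over *all* scales, shared, so a scale that sees
only noise is not amplified to full response. Response is the per-pixel
maximum over scales.

Defaults — scales (2, 3, 5, 8, 12, 18, 26, 36) px, threshold 0.28,
minimum object/hole size 64 px — were chosen on a multi-seed synthetic
sweep (vessel widths 5–60 px, tissue texture 5%, additive noise 1%) so
that recall and specificity, averaged over scenes spanning the width
range as segmentation benchmarks on small sample sets report, stay
above 0.8 and 0.95. Wide vessels set the upper scale; the threshold
balances the halo of large-scale responses (hurting specificity at
intermediate widths) against interior coverage of the widest vessels,
whose response level varies a few tens of percent with the local
texture realization. Two geometry caveats for synthetic evaluation:
a vessel that terminates inside the frame loses large-scale response
near its end caps (real vessels leave the field of view), and a vessel
occupying a large fraction of a small frame distorts the global
normalization — evaluation scenes keep frame height at least ~4.5x the
vessel width.

A learned patch-based segmenter can replace this default through the
`VesselPredictor` protocol: patches are extracted with overlap, each
mapped to a probability patch, overlaps averaged on stitching, and the
result binarized at 0.5. The reference training recipe documented on
the interface (256-px patches, batch 16, cross-entropy + Dice, Adam at
1e-3, ~10⁴ iterations, 5-fold cross-validation) is the protocol such a
model would follow; training one is outside this package's scope
because no annotated data is distributed.

Masks are thinned with a homotopy-preserving morphological thinning to
an 8-connected unit-width skeleton and traced into branch-free
centerline paths (walks from degree-1 endpoints to the next endpoint or
branch point; loops are rejected). Centerline tangents come from
moving-average-smoothed coordinates (window 5) to stabilize normals
against the staircase pattern of pixel skeletons.

## Robust PCA

The registered green-channel video, one flattened frame per column,
is decomposed by principal component pursuit,
`min ‖L‖* + λ‖S‖₁ s.t. D = L + S`, solved by the inexact
augmented-Lagrangian method (singular-value thresholding for L,
elementwise soft thresholding for S, penalty growth ρ = 1.5).
Defaults: λ = 1/√max(m, n) (the standard exact-recovery regime),
relative Frobenius tolerance 1e-7, at most 500 iterations; typical
videos converge in 30–40. The inner SVD uses a seeded randomized
range-finder (two power iterations, oversampling 10) when the running
rank estimate is small, falling back to a full economy SVD otherwise;
the fixed probe seed keeps results bit-reproducible. Decompositions of
long videos run on 150-frame windows — the count that reliably
produces a dominant spectral line downstream. The sparse video used for
velocimetry is |S| rescaled by its 99.5th percentile and clipped to
[0, 1]; both polarities count as moving-cell signal.

## Kymograph velocimetry

The kymograph samples the sparse video bilinearly at 1-px arc-length
spacing along a centerline section, one row per frame. For the
spectrum the image is center-cropped to the largest square (cropping,
not resampling — anisotropic resampling would silently rescale the
velocity), mean-subtracted, Hann-windowed to suppress the axis-aligned
leakage cross, and zero-padded 4× for finer spectral sampling. For each
candidate angle θ′ from the temporal-frequency axis (grid 0.25°, both
flow-direction branches), the mean magnitude along the line through the
origin is accumulated over a radial band (default 2 to 0.45·N cycles,
DC excluded); the grid maximum is refined by parabolic interpolation.
Then `v = cot θ′` px/frame. The fraction of band energy on the winning
line is the quality score; below 0.02 an estimate is flagged
low-confidence. Speed is the primary output; the sign branch is
reported separately as a flow direction.

By default only vessels with diameters of 20–100 µm are selected for
velocity reporting in the pipeline (capillaries reconfigure too readily
for stable per-vessel speeds); the bound is configurable. Where one
vessel yields several sections, the median is the vessel's velocity —
a convention, flagged as such.

## FWHM diameter

Profiles are sampled bilinearly at unit spacing along normals placed at
regular arc-length intervals. Extremum *locations* are found on a
width-3 moving average; the dip minimum value is read from the raw
profile (smoothing fills narrow capillary dips), shoulder values from
the smoothed one (a single bright pixel should not set the level). With
m the minimum and p_L, p_R the highest shoulders on each side, the
width is measured at level `m + ((p_L+p_R)/2 − m)/2`, the crossings
adjacent to the minimum interpolated linearly between bracketing
samples. Per-vessel aggregation is the median over normals; failing
normals (profile exits the frame, no dip, level never crossed) are
skipped and counted. Diameter is measured on the median frame of the
analysis window, which suppresses passing-RBC fluctuations.
Classification: capillary < 20 µm ≤ arteriole/vein ≤ 100 µm <
out-of-range (the 20 µm boundary belongs to the upper class, since
capillaries are defined by "less than 20 µm").

## Statistics layer

Cohorts are tables of (group, subject, timepoint, quantity, value).
Summaries are arithmetic mean ± sample SD (n−1); cells with one subject
report a missing SD, empty cells are absent rather than zero. For
cross-quantity trend comparison a series is range-normalized then
mean-centered: `x → (x − mean x)/(max x − min x)`, giving mean 0, range
1, and invariance to positive affine transforms; z-scoring is available
as an alternative mode since the phrase "normalized and centralized"
admits both readings. Significance against the pre-intervention
baseline uses a two-sided paired Student t-test (the same subjects are
measured at both timepoints; Welch's unpaired variant is available
behind a flag) at α = 0.1, with no multiple-testing correction —
matching the per-timepoint presentation style of the studies this
supports. All-zero differences yield t = 0, p = 1; zero-variance
nonzero differences yield p = 0.

## Synthetic data: what it does and does not emulate

`render_scene` produces 16-bit RGB videos with: dark vessels of rounded
(super-Gaussian, order 4) cross-profile — built so the darkening
reaches half its peak exactly at the nominal wall, making the profile
FWHM equal the nominal width; strongest contrast in the green channel
(red/blue get half), emulating hemoglobin absorption; static smooth
tissue mottling (Gaussian-filtered noise, σ = 1 px, 5% default) — real
tissue is never uniform, and this texture is what anchors template
matching; sparse bright Gaussian particles (σ ≈ width/4) advected along
the centerline at constant per-vessel speed, entering as a Poisson
process; per-frame integer rigid jitter; saturated specular disks; and
additive Gaussian noise. Particle brightness (peak 0.15) is kept well
below the static vessel contrast because the moving-cell signal in
real videos is subtle — that is why a sparse/low-rank separation is
needed at all. Identical specs including the seed render bit-identical
videos.

Default scene calibration is 0.64 µm/px with a 10 ms frame interval,
chosen so that microcirculatory speeds up to ~500 µm/s stay below
~8 px/frame, where 150-frame kymographs resolve streak slopes well.

Not emulated: pulsatile flow, vessel branching and remodeling, depth
effects and defocus, photon (shot) noise statistics, rolling-shutter
artifacts, non-rigid tissue deformation. Passing tests therefore
demonstrate correctness of the measurement chain under its stated model
(rigid motion, constant per-vessel speed, static background), not
robustness to every property of in-vivo footage.

## Problem sizes used in tests and the benchmark script

Velocity-recovery runs use 64×224-px scenes, 150 frames, ten seeds per
planted speed; registration and segmentation checks use 96–160-px-tall
scenes; RPCA planted models are 200×150. These sizes keep each full
benchmark run to a few minutes on one CPU while leaving every estimate
well-conditioned (the kymograph still spans 150 px × 150 frames, the
spectrum's dominant line is sampled over dozens of radial bins).

## Known limitations

- Velocities above ~10 px/frame compress θ′ toward zero where angular
  resolution degrades; choose a shorter frame interval for fast flow.
- The FWHM rule takes the *highest* shoulder peak on each side; on
  strongly textured tissue this raises the level slightly and biases
  diameters upward by a few percent — an inherent property of the rule,
  not of the implementation.
- Template matching assumes static structure dominates the template;
  full-frame templates over densely perfused fields can lock onto the
  moving cell train.
- Centerline tracing handles branch-free segments; loops and branch
  topology analytics are out of scope.
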