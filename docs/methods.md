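# Methods

## Reaction model

The model is the steady state of first-order activation/deactivation with a
non-limiting GTPase pool and no transport of the active form: the active
fraction at each position is the ratio of summed GEF to summed GAP rates.
Everything is one-dimensional along the axis from the protruding edge
(x = 0) into the cell; the default domain is the 35 µm micropattern
diameter at 0.05 µm spacing (two orders of magnitude below the sharpest
model length, γ = 5 µm). Rates are in arbitrary units — only ratios are
observable — and the worked defaults are α_C = α_R = 1, β_C = β_R = 0.5,
β_b = 1 with GEF decay λ = 10 µm and localized-GAP decay γ = 5 µm.
Profiles are not normalized inside the model; normalization belongs to the
quantification stage. Temporal dynamics (pulses, excitability) and
spatial transport are out of scope by design; the diffusion length
√(τD) is provided only for order-of-magnitude reasoning about the
rejected transport alternative.

`bump_position` returns `None` (not 0) when γ·ln((λ−γ)/(rγ)) is negative,
so callers can distinguish edge-peaked from bumped profiles; the exact
boundary r = (λ−γ)/γ returns 0.0 while `bump_exists` stays strict, so
"exists" always means a *strictly interior* maximum.

### Concentration-dependent localized GAP

The crosstalk refinement writes the localized GAP rate as a linear
function of the local Cdc42 and Rac1 levels,
β_b(x) = (β_Cb·Cdc42(x) + β_Rb·Rac1(x))·e^(−x/γ_a). The explicit
localization factor e^(−x/γ_a) represents the actin/tip machinery required
for β2-chimaerin recruitment at the lamellipodium tip; its length is fixed
at γ_a = (1/γ − 1/λ)⁻¹ (10 µm at the defaults) so that the Cdc42-driven
component, ∝ e^(−x/λ)·e^(−x/γ_a), decays with the measured β2-chimaerin
length γ = 5 µm. Because Rac1 inhibits itself, the steady state solves a
per-position quadratic whose discriminant is positive by construction; the
unique non-negative root is taken in closed form. A damped fixed-point
iteration (damping 0.5, tolerance 1e−10) is retained purely as a test
oracle and agrees with the closed form to < 1e−9. Knockdowns are scalar
multipliers on the affected rates (α_C for Cdc42 depletion; β_Cb and β_Rb
for β2-chimaerin depletion), complete by default with a partial-efficiency
option. With the default crosstalk coefficients (β_Cb = 0.4, β_Rb = 0.3)
the wild-type β_b(0) equals 1.0, consistent with the plain-model default.

## Optogenetic input model

Gray levels are relative (8-bit DMD mapped to [0, 1]); absolute photon
flux is out of scope. Standard gradients are linear ramps
I(x) = A·max(0, 1 − x/extent) with extent = diameter/slope-class.
Membrane recruitment is the light profile convolved with the normalized
two-sided exponential e^(−|x|/ℓ)/(2ℓ) — the steady-state Green's function
of lateral membrane diffusion with first-order unbinding of the
CRY2–CIBN dimer — with ℓ = 5 µm by default. Boundaries reflect at both
cell edges, which conserves the recruited mass exactly in the discrete
convolution (mass = Σ values·Δx; the kernel is normalized to unit
discrete sum). Patterns are one-dimensional along the stimulation axis;
two-dimensional rendering is delegated to the synthetic-data generator.
No kinetic (time-resolved) binding model is included: the stimulations
analyzed are steady.

`fit_tail_length` estimates ℓ by log-linear least squares on the window
[boundary + 0.25 ℓ, boundary + 1.25 ℓ], clipped to stay one ℓ away from
the far cell edge. Past the illumination boundary the reflected-kernel
step response is a single exponential of length ℓ from the boundary
onward (all images reflected at the bright edge share the same decay), so
the near window is unbiased; the image reflected at the *far* edge adds an
e^(+x/ℓ) term which makes wider windows — e.g. one reaching 4 ℓ past the
boundary — several percent long. On the 35 µm domain the default window
recovers ℓ = 5 µm to better than 1%, and ℓ ∈ {2, 5, 10} µm to < 0.1% when
the fit window is far from both boundaries.

## Synthetic data: the stated world

The generator emulates the reference dataset's statistical structure with
known ground truth; the published summary statistics are the generator
truths.

**Mean shapes.** The Cdc42 mean shape is a plateau of width w followed by
e^(−(x−w)/8.3): a plain exponential of decay 8.3 µm cannot reach a
windowed half-amplitude extent of 8.9 µm, and the plateau reconciles both
printed numbers while matching the flat-topped appearance of edge-proximal
profiles. The Rac1 mean shape is the bumped model profile with the tail
decay pinned to λ = 9.6 µm. Calibration is by root-finding against the
package's own estimators on the noiseless shape: w solves
extent = 8.9 µm (1-D Brent), and (γ, r) solve peak = 5.8 µm and
extent = 14.6 µm (2-D solve in log parameters, initial guess from
inverting the closed-form bump position). Calibrated values: w = 4.346 µm,
γ = 5.863 µm, r = 0.2368; the closed-form bump position at the calibrated
triple is 5.805 µm. The round trip — quantifying the noiseless calibrated
shape — reproduces every target to 0.01 µm.

**Measurement window.** Profiles live on a 20 µm window (edge to nucleus)
at 0.1 µm spacing. The printed extents presuppose min/max normalization on
a finite window; 20 µm is the calibrated choice that makes the windowed
extent metric consistent with the printed 14.6/8.9 µm values, and it is an
explicit configuration field.

**Noise.** Per cell, a multiplicative lognormal amplitude factor
(σ = 0.2) models cell-to-cell expression/sensor variability; per position,
additive Gaussian noise with σ = 0.1 × the mean-shape peak models
measurement noise. Images add Poisson shot noise and Gaussian read noise
(σ = 3 counts) on a baseline of 100 and a signal amplitude of 400 counts,
at 0.25 µm/px (so the 10-px linescan width spans 2.5 µm). These levels
are not derived from deposited data (none exist); they are plausible
levels chosen once, and the recovery tolerances below are statements about
this stated world, not about real microscopes.

**Migration movies.** Each cell draws a fixed heading from von Mises(0, κ)
about the gradient axis and translates at the condition's mean speed with
20% multiplicative Gaussian speed jitter per frame; masks are disks
(radius 10 µm) with slowly drifting low-order Fourier boundary
perturbations (2% amplitude) plus a small protrusive bias toward the
heading, rasterized at 0.5 µm/px, 2 min frame interval, 60 min duration.
Defaults for a stimulated condition are 0.5 µm/min and κ = 2. The movies
contain no nucleus, no division, no collision, and no shape change beyond
the boundary perturbation — a green migration test therefore validates the
tracking/statistics chain, not segmentation robustness on real imagery.

## Quantification choices

- **Linescans** sample bilinearly every pixel along the line and average
  across a 10-px width; positions are µm from the cell edge.
- **Normalization** follows the five-extreme convention: the mean of the
  five smallest values maps to 0, of the five largest to 1. Profiles of
  the same reporter compared across conditions are *not* normalized.
- **Ensemble averaging** is cell-first: replicate lines are averaged per
  cell before the unweighted cross-cell mean and s.d.
- **Decay length** is nonlinear least squares of A·e^(−x/λ) + B with a
  free baseline (absorbing the nonzero far-field signal of non-normalized
  profiles). For the plateaued Cdc42 shape the fit starts where the
  lightly smoothed ensemble mean first drops below 0.9 × its maximum
  (inside the exponential flank, where the model class is exact and the
  start point therefore does not bias λ).
- **Rac1 tail decay** is the λ of a fit of the bumped model family
  A·e^(−x/λ)/(r + e^(−x/γ)) over the whole window. A plain exponential
  fit beyond the peak is structurally unidentifiable here: any shape with
  peak ≈ 5.8 µm and extent ≈ 14.6 µm on a 20 µm window has a post-peak
  flank whose local decay length stays above 12 µm everywhere inside the
  window (the asymptotic 9.6 µm is reached only beyond it), and the
  three-parameter exponential-plus-baseline fit degenerates to its linear
  limit. Fitting the generating model class recovers the asymptotic decay
  without bias (+0.02 µm at n = 31).
- **Peak detection** smooths with a Gaussian of σ = 0.5 µm, takes the
  global maximum (ties toward the edge) and refines it by quadratic
  interpolation; maxima at either domain end are reported as edge-peaked
  (`None`), never as 0.
- **Extent** is the first half-amplitude crossing *beyond* the maximum,
  located by linear interpolation, so bumped profiles measure their
  decaying flank; no crossing inside the window reports `inf`.
- **Curve comparison** is a two-sided Wilcoxon rank-sum test per position,
  uncorrected by default (matching common curve-overlay practice); a
  Benjamini–Hochberg option exists.
- **Input–output matching** compares five-extreme-normalized extents of
  the activating input (the membrane recruitment profile) and the
  simulated activity output at a 2 µm resolution (two standard deviations
  of the extent estimate).
- **Edge enrichment** discretizes the mask boundary into 1 µm arcs and
  compares, per arc, the mean intensity of the outermost 1 µm band of the
  cell with the adjacent 1 µm cytosolic band; the reported fraction is the
  share of arcs with edge > cytosol.

## Migration analysis choices

Segmentation is a global Otsu threshold per frame, keeping the largest
connected component with holes filled; a second component larger than half
the dominant one raises an error rather than guessing. Instantaneous
speed is the frame-to-frame centroid displacement rate, boxcar-averaged
over five consecutive frames, then averaged over a configurable time
interval. The displacement angle runs from the centroid averaged over the
first three frames to the last three, measured against the gradient axis;
zero-displacement cells are excluded (and counted), not assigned an angle.
Angular precision is the mean resultant length
p = √((Σsinθ/n)² + (Σcosθ/n)²); the point estimate on the original sample
is primary and the dispersion of 1000 seeded bootstrap resamples is its
reported uncertainty. The heading concentration κ is recovered by
inverting p = I₁(κ)/I₀(κ).

Morphodynamic maps resample each frame's contour to 360 points by arc
length starting from the gradient direction and assign each point the
signed distance to the next frame's boundary (positive outward) divided by
the frame interval. The signed distance is measured to the next frame's
*sub-pixel* contour (nearest vertex of the densified marching-squares
contour, sign from bilinear mask interpolation) rather than to the binary
mask's Euclidean distance transform: the EDT measures to pixel centers and
carries a ±0.5 px orientation-dependent offset, while the contour distance
is exact to ~0.05 px for identical masks. Consistency check: mean edge
velocity × contour perimeter matches the pixel-count area change rate to
within 5% on smooth test shapes. Mask topology changes (splits/merges)
flag the frame and fill its column with NaN.

## Numerical notes and limitations

- All generators are deterministic under a fixed seed; pipeline runs
  record seed, configuration and version in their reports.
- The brute-force bump oracle uses a 0.005 µm grid; closed-form and
  brute-force positions agree to < 0.01 µm over λ ∈ {6…15},
  γ ∈ {2…8} (γ < λ), r ∈ {0.05…0.95}.
- The bump-existence threshold is scanned over r ∈ [0.05, 3] in steps of
  0.001: the largest r with a strictly interior maximum is 0.999 at
  λ = 10, γ = 5, against the closed-form threshold of 1.
- Recovery tolerances at the reference sample sizes (n = 19/31 cells, 200
  seeded replicates): mean estimated decay, peak, tail decay and extents
  land within one printed SEM of the generator truth. The extent
  estimators carry a small negative bias (≈ −0.3 to −0.5 µm) from the
  five-extreme normalization of noisy ensemble means — the extreme-value
  estimates of the baseline and peak are inflated by noise — which stays
  within the SEM band and is accepted rather than corrected, since the
  convention is part of the measurement definition.
- The von Mises κ estimate from a single ~18-cell ensemble has sampling
  scatter of roughly ±0.4 at κ = 2; recovery statements are about the
  mean over several seeded ensembles.
- The edge-velocity magnitude is biased low by a few percent for
  boundary displacements of ~1 px (nearest-point distance to a rough
  contour); band structure and sign are unaffected.
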