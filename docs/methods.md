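# Methods

`synthlung` builds a fully synthetic free-breathing lung-MRI acquisition in
which every quantity the downstream analysis tries to measure — per-voxel
deformation, functional class, signal dynamics, noise level — is known by
construction. The package then runs the same analysis a clinical pipeline
would run (registration, signal-based and deformation-based ventilation
mapping, perfusion-amplitude mapping, defect thresholding) and scores it
against that ground truth.

## Phantom model

### Geometry

The expiration-state anatomy is a 128×128 coronal cartoon: a 90×90 body
square centered in the grid, two 16×32 rectangular lungs placed symmetric
about the vertical midline (12-column gap, starting at row 40), and a
radius-2 vessel disk centered between the lungs at lung mid-height. The
lung ROI is 1024 voxels. Rows index the head–foot direction (y), columns
left–right; the image-left lung is the anatomical right lung. The lung
vertical offset and inter-lung gap are not constrained by the physics of
the model; the defaults above are package choices and live in
`LayoutConfig`.

Each lung voxel belongs to one of eight functional classes: normal tissue
(VV|QV), three non-ventilating defects distinguished by their constant
signal level (low = 8 AU, inspiration level = 16 AU, high = 100 AU),
delayed ventilation, perfusion defect (VV|QD), delayed perfusion, and
compensatory hyper-expanded tissue. Six classes are placed as random
4-connected 60-voxel clusters grown from uniform-random seeds (resampled
on collision); placement is a pure function of the seed.

### Deformation

Motion is one-dimensional (y). A per-voxel fractional expansion matrix E
is balanced per column so that

* C1 — the mean of E over the 32 lung rows equals the target e (default
  0.25, i.e. a linear expansion factor of 1.25) in every lung column, and
* C2 — each full column of E sums to zero, the body deflating uniformly
  (per column) to compensate.

Non-ventilating defects carry E = 0; normal voxels in their columns are
promoted to the compensatory class and carry e·(32−n_fixed)/n_normal.
Both conditions hold to 1e−10 by construction and are asserted in tests.

The forward displacement field (expiration → deformed space) is the
cumulative sum of E along y; the inverse field is obtained per column by
linear scattered interpolation of the forward-transformed grid j = y + F
and negation. Images are warped with linear interpolation and nearest-edge
extrapolation. All warping runs on a 4× upscaled grid and is
block-averaged back, which keeps the forward/inverse transformation error
at the sub-voxel level. Jacobian determinants use central differences
(one-sided at the borders); for a y-only field det J = 1 + ∂u_y/∂y.

Per frame, each voxel's expansion is scaled by its own respiration factor
r(t, x) ∈ [0, 1] and the body deflation is re-balanced, so C2 holds at
every respiratory state. Note that a phantom containing delayed-ventilation
clusters is never globally at rest: those clusters inflate half a
respiratory period out of phase.

### Signals and noise

Every class follows the periodic two-component signal model

    s(t) = s0 − A_V cos^{2n}(πt/τ_V − φ_V) + A_Q sin^{2m}(πt/τ_Q − φ_Q)

with n = 3, m = 2, τ_V = 5 s, τ_Q = 0.8 s, s_exp = 20 AU, s_body = 200 AU.
Proton density scales inversely with volume, so a voxel expanding by the
linear factor (1 + e) has ventilation amplitude A_V = s_exp(1 − 1/(1+e));
compensatory voxels use their own per-column e in this formula, which
keeps their signal consistent with their larger expansion (without this,
signal-based ventilation could not recover the compensated expansion and
the two ventilation measures would disagree even under perfect
registration). The volume surrogate is the inverse of the ventilation
part of s(t); its min–max normalization over the sampled time grid is the
respiration factor. Delay phases of π/2 shift the respective component by
half its period (2.5 s for ventilation, 0.4 s for perfusion) — i.e. they
are in anti-phase with the normal class.

A series has 250 frames at 0.192 s. Per frame, signals are painted in
expiration space, warped by the frame's inverse field on the 4× grid,
block-averaged to 128², noise is added, and the result is bilinearly
interpolated to 256² (noise before the final interpolation, as the
acquisition noise would be). Noise mimics a four-channel sum-of-squares
magnitude reconstruction: each channel carries s/√4 plus independent
Gaussian noise; the per-channel σ is calibrated analytically (non-central
chi first/second moments, solved by bisection) so a constant signal at
s_exp has combined-magnitude SNR 5. A Monte-Carlo test pins the
calibration to within 2%.

## Analysis pipeline (reference registration)

Frames are sorted by the normal-class respiration factor into 10
equal-count bins (bin 1 = expiration, bin 10 = inspiration; ties break by
frame index). Reference (REF) registration warps every frame toward
expiration by its own ground-truth forward field; its only error source is
the forward/inverse interpolation. External registrators plug in through
an adapter contract operating on the 10 bin-mean images.

**RVent** (signal-based ventilation) = s_reg(s_exp − s_insp)/(s_insp·s_exp)
on the bin-10/bin-1 averages of the registered series; with the expiration
average as the fixed image this is s_exp/s_insp − 1. Two corrections are
applied before averaging, both standard in magnitude-MRI processing:

1. *Cardiac separation.* The cardiac term A_Q sin^4 is non-negative with
   a DC of 3/8·A_Q; left in place it contaminates both state averages and
   deflates RVent by ~12%. Each voxel's series is regressed against a
   global non-negative cardiac template (ROI-averaged high-passed signal,
   phase-binned, minus its quietest phase) and the fitted component is
   subtracted. The regression coefficient has zero-mean noise, so voxels
   without a cardiac component are not biased.
2. *Noise-floor inversion.* Sum-of-squares magnitudes are non-central-chi
   distributed; at SNR 5 the first-moment bias compresses the 16→20 AU
   signal ratio and deflates RVent from 0.243 to ~0.21. The state
   averages (temporal means, hence nearly noise-free) are mapped back
   through the analytic first moment, with σ estimated from the
   background region (central-chi mean).

**JVent** (deformation-based ventilation) = det J − 1 of the averaged
bin-10 forward field. For REF the field average and Jacobian are computed
on the 4× upscaled grid and block-averaged down, which keeps defect
boundaries sharp; for external registrators the Jacobian is taken on the
field the adapter returns.

**QA** (perfusion amplitude): the registered series (lung ROI) is
high-pass filtered at 0.9 Hz — by default a zero-phase FFT filter with a
hard cutoff, the standard Fourier-decomposition realization; a low-order
recursive filter would attenuate the cardiac fundamental (|H|² ≈ 0.93 at
1.25 Hz for a 4th-order zero-phase Butterworth, which is retained as an
option) and measurably deflate QA. Frames are then grouped by cardiac
phase (the period is estimated from the spectral peak of the ROI-averaged
signal; the default grid revisits 25 distinct phases 10 times each),
phase means are formed, the extremal phases are picked from the
ROI-averaged signal, and QA is the per-voxel difference of the two phase
means. The phase averaging is what makes per-voxel QA usable at SNR 5;
`phase_bins=1` recovers a single-frame variant. Before filtering, the
per-frame noise floor is corrected with the classical square-root rule
ŝ = sqrt(max(M² − (k−1)σ², 0)), whose residual bias is nearly constant
over the relevant signal range and therefore drops out of the amplitude;
without it the magnitude operation compresses signal differences by the
local slope of the bias curve (~4% at lung signal levels). The expected whole-lung
mean is well below the raw cardiac amplitude of 6 AU because ~23% of the
ROI has no cardiac component, delayed-perfusion clusters contribute in
anti-phase (negative QA), and the sampled phase grid does not land exactly
on the continuous extrema; the single-voxel oracle test pins the in-house
value.

An image-guided edge-preserving filter (guided filter, box formulation,
radius 3, eps = (0.1·dynamic range)²) is available for RVent on low-SNR
data (RVent*); constant maps are fixed points and large eps degenerates to
a box mean.

## Evaluation

Defects are voxels strictly below 0.4× the 90th percentile
(linear-interpolation percentile — the threshold is sensitive to the
percentile convention, so it is fixed and tested against a brute-force
oracle) of the in-ROI map values; VDP/QDP is their share of the lung ROI.

Scoring happens where the ground truth lives, on the base 128² grid:
masks thresholded on the final-grid maps are carried down by majority
vote, and TP/TN rates are computed per lung quadrant (each lung split at
its vertical midline; 256 voxels per quadrant, odd rows go to the lower
quadrant). In the all-classes scoring the delayed classes count as truth
positives: both genuinely measure ~zero ventilation/perfusion at the
normal-class reference phases, so a map that flags them is right to do
so. A switch (`delayed_as_positive`) exposes the alternative convention.
Per-class sensitivities mask out the other seeded classes from the
quadrant ROI.

Parameter statistics (whole-lung means/medians, quadrant relative
differences) run on the lung *core*: the ROI eroded by 2 final-grid
voxels, the width of the partial-volume ring created by the
block-average/bilinear interpolation chain, within which "lung signal" is
a lung/body mixture. Ventilation statistics additionally exclude the
delayed-ventilation class, whose defined expansion at the evaluated
(normal-class inspiration) state is zero — it is therefore also excluded
from the relative-difference truth map, along with non-expanding defects.
The QA truth map is the same pipeline run on the matched noiseless series;
near-zero truth voxels (below 10% of the ROI's 90th percentile) are
excluded from QA relative differences.

Group comparisons use Friedman's omnibus test with post-hoc Wilcoxon
signed-rank tests at the 5% level; degenerate (identical) groups report
p = 1 and undefined rates (quadrants without truth voxels) propagate as
NaN and drop out of medians.

## Expected values under the default conditions

With 250 frames of the spiky cos^6 respiratory waveform, the
top-decile bin has mean r = 0.971, so both ventilation measures are
expected to read 0.25·0.971 ≈ 0.243 in the core — a relative difference
of −0.03, which the quadrant medians reproduce. The 20-phantom medians
(seeds 0–19) are ≈ 0.235 (RVent) and ≈ 0.238 (JVent) for the whole-lung
core mean, ≈ 3.7 AU for QA, median quadrant sensitivity 1.00 (JVent) and
≥ 0.96 (RVent, QA), and measured SNR 5.02.

## Problem sizes and runtime

The repeated experiment uses 20 phantoms (seeds base+0..19) at the full
default size (128² base grid, 4× warping, 256² output, 250 frames); one
phantom takes ~12 s on a single CPU and the full run ~3 min. Tests reuse
one session-scoped run; fast orchestration tests use 50-frame series.

## What the phantom does and does not show

Passing these tests shows that the quantification pipeline is unbiased
and sensitive *given* its own assumptions: 1-D motion, a rectangular
lung, proton-density-only contrast, periodic noise-free class signals
plus stationary coil noise, and perfect registration. It says nothing
about through-plane motion, realistic lung shapes or texture (which real
registration depends on), relaxation/TE/TR physics, flow artifacts, or
non-stationary breathing — real-data validation cannot be replaced.
Known limitations: the outer-ring partial-volume voxels are excluded from
parameter statistics but not from defect scoring, where they depress the
signal-based specificity; the cardiac template regression leaves ~0.3 AU
of respiratory spectral leakage; and external registrators are exercised
only through the adapter contract, not re-implemented.
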