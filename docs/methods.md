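# Methods

This note records the scientific and numerical choices behind `cineflow`:
what is modelled, which parameters matter, what the phantom generator does
and does not emulate, and where the design was genuinely open.

## Problem setting

Cine SSFP imaging of the heart shows the blood pool as a bright region with
speckle-like intensity fluctuations that travel with the blood. Given a
temporal window of cine frames, the package regresses the dense in-plane
displacement of every blood-pool pixel from the central frame to the next.
Supervision comes from a velocity reference (in a clinical setting, the
in-plane projection of a 4D-flow acquisition; here, the phantom's analytic
field) converted to pixel displacements by `D = (Δt·vₓ/psₓ, Δt·v_y/ps_y)`
with velocities in cm/s (×10 to mm/s internally), spacing in mm and Δt in
seconds. Predicted displacements are divided by the same factors to give
velocities for evaluation.

Conventions: arrays are `[T, H, W]`; `x` is the column direction, `y` the
row direction; pixel centers at integer coordinates; velocities cm/s.
Temporal windows wrap cyclically — the reconstructed phases cover one full
cardiac cycle, so phase 0 and phase T−1 are physiological neighbours. The
window is symmetric (±4 around the central frame by default); the half-width
is configurable.

## Preprocessing

Intensity normalization maps every pixel by `(P − P₅)/(P₉₅ − P₅)` where the
percentiles (linear interpolation between order statistics) are computed
from the pooled blood-pool pixels of *all* phases of a case. Values outside
[0, 1] are kept: flow-induced signal loss is part of the signal being
tracked. Normalization is per case, not per fold. Threshold comparisons
("more than 6 bpm", "> 5 cm/s", "> 4 cm/s") are strict everywhere.

The trilinear plane-sampling operation resamples a `[X, Y, Z, 3]` velocity
volume at the world coordinates of each plane pixel and keeps the two
in-plane components (`v·e_x`, `v·e_y`). Trilinear interpolation is exact on
trilinear fields, which the tests exploit as an oracle. Out-of-volume
pixels are zeroed and counted rather than raising.

In-plane alignment between cine and reference is expressed as an explicit
integer-pixel translation operator; automatic registration is out of scope.

## The phantom generator

The generator produces a two-chamber long-axis scene: an elliptical
ventricle (64×64 grid, semi-axes ≈ 17×13 px at default size) joined at a
valve gap to a smaller atrium. The analytic flow has three parts:

* a solid-rotation vortex in the ventricle whose boundary speed peaks at
  `vortex_peak_speed` (default 10 cm/s) under a temporal envelope with a
  Gaussian systolic surge (peak at 25 % of the cycle, width 8 %) on a
  persistent baseline (default 30 % of peak — intra-cardiac swirl never
  fully stops);
* a gentler counter-swirl in the atrium (50 % of the ventricular strength);
* an inflow jet through the valve gap, directed from atrium to ventricle,
  with temporal profile `g(t) = E·exp(−(t−t_E)²/2σ²) + A·exp(−(t−t_A)²/2σ²)`
  (defaults E = 56 cm/s at 65 %, A = 40 cm/s at 90 %, σ = 5 % of the
  cycle — σ is well below |t_A−t_E|/4, so the configured peaks are attained
  to better than 1 % in continuous time). The spatial weight is 1 on an
  axial plateau through the valve region and decays as a Gaussian across
  and beyond it, so the maximum speed in the transmitral ROI equals `g(t)`.

The defaults mimic a 30-phase acquisition at 60 bpm (Δt = 33 ms) with
1.5 mm pixels. The truth field is identically zero outside the labelled
mask. Rendering starts from band-limited Gaussian speckle (correlation
length 1.5 px) on a bright pool over a dark background and advects it
frame-to-frame by backward warping (bilinear sampling, constant padding)
along the true displacement; forward splatting was rejected as noisier.
Optional extras: speed-proportional attenuation `exp(−λ|v|)` (off by
default so the analytic field remains the sole supervision signal) and
additive Gaussian noise. A fixed seed makes a phantom bit-reproducible.
A configured phantom whose displacement exceeds H/4 px per frame is
rejected as unrealistic rather than rendered.

What the phantom does **not** emulate: SSFP signal physics (saturation,
banding, through-plane inflow enhancement), chamber wall motion (the
geometry is static; only the blood moves), through-plane flow, respiratory
or heart-rate inconsistency between cine and reference, and four-chamber
anatomy (the default scene has two chambers; the other two labels simply
stay empty). Passing tests therefore demonstrate that the pipeline recovers
known advective motion under controlled conditions — not clinical-grade
performance on patient data.

## Network and training

The regressor is a residual U-Net over a 9-frame window concatenated as
channels. Contracting path: a residual block at full resolution, then four
scales reached by one 2×2 max pool followed by three stride-2 1×1
convolutions that also double the channel count (base 32 channels,
doubling per level; channel widths, activation and normalization are not
dictated by the problem, so standard ResNet practice is used: two 3×3
convolutions + batch normalization + ReLU with an identity — or 1×1
projection — shortcut). Expanding path: nearest-neighbour upsampling,
concatenation skips, one conv-BN-ReLU block per scale. Auxiliary 2-channel
1×1 heads sit at decoder scales 1/8, 1/4 and 1/2, each inserted before the
next upsampling and resampled to full size by nearest neighbour; the final
head predicts at full resolution. Convolutions feeding batch norm carry no
bias (it would be cancelled and its gradient is identically zero — the
deep-supervision wiring test demands every parameter receive gradient).

The loss is the masked end-point error of the final head plus weighted
auxiliary EPEs; default weights (0.25, 0.5, 0.75) increase toward full
resolution and are logged. Only blood-pool pixels enter the loss, so
outside-mask predictions are unconstrained and are zeroed at inference.

Because the package is pure NumPy, `cineflow.nn` provides a small
reverse-mode autodiff: convolutions are lowered to single im2col matrix
products, and the whole graph is verified against central finite
differences in float64. Training runs in float32. Two numerical points
deserve note:

* the EPE loss is non-smooth at zero error; a tiny ε (1e−12) inside the
  square root regularizes the gradient;
* batch-norm running statistics lag the weights, which is catastrophic when
  activations are nearly constant (e.g. a zero-flow phantom). After the
  last epoch a precise-BN pass re-estimates the inference statistics with
  the final weights over the training set, making eval-mode predictions
  consistent with training behaviour.

Optimization is Adam (lr 1e−3, batch 8); epochs are experiment-specific.
Cross-validation splits at *case* level (never image level) into folds
whose sizes differ by at most one; every case is predicted exactly once, by
the model whose training fold excluded it. Seeding covers the fold split,
weight initialization and batch order, so a run is reproducible end to end.
No data augmentation is applied.

### Experiment scales

The recovery experiments use 64×64, 30-phase phantoms with per-frame
displacements below 2 px (vortex 7 cm/s with a 0.6 baseline, jet 6/4.2
cm/s — chosen so the zero-predictor EPE is a non-trivial ≥ 0.5 px), a
base-8-channel network, 60 epochs for single-phantom memorization and
20 epochs for 2-fold cross-validation on 8 phantoms whose flow amplitude
varies ±30 % across cases. These sizes are the package's reference desk
experiment; wider networks and longer schedules only improve the margins.

## Evaluation metrics

Velocity EPE and angle error condition on the *reference* speed exceeding
the gate (5 cm/s by default): evaluation is stratified by the true flow
regime, and a noisy prediction cannot move pixels in or out of the
evaluated set. Pixels where either vector is exactly zero are excluded
from the angle error with a returned count. The relative error is the
signed percentage difference of mean speeds over all masked pixels
(means-ratio reading; a mean-of-pixelwise-ratios alternative was considered
and rejected as unstable near zero reference speed). The cycle correlation
is the Pearson r of the two per-phase spatially averaged speed series.
Cohort tables aggregate case-level values to mean ± SD (not pixel-pooled).
A percentile-threshold "accuracy" (fraction of qualifying pixels whose EPE
is below the 30th percentile of reference speed) is provided but off by
default; the definition is one plausible reading of an ambiguous
convention, and is labelled as such.

## E/A extraction

The transmitral ROI is bounded by the chord between the valve hinge points
(the LV contour's first and last vertices) and a clamped quadratic b-spline
through hinge–center–hinge, intersected with the LV mask and recomputed per
phase. Collinear landmarks collapse the region onto the chord and are
flagged as degenerate rather than silently returning an empty ROI. The
E and A velocities are the first and last prominent local maxima
(prominence ≥ 10 % of the diastolic range) of the per-phase maximum ROI
speed after diastole onset, each refined by a three-point parabolic fit so
peaks falling between phase samples (e.g. 65 % of a 30-phase cycle) are
recovered to ~1 %. Diastole onset defaults to the curve minimum in the
30–60 % window of the cycle — a heuristic documented as this package's
rule, overridable by an explicit phase. Fewer than two prominent peaks is
an explicit failure status, never a NaN ratio; cohort statistics skip
failures with a logged count. Classification uses the echocardiographic
band: normal iff 0.75 < E/A < 1.5, strictly.

Agreement statistics: Bland-Altman bias and 1.96 × sample-SD limits of
agreement, Pearson correlation, and a two-sided paired t-test (α = 0.05).
Confusion metrics (accuracy, per-class precision/recall/F1) come from
scikit-learn behind the module surface.

## Visualization

Vector overlays draw arrows at subsampled blood-pool pixels with speed
above a display threshold (4 cm/s by default, suppressing velocity noise);
arrow length and colour are monotone in speed. Rendering is deterministic
for fixed inputs.

## Known limitations

* The phantom's advection is first-order (one backward-warp step per
  frame); fast jets traversing many pixels per frame accumulate
  interpolation blur, which is why rendering rejects displacements above
  H/4 px.
* The NumPy network trains comfortably at desk scale but is not meant for
  cohort-scale training; there is no GPU path.
* The E/A timing rule and the percentile-accuracy definition are this
  package's documented choices where the underlying conventions are
  ambiguous.
* Batch-norm recalibration assumes the inference distribution matches the
  training distribution; domain shift between folds is mild for phantoms
  but would need care on real data.
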