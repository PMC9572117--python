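# Methods

## Problem setting

A trunk-worn tri-axial accelerometer (100 Hz) observes quasi-static
postural sway. The longitudinal axis A_y is gravity-aligned at rest, A_z
points anterior, A_x lateral. With the sensor mounted at lever arms H1
(bottom joint, antero-posterior tilt) and H2 (belt joint, medio-lateral
tilt), the sway displacements are reconstructed per sample as

    D_AP = H1 · A_z / sqrt(A_y² + A_x²),
    D_ML = H2 · A_x / sqrt(A_y² + A_z²),

and the classifiers decide, per 10 s window (shift 1 s for continuous
monitoring), whether the movement is potentially unstable. Walking and
other daily activities are assumed to be excluded upstream; only standing
windows enter the pipeline.

## Rig simulator

The generator emulates a mechanical two-joint rig that imposes movements
of four classes: quiet standing (ST, label 0) and three unstable classes
(AP, ML, UNS, label 1). Per pattern:

- Tilt traces θ_AP(t), θ_ML(t) are sums of 5 sinusoids with random phases
  and frequencies drawn *stratified* — one per equal sub-band of the sway
  band (default 0.1–2 Hz, the band where postural sway concentrates).
  Stratification keeps the spectral shape comparable across patterns:
  with fully independent frequency draws, a pattern may be almost purely
  slow, which makes derivative-weighted features (D_RMS) and the d3–d5
  wavelet band nearly empty and classifying such a pattern from those
  features ill-posed. The traces are peak-normalized: max|θ| equals the
  class amplitude exactly.
- Class amplitudes: ST sways at `amp_stable` (default 0.005 rad) on both
  axes; AP/ML at `amp_unstable` (default 0.1 rad) on the named axis while
  the untouched joint moves at a random sub-stable amplitude
  U(0.3, 0.9)·amp_stable (the operator holds it); UNS at `amp_unstable`
  on both axes. The 20× amplitude ratio leaves a support gap in every
  extracted feature between ST and the unstable classes that is robust to
  the residual frequency/phase/lever-arm variability — the synthetic
  analogue of the clean class separation that imposed rig movements
  produce in reality.
- Acceleration is the quasi-static projection of gravity onto the tilted
  sensor axes, implemented as the exact algebraic inverse of the
  displacement equations: the generated (A_x, A_y, A_z) is the unique
  gravity-magnitude vector satisfying D_AP = H1·tan θ_AP and
  D_ML = H2·tan θ_ML simultaneously (for single-axis tilt this reduces to
  A_z = g sin θ, A_y = g cos θ). Optional i.i.d. Gaussian sensor noise
  (default 0: the reference experiments use the noiseless rig; robustness
  is studied at the feature level instead).
- Six geometry cases: H1 ∈ {1.0, 1.1, 1.2} m × H2 ∈ {0.5, 0.6} m,
  plausible chest heights for the rig, which does not prescribe values.
- Labels are assigned by the imposed movement class, not by
  re-thresholding displacement; the `instability_displacement` parameter
  (0.04 m) is a documented margin: noiseless unstable patterns exceed it,
  ST patterns stay below half of it.

Generation is deterministic given a seed (per-pattern child seeds via
`numpy.random.SeedSequence`).

What the simulator does **not** emulate: human biomechanics (ankle/hip
strategy dynamics, multi-scale neuromuscular feedback), transitions and
daily activities, sensor drift/quantization, and the artefacts of a rigid
structure. Perfect accuracy on this generator therefore demonstrates the
correctness and calibration of the pipeline on separable data, not
clinical performance.

## Pre-processing and features

- Pre-filter: 4th-order Butterworth low-pass, 5 Hz cutoff, applied
  forward-backward (zero phase). 5 Hz comfortably contains sway dynamics
  while suppressing sensor noise; DC is preserved because the gravity
  component carries the tilt information. Samples with vanishing
  projection denominators (free-fall-like) are flagged invalid and
  excluded from features rather than interpolated.
- Time features (per window): signed extrema of D_AP and D_ML; D_RMS with
  the pair count as denominator (the two-point window then yields exactly
  the step length); CEA95 = π·(CSF·σ_AP)(CSF·σ_ML) with σ the unbiased
  (n−1) standard deviation and CSF = 2.4477, the printed 4-decimal value
  of sqrt(χ²₂⁻¹(0.95)).
- Wavelet features: 5-level DWT, Daubechies-4, periodization mode (db4 is
  the common orthogonal choice in sway DWT analyses; orthogonality gives
  energy conservation). Per level a ∈ {d3, d4, d5}: mean MV_a, unbiased
  std STD_a, energy E_a = Σ T(a,k)², computed separately on the D_AP and
  D_ML windows and summed per (feature, level) — 9 inputs in the fixed
  order MV_d3..MV_d5, STD_d3..STD_d5, E_d3..E_d5. d1/d2 (≳12.5 Hz,
  sensor-noise band) and the a5 approximation (which absorbs the window
  mean) are excluded. Note: energy conservation of the periodized DWT is
  exact only for window lengths divisible by 2⁵; the 1000-sample 10 s
  window hits an odd cascade stage and inflates coefficient energy by
  <1%, which is irrelevant for classification and documented in the
  tests.

## Threshold voting classifier

Per feature, the threshold is the Youden-optimal cut (max sensitivity +
specificity − 1) over midpoints of sorted unique training values, with
ties broken toward the larger threshold (conservative toward "stable").
Both vote orientations are scanned and the better one kept, since
instability drives the signed minima *down*. Votes are strict
exceedances in the unstable direction. The direction-specific extrema
pairs {DAPmax, DMLmax} and {DAPmin, DMLmin} are each collapsed by a
logical OR — a purely antero-posterior instability fires only the AP
member, so the pair acts as one "any-axis exceedance" vote — giving 4
effective votes together with D_RMS and CEA95. The window is unstable
when at least 50% of effective votes are set (ties to unstable, the
conservative choice for a safety application).

Reliability: RI_Th = 100·|mean(votes) − 0.5|/0.5 (100 for a unanimous
vote). The feature-distance index RI_JF normalizes each feature's
threshold distance by the training-set maximum |J_F − J_th| (frozen in
the model), clips to [−1, 1], counts a feature only when its own vote
agrees with the final prediction, max-pools inside OR groups, and
averages: RI_JF = 100·mean(J_P). RI_Th is the index used in method
comparisons; RI_JF diagnoses how close individual features sit to their
thresholds.

## Sugeno neuro-fuzzy classifier

A single-output first-order Sugeno system: rule r fires with
w_r(x) = Π_d exp(−(x_d − c_rd)²/(2σ_rd²)) and contributes a linear
consequent; the output is the firing-weighted average. Structure comes
from subtractive clustering on the unit-hypercube-normalized training
inputs (potential P_i = Σ_j exp(−4‖x_i − x_j‖²/roi²); squash radius
1.25·roi, accept 0.5, reject 0.15 — the de-facto constants of the
reference implementation), one rule per center, σ = roi·range/√8. The
range of influence roi defaults to 0.3, the sweep optimum on both
feature sets (grid 0.1–0.6 via `roi_sweep`, winner by test Q%, then
reliability mean/std, then smallest radius).

Hybrid training (default 50 epochs, initial step 0.01): each epoch
re-fits all consequents by global least squares (SVD-based, minimum-norm
on rank deficiency) and moves centers and widths one normalized gradient
step downhill on the MSE, the step taken in range-normalized coordinates
so inputs of different physical scale move comparably. A step that would
increase the training RMSE is rejected and the step size halved, making
the recorded error history non-increasing; training aborts if the error
exceeds 1e6. Firing strengths are normalized in log space (softmax), so
outputs remain the nearest-rule blend arbitrarily far from all centers;
the fallback to the mean rule constant triggers only if every strength
is exactly zero. Classification rounds the continuous output at the 0.5
separator (ties to unstable); RI = 100·|y − 0.5|/0.5 clipped to [0, 100]
since the Sugeno output is not confined to [0, 1].

## Evaluation protocol

Q% = 100·(1 − mismatch fraction); reliability summarized by mean and
unbiased std (0 by convention for a single value). Split: seeded
shuffle, first round(0.6·N) patterns to training. Noise robustness:
models are fit on clean training features; each feature column of both
splits is corrupted with zero-mean Gaussian noise of std =
(level/100)·max|column| (the absolute maximum so sign-spanning features
get a meaningful scale), replicated over 10 noise seeds and averaged.
Re-fitting on corrupted training data is available behind
`corrupt_train=True`. Level 0 reproduces the clean reports bit-exactly.

## Problem sizes and numerical choices

The reference experiment (acceptance script and end-to-end tests) uses
600 patterns — 25 per class per geometry case, the same 4×6 design as
the ~50-per-cell acquisition campaign at half density — which keeps a
full from-scratch run at a few seconds while leaving ≈240 test patterns.
One generator test exercises the full 1239-pattern campaign design.
Candidate ROC cut-points include sentinels outside the value range so
"all stable"/"all unstable" votes are representable. Constant features
draw a degeneracy warning and are skipped in RI_JF (zero normalizer).
Subtractive clustering always returns at least one center (identical
points give exactly one).

## Known limitations

- The simulator's separability is by construction; real trunk sway of
  frail users will overlap between classes, and thresholds, roi and the
  noise findings must be re-estimated on human data.
- The threshold OR-grouping assumes the four extrema are the only
  direction-specific features; adding direction-specific features
  requires extending the groups.
- The DWT feature set discards the a5 approximation, hence very slow
  (<1.5 Hz) sway differences are only visible through leakage into d5;
  with real, unstratified sway spectra this is a genuine failure mode of
  the 9-input set.
- No statistical hypothesis testing between methods is performed; the
  comparison reports the indexes themselves.
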