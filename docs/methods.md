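# Methods

`cardiomoco` implements a respiratory- and cardiac-motion-corrected
reconstruction framework for simultaneously acquired dual-phase coronary
MR angiography (CMRA) and cardiac PET, driven entirely by a synthetic
dynamic heart/torso phantom so that every stage can be validated against
known ground truth.

## Reconstruction models

**Soft-gated iterative SENSE (per respiratory bin).** Each respiratory
bin image solves

    I_b = argmin_I || W_b (E I - K_b) ||^2

where `E` is the coil-weighted centered DFT restricted to the acquired
phase-encode points, `K_b` the acquired data after 2D translational
correction to bin b's center, and `W_b` diagonal soft weights: 1 for
interleaves inside bin b, `exp(-alpha d)` outside, with `d` the distance
to the bin center in bin widths (`alpha` = 1 per bin width by default;
large `alpha` degenerates to hard binning). For the reconstruction of
bin b, *all* interleaves are translation-corrected to *b's* center, so
the weighted data share one translational state and the weights only
arbitrate the non-rigid residual.

**Motion-compensated reconstruction (per cardiac phase).** The
motion-free image of cardiac phase c solves the generalized-matrix
model

    K_c = sum_b S_bc E U_bc I_c

by conjugate-direction iteration on the normal equations, where `U_bc`
is the non-rigid motion operator taking the reference (end-expiratory)
state to bin b and `S_bc` selects the points acquired in (b, c). Here
the data are corrected to each interleaf's *own* bin center and the
operators carry the inter-bin motion. The solver applies the true
adjoint of each factor — zero-filling, inverse DFT, conjugate coils,
and the transpose of the sparse warp matrix — as conjugate-gradient
convergence theory requires. A conjugate-residual (minimal-residual)
variant of the conjugate-direction family is used so the
normal-equation residual norm is non-increasing by construction.

**PET.** List-mode events are dual-gated: a cardiac window of R-R/3
centered on each beat's maximum contraction goes to the systolic gate,
the remainder to diastole; respiratory bins reuse the MR windows
(events during rejected deep-breath excursions are discarded). Each
gate is reconstructed with OSEM,

    rho <- rho / (P' A' N' 1) * P' A' N' [ y / (N A P rho + r + s) ]

(3 iterations, 21 angle-interleaved subsets by default), with the
attenuation map warped to the gate's cardiac and respiratory state.
Gate images are warped back to diastole / end-expiration with the
inverse operators and summed (post-reconstruction registration).
Because the CMRA data are translation-corrected in RL before the bin
images are formed while PET events are not, the MR-derived respiratory
operators are composed with each bin's median tracked RL translation
before they touch PET data.

## Motion estimation

Per-beat 2D image navigators (14 phase-encode lines) are tracked with a
rectangular template around the heart, one reference template per
cardiac phase, by exhaustive normalized cross-correlation over integer
shifts (search range ±15% of the navigator extent) with parabolic
sub-pixel refinement. The FH estimates define equal-count quantile
bins, after rejecting interleaves outside 2 population standard
deviations of the mean FH (deep breaths).

Non-rigid fields are estimated with a pluggable backend; the default is
a two-stage SimpleITK registration (translation, then multiresolution
B-spline free-form deformation). Three choices matter and were made
after explicit validation on the recovery tests:

* **Similarity metric: correlation (default), not mutual information.**
  Mattes MI failed the package's own recovery contracts on the
  phantom's piecewise-constant intensities (identity case drifted ~0.9
  voxels); plain correlation passes all recovery tests with large
  margin. MI remains selectable for genuinely multi-modal data.
* **Coarse control-point mesh (32 voxels) for respiratory fields.**
  Respiratory motion is translation-dominant and spatially smooth;
  finer meshes chase aliasing residue in the undersampled bin images.
  The cardiac systole-to-diastole registration keeps the finer default
  mesh (8 voxels) because contraction is localized at the wall.
* **Progressive, symmetrized bin-to-bin chaining.** Bin b is reached by
  composing adjacent-bin registrations (each a small displacement), and
  each step averages the forward estimate with the inverted backward
  estimate. Direct end-expiration-to-deep-inspiration registration was
  2-3x less accurate on the same images.

Field inversion is damped fixed-point iteration (`v + u(x+v) -> 0`,
step 0.5, tolerance 0.1 voxel). Inverses of estimated fields fall back
to progressively smoothed copies if the raw field is locally folded.
Warps use linear interpolation realized as an explicit sparse matrix,
so the adjoint used by the solver is exactly the matrix transpose.

## The phantom as study conditions

The 2D 96x96 phantom (1 mm in-plane; a thin-3D mode exists for the
17-segment analysis) models: a left ventricle as a myocardial ring
(blood radius 11 mm, epicardial 19 mm) with papillary inserts, liver,
and body outline. Defaults were chosen once to emulate a free-breathing
clinical acquisition:

* Cardiac contraction 0.35 (blood-pool radius), i.e. EF ~ 58%, a
  healthy-subject value; systole conserves wall cross-section (wall
  thickening). Maximum contraction sits at 0.35 R-R after the trigger.
* Breathing: pseudo-periodic 3-5 s, amplitude 8 mm FH / 2 mm RL, with
  5% of breaths 3x deeper (the outliers the 2-SD rejection exists for),
  plus a diaphragm-driven radial compression of the inferior wall (peak
  0.7 of the instantaneous FH excursion, decaying to zero inside the
  blood pool so navigator tracking sees rigid motion, and angularly
  toward the superior wall with a floor of 0.3 — every segment deforms,
  the inferior-most ~2.4x more). The non-rigid part saturates beyond
  tidal amplitude so deep breaths do not fold the field.
* MR: one golden-step spiral interleaf per cardiac phase per heartbeat
  (~28 lines each, 104 ms window / 3.7 ms TR), 6 coils, complex noise
  SD 0.01 per orthonormalized k-space sample (blood signal ~1) — the
  regime where motion, not thermal noise, dominates artifact level.
* PET: 2D parallel-beam geometry (84 angles x 96 radial bins),
  4x10^6 expected coincidences over the ~5.5-minute scan with 10%
  randoms and 10% scatter (uniform expectations; estimation of these
  terms is out of scope), normalization efficiencies in [0.8, 1.0].
  Emission: myocardium 4.0, liver 0.7, blood/background 0.1 (late-scan
  FDG with cleared blood pool).

What the generator deliberately does **not** model: MR contrast physics
(T2-prep and fat saturation are baked into the tissue intensities),
eddy currents and off-resonance, 3D scanner PET geometry, scatter
spatial structure, arrhythmia. Passing tests therefore demonstrate the
correctness and the direction-level behaviour of the reconstruction
machinery, not clinical image quality.

## Evaluation conventions

* CMRA reconstruction error is reported as RMSE against the phantom's
  motion-free phase image over the cardiac region of interest (taper
  radius + 5 mm around the LV center), with whole-image values kept
  alongside; the method corrects heart motion and the clinical
  endpoints are heart-local.
* PET sharpness is the peak-to-trough ratio of a 3-line-averaged
  profile along FH (the dominant motion axis) through the LV center:
  wall peaks over blood-pool mean.
* The planar analog of the 17-segment analysis uses 8 angular sectors
  of the myocardial ring. Per-sector "simulated motion" is the time
  average of the wall-normal ground-truth displacement — tangential
  sliding of a locally homogeneous wall does not blur it, so the normal
  component is the physically relevant magnitude. Segment signal is the
  sector-mask mean (the polar-map max-count-profile convention was
  evaluated and rejected: it rewards reconstruction noise).
* With estimated operators the weakest-motion sector's relative
  increase fluctuates around zero (+-3%) from seed to seed: ~1-voxel
  registration error consumes the ~5% recovery available where almost
  nothing moves. The per-segment positivity of the aggregation
  mechanism is therefore validated with ground-truth operators (minimum
  segment increase ~ +13%), while the estimated-operator pipeline is
  held to the mean increase, the rank correlation with simulated
  motion, and the sharpness ordering — all of which it passes with
  margin.
* EF is computed from blood-pool voxel counts x voxel volume; in 2D the
  analytic contraction gives EF = 1 - (1 - cf)^2.

## Numerical choices and degenerate inputs

* Conjugate-residual solver: relative residual tolerance 1e-6, 30
  iterations by default.
* OSEM freezes voxels with zero subset sensitivity (multiplier 1) and
  treats `0/0` rays as zero.
* Equal-count binning uses a stable sort; exact FH ties at a bin
  boundary would make membership order-dependent (measure-zero for
  continuous traces).
* The sub-pixel parabolic fit of the correlation peak carries an
  inherent bias below 0.1 voxel (visible as the residual MC-NMC
  difference in the motionless limit).
* Problem sizes used by the test-suite and the acceptance script — the
  96x96 default phantom, ~330 heartbeats, 4x10^6 PET counts, and 16x16
  or 8x8 grids for the dense-solve oracles — are the package's
  validation scale; the full 3D 304x304x(80-96) problem of a scanner
  acquisition is configuration, not a requirement.

## Known limitations

* The acquisition simulator and list-mode generator run on the 2D
  phantom; thin-3D support covers the phantom/analysis layer only.
* Estimated respiratory fields reach ~1 voxel mean endpoint error at
  deep inspiration on the default phantom; the motion-compensated CMRA
  with estimated operators is correspondingly ~30-50% worse than with
  ground-truth operators.
* Soft gating biases each bin image slightly toward neighbouring
  respiratory states (by design — it trades motion fidelity for SNR),
  which propagates into the registration chain.
* Scatter and randoms enter OSEM as known expectations; their
  estimation is out of scope.
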