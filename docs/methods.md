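# Methods

This note documents the model, the numerical choices and the synthetic
study conditions behind `rifdecon`, and what the test suite does and does
not demonstrate about real data.

## The forward model and its assumptions

The package treats a dynamic PET voxel or ROI as a linear, stationary
system: tissue activity is the causal convolution of the arterial input
with a perfusion-scaled residue function, `C_tis = f·C_a ⊗ RIF`. The
assumptions inherited from that formulation are

* the physiological state (CBF, permeability) is constant over the scan;
* the AIF measured in the aorta, after an adjustable pure delay ΔT,
  is the input seen by the voxel (no dispersion correction — justified by
  the short aorta-to-brain distance, and deliberately out of scope);
* activity is calibrated and decay-corrected upstream by reconstruction.

On the uniform 1-s grid the model is `C = Δt·A·R` with `A` the
lower-triangular Toeplitz matrix of AIF samples. `Δt` is kept outside `A`
so that changing time units cannot silently rescale the regularization
weight.

All internal computation uses seconds and s⁻¹; perfusion-like quantities
are reported in the conventional mL·min⁻¹·(100 mL)⁻¹ (factor 6000).

## Regularized inversion

`R` is expanded in a clamped cubic B-spline basis (order m = 4,
`k = ⌊n/5⌋` uniform interior knots; both configurable). The spline alone
reduces the unknowns five-fold and enforces C² smoothness; on top of it a
Tikhonov term penalizes the first-derivative seminorm **of R itself**
(`P = L·B`, not a penalty on the coefficients — penalizing V would weight
the knots unevenly and is not the same functional). The solution for each
λ comes from a joint diagonalization of `(DᵀD, DᵀD + PᵀP)` computed once
per AIF and reused across the whole λ grid and across voxels that share
an (aligned) input function; it agrees with a dense normal-equations
solve to better than 1e-8 on well-conditioned test systems.

No positivity or monotonicity constraint is imposed on R: smoothness is
used as the prior, matching the unconstrained penalized formulation.
Negative excursions are retained in the solution, clipped to zero only
for physiology derivations, and reported as a `clipped_fraction`
diagnostic. An optional non-negativity post-projection exists and is off
by default.

### The λ grid and the L-curve corner

λ is chosen at the corner of the L-curve: the point of maximum signed
curvature of (log residual norm, log seminorm) as a function of log λ,
with first and second derivatives from local quadratic (Savitzky–Golay)
fits over a 5-point stencil. Ties break toward larger λ (the smoother
solution). Two practical refinements matter:

* **Grid span.** With a seminorm penalty the component-wise damping
  thresholds are the generalized singular values of (D, P), which for
  these systems extend several decades beyond the largest singular value
  of D. The default grid is therefore 60 log-spaced points over
  `[1e-8·σmax, 1e4·σmax]`; a grid capped at σmax truncates the
  oversmoothing branch and pins the corner to the grid end.
* **Flat-segment masking.** At small λ the spline basis alone fixes the
  solution and neither norm moves; curvature there is numerical noise.
  Grid points whose L-curve speed is below 1e-4 (log units per step) are
  excluded from corner candidacy. If the whole curve is flat every λ is
  equivalent and the largest is returned.

Norm monotonicity (residual non-decreasing, seminorm non-increasing in λ)
is asserted on every run; violations beyond 1e-8 relative trigger a
degenerate-L-curve warning and corner detection falls back to smoothed
norms.

A known limitation, visible in the phantom studies: upsampling the late,
slowly varying frames to 1 s creates many redundant samples, which pulls
the corner toward weaker regularization and mild overfitting of the late
curve — and conversely, under heavy noise the corner oversmooths the
first seconds of R, suppressing the vascular transient and biasing CBF
low for tracers with a large unextracted fraction (FDG, FET). The λ grid
and all corner parameters are exposed in the configuration rather than
hidden behind a heuristic fix.

## Physiology from the recovered R

* **CBF** is read as max(R) rather than R(0): regularization and residual
  delay can shift the peak by a sample or two, and the maximum is the
  standard robust estimator that equals R(0) in the ideal case.
* **Extraction fraction.** A line is fitted by ordinary least squares to
  ln RIF over a tail window, and E is the fitted line evaluated at the
  time of the RIF peak. The default window starts 60 s after the peak —
  by which time a vascular phase with a few-second time constant has
  decayed by many orders of magnitude — and runs to the end of the scan,
  excluding samples below 1e-3 of the peak: at that depth a regularized
  solution is dominated by smoothing error, and because the fit is
  back-extrapolated over hundreds of seconds, log-noise there corrupts
  the intercept far more than it informs the slope. E is clamped to
  [0, 1.05]. A purely mono-exponential RIF (water) yields E = 1 under
  this convention; published values slightly below 1 depend on an
  unstated window choice, so ours is documented rather than guessed.
* **MTT** is the trapezoidal area under RIF plus the analytic integral of
  the fitted mono-exponential tail beyond the scan. If the tail decay
  rate is below 1e-4 s⁻¹ the tracer is effectively trapped: MTT is
  reported as infinite and vd as undefined (NaN), matching the dash
  printed for FDG-class tracers.
* **vd** uses the integral ratio `∫C_tis/∫C_a` when the tissue curve has
  decayed below 10% of its peak by the end of the scan ("returned to
  zero" is thresholded, since no threshold is published), and
  `CBF × MTT` otherwise. For a tracer whose tissue curve is still rising
  at scan end while its global peak is an early vascular transient
  (FET-like), the 10% rule can select the integral ratio before
  equilibrium and underestimate vd; the rule and threshold are
  configurable.
* **K1 = E × CBF** holds exactly by construction; per-voxel products are
  computed (not products of means).

## Arterial delay

Each voxel's arrival delay is estimated before deconvolution from the
segment running from scan start to the tissue peak plus 10 samples, by
fitting `[C_a shifted by ΔT] ⊗ f·e^{−kt}`: ΔT on a 1-s grid search
refined to 0.1 s within ±15 s, k by bounded scalar minimization on
(1e-3, 2] s⁻¹, f in closed form. Grid-then-refine was chosen over joint
nonlinear optimization for determinism and noise robustness. Positive ΔT
means the tissue sees the bolus later than the aorta, and alignment
shifts the **AIF** forward in time (linear interpolation, zero-filled
left edge). Estimates at the ±15 s bound are flagged. Flat voxels (peak
below 3 robust deviations of the series) raise a low-signal error and
are masked rather than fitted.

## Conventional compartment model

The comparison model is the standard two-tissue configuration with blood
volume fraction: `C_tis = Va·C_a + (1−Va)·(C_e + C_i)` with influx K1,
efflux k2, binding k3, back-leak k4, and the closed-form bi-exponential
kernel in the eigen-rates α, β. k4 is fixed to zero by default (an hour
of data cannot support it); water additionally fixes k3 = 0. The kernel
convolution is evaluated analytically for the piecewise-linear AIF (an
exponential integrator implemented as a linear recurrence), so the model
curve matches a high-order ODE integration to ~1e-8 relative and the
fitted rate constants carry no first-order quadrature bias. The repeated
eigen-rate case (e.g. all rates zero) uses the exact `t·e^{αt}` limit
branch. Fitting is bounded least squares (K1 ≤ 300 mL·min⁻¹·100 mL⁻¹,
k2, k3 ≤ 5 min⁻¹, Va ≤ 0.2) from 10 fixed multi-starts spread over the
bound box; uniform weighting by default with optional frame-duration
weights. Note the model has no perfusion: its K1 is a clearance, and its
implicit minimum transit time is zero.

## Synthetic study conditions

The generator emulates the acquisition the method was designed for; its
defaults are the study conditions of the tests.

* **Frame schedules** are the published per-tracer framings: water
  40×1, 5×4, 6×10, 3×20, 2×30, 8×60 s (12 min); FE-PE2I and FET
  40×1, 10×5, 15×10, 6×60, 10×120, 2×300 s (40 min); PIB and FDG the
  same with 6×300 s (60 min).
* **AIF**: gamma-variate first pass (default onset 10 s, shape 3,
  scale 4 s → peak at 22 s, scaled to 100 kBq/mL), plus a recirculation
  copy (15%) dispersed through a 20-s exponential and a slow equilibrium
  tail with a 600-s whole-body washout. Both extras vanish when the
  recirculation fraction is zero, which the analytic-integral tests use.
* **Residue functions** by tracer class: flow-limited
  `exp(−f·t/vd)` (water: CBF 69, vd 90); diffusion-limited
  `(1−E)·e^{−t/τv} + E·e^{−w t}` with vascular τv = 4 s (the vascular
  mean transit time is a few seconds) and w derived from the target vd
  so that CBF × MTT = vd exactly (FE-PE2I: E 0.78, CBF 58, vd 383;
  PIB: E 0.62, CBF 50, vd 288; FET: E 0.032, CBF 53, vd 48); trapping
  with w = 0 (FDG: E 0.19, CBF 37, vd undefined). The bi-exponential
  family is the simplest form with the observed two-phase behaviour; it
  is not a microvascular claim.
* **Noise** is Gaussian with per-frame standard deviation
  `σ0·sqrt(max(C,0)+0.1)/sqrt(duration)` — a Poisson surrogate whose
  variance grows with activity and integrates down with frame length.
  The noisy-recovery tests use σ0 = 0.5, i.e. ~12% relative noise at the
  tissue peak in a 1-s frame, a plausible voxel-level figure for this
  scanner class; delay-recovery tests use σ0 = 0.2 (~5%). True list-mode
  Poisson statistics, scanner PSF, scatter and attenuation are not
  simulated, so passing tests demonstrate correct inversion of the
  stated forward model, not robustness to reconstruction artefacts,
  motion, or model mismatch in real scans.
* **Phantoms** are small 4-D volumes in x-slabs: an aorta surrogate slab
  carrying the framed AIF, one slab per tracer region with optional
  per-region delay, background zero. Identical seeds give bit-identical
  volumes, and truth files round-trip through JSON.

An important pipeline consistency: tissue curves are frame averages
stamped at mid-times and upsampled back to 1 s (shape-preserving PCHIP —
monotone, no overshoot at the 1-s→5-s framing transition; linear mode
available), which acts approximately as a half-sample shift plus box
smoothing. The AIF must pass through the *same* framing and resampling
(as it does when extracted from the aorta region of the framed image);
deconvolving framed tissue against an unframed AIF leaves a systematic
mismatch that biases peak R by several percent.

## Problem sizes and determinism

ROI-level studies run on the native grids (n = 691 samples for the
12-min water framing up to n = 3451 for 60-min framings). Phantom map
studies use 9×6×2 volumes, Monte-Carlo statements use 20–200 seeds, and
every stochastic step takes an explicit seed; serial and parallel
voxelwise runs are bitwise identical, and outputs embed a config hash
for provenance.

## Known limitations

* CBF is biased low by a few percent under realistic noise (the corner
  oversmooths), consistent with the expectation that regularized
  deconvolution slightly underestimates perfusion; the bias grows for
  tracers with a dominant fast vascular phase (FDG, FET).
* The extraction fraction of a genuinely mono-exponential tracer reads
  as 1.0 by the intercept convention, not the 0.94–0.96 that a
  different (unpublished) tail-window choice would produce.
* Metabolite and plasma-to-blood corrections are applied only as
  user-supplied tables; the package ships no tracer-specific correction
  curves.
* Dispersion correction, motion correction, spatial smoothing and
  registration are out of scope.
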