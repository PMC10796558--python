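# rifdecon

Model-free estimation of tissue perfusion and the residue impulse response
function from high-temporal-resolution dynamic PET.

Long-axial-field-of-view PET scanners are sensitive enough to frame the
tracer bolus passage at 1 s. At that resolution the fundamental
indicator-dilution relation

```
C_tis(t) = f · C_a(t) ⊗ RIF(t),        R(t) = f · RIF(t)
```

can be inverted directly — no compartment model — for *any* tracer,
whether freely diffusible (water), diffusion-limited (PIB, FE-PE2I, FET)
or trapped (FDG). Here `C_tis` is the tissue time-activity curve,
`C_a` the arterial input function (image-derived from the descending
aorta), `f` is perfusion (CBF), and RIF(t) is the residue impulse
response: the fraction of an instantaneous tracer bolus still in the
tissue `t` seconds after delivery (RIF(0) = 1, non-increasing).

Deconvolution of the first-kind Volterra system is ill-posed, so the
package solves it by Tikhonov regularization:

* R is expanded in a clamped cubic B-spline basis, `R = B V`, with one
  coefficient per ~5 samples;
* `V` minimizes `‖Δt·A·B·V − C_tis‖² + λ²‖L·B·V‖²`, where `A` is the AIF
  Toeplitz matrix and `L` the discrete first-derivative operator acting
  on R;
* λ is selected at the corner (maximum curvature) of the L-curve — the
  log-log trade-off between residual norm and solution seminorm.

From the recovered R the package derives, per ROI or per voxel:

| quantity | definition | units |
|---|---|---|
| CBF | peak of R | mL·min⁻¹·(100 mL)⁻¹ |
| E | extraction fraction, back-extrapolated amplitude of the slow RIF tail | — |
| K1 | E × CBF, unidirectional influx constant | mL·min⁻¹·(100 mL)⁻¹ |
| MTT | area under RIF (+ analytic tail) | s |
| vd | distribution volume, ∫C_tis/∫C_a or CBF × MTT | mL·(100 mL)⁻¹ |
| ΔT | arterial transit-time delay, fitted per voxel within ±15 s | s |

A conventional two-tissue compartment model (K1, k2, k3, k4, Va; Laplace
closed-form kernel, constrained multi-start fitting) is included for
comparison, and a synthetic generator produces AIFs, tracer-class residue
functions, framed noisy TACs and 4-D phantoms with known ground truth.

## Worked example

Simulate a PIB-like thalamus curve (60-min framing, 6-s arterial delay)
and invert it:

```python
import numpy as np
import rifdecon as rd

preset = rd.TRACER_PRESETS["pib"]            # CBF 50, E 0.62, vd 288
sched = preset.schedule                      # 40×1 s ... 6×300 s frames
t = np.arange(0.0, sched.total_duration, 1.0)

aif_fine = rd.default_aif(t)                 # aorta-like input, peak 100 kBq/mL
rif = rd.ground_truth_rif(preset.spec, t, cbf_s=preset.cbf_per_s)
tissue = rd.simulate_tissue_tac(aif_fine, preset.cbf, rif,
                                delta_t=6.0, schedule=sched)
aif = rd.FramedCurve(sched.mid_times, sched.frame_average(t, aif_fine.c))

results = rd.TikhonovDeconvolution(tissue, aif).fit()
print(results.summary())
```

```
Tikhonov model-free deconvolution
==============================================
CBF                               48.4  mL/min/100mL
Extraction fraction E            0.638
K1 = E x CBF                      30.9  mL/min/100mL
MTT                              357.2  s
vd                               286.7  mL/100mL
Arterial delay dT                  4.7  s
----------------------------------------------
lambda (L-curve corner)          0.272
negative-R fraction              0.000
n time points                     3451
```

The estimates sit within a few percent of the phantom truth (CBF 50,
E 0.62, vd 288) and K1 reproduces the published thalamus value of
31 mL·min⁻¹·100 mL⁻¹ for this tracer class. The same data fitted with the
conventional irreversible two-tissue model give K1 = 31.0, k2 = 0.107
min⁻¹ (`rd.TwoTissueCompartment(tissue, aif, fixed={"k4": 0.0}).fit()`).

Voxelwise maps come from the command line:

```bash
rifdecon simulate --tracer-preset water --seed 3 --shape 16 16 4 \
    --out phantom.nii --truth truth.json
rifdecon run --pet phantom.nii --schedule phantom_frames.json \
    --aorta-mask phantom_aorta.nii --labels phantom_labels.nii --out maps/
```

producing one NIfTI per parameter (cbf, mtt, delay, vd, e, k1 plus
diagnostics), a provenance sidecar and a region-summary TSV.

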