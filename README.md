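# echocorrect

Echo-intensity artifact correction for ring-array ultrasound computed
tomography (USCT).

## The problem

In reflection-mode USCT a 2048-element annular transducer surrounds the limb
and reconstructs echo-intensity slices. Echo intensity (EI) is a quantitative
biomarker — elevated muscle EI indicates fat/connective-tissue infiltration
and supports sarcopenia assessment — but two acquisition-geometry effects
bias it systematically:

* **Eccentricity artifact.** Beam overlap at the ring centre and the reduced
  effective channel count at the periphery produce a radial
  "centre-brightening, edge-darkening" pattern. For a multiplicative
  beamformer (DMAS) the output magnitude scales as `N_eff(ρ)²·A(ρ)²`, which
  amplifies the radial sensitivity difference.
* **Inclination artifact.** Where the limb surface is tilted with respect to
  the imaging plane, specular echoes deflect away from the receiving
  elements and the reconstructed intensity drops.

`echocorrect` implements both corrections, the interface acoustics behind
them, four uniformity metrics to score them, and a synthetic phantom
generator with exact per-pixel ground truth, so the whole method can be
developed and validated without USCT hardware.

## Method at a glance

**Radial (eccentricity) correction** — calibration–estimation–compensation:

1. a uniform phantom is imaged through the ordinary pipeline, giving the
   calibration frame `I_cal(x, y)`;
2. the radial profile `S(ρ)` is the annular mean of `I_cal` over
   `Ω(ρ) = {(x,y): ρ−Δ ≤ ρ(x,y) < ρ+Δ}`, smoothed with a Savitzky–Golay
   local cubic regression (33-sample window) into `S̃(ρ)` and normalised as
   `Ŝ(ρ) = S̃(ρ)/S̃(0)`;
3. the gain `G(ρ) = 1/(Ŝ(ρ)+ε)` is clipped at `G_max` inside the effective
   radius `R_eff` and zeroed beyond it, then applied pixel-wise:
   `I_corr = G_clip(ρ)·I` (linear amplitude domain).

**Inclination correction** — incident-angle gain:

1. the surface contour of the target slice is extracted from a maximum
   intensity projection of the slices below it (threshold + morphology);
2. the per-pixel incident angle is `θi = arctan(radial shift of the
   boundary / slice spacing)`, interpolated and smoothed over the
   near-surface band;
3. Snell's law `sinθi/c_i = sinθt/c_t` and the pressure transmission
   coefficient `T(θi) = 2 z_t cosθi/(z_t cosθi + z_i cosθt)` give the gain
   `G(θi) = T(0)/max(T(θi), ε)` (clipped at `G_max`), applied as
   `I_corr = I + κ·C(θi)` in dB with `C = 20·log10 G`, or `I·G^κ` in the
   linear domain. The strength κ can be auto-tuned by minimising the
   overflow rate (fraction of pixels leaving a preset display window).

**Uniformity metrics** — RIS (radial intensity slope), CPR
(centre-to-periphery ratio), RNU (radial non-uniformity index) and CV
(coefficient of variation), all scale-invariant, with paired before/after
comparison (exact Wilcoxon signed-rank).

## Worked example

```python
import echocorrect as ec

# a uniform phantom imaged under a radial sensitivity field
# (edge 40% darker than the centre)
spec = ec.PhantomSpec(fov_radius_px=128.0)
cal, truth = ec.make_calibration_phantom(spec, ec.SensitivityModel.gaussian(0.6))

result = ec.RadialCalibration(cal).fit(epsilon=1e-3, g_max=2.0, r_eff=0.95 * 128)
print(result.summary())

corrected = result.apply(cal)
print(ec.compute_metrics(cal, r_eff=0.95 * 128))        # before
print(ec.compute_metrics(corrected, r_eff=0.95 * 128))  # after
```

prints

```
Radial sensitivity calibration
==============================================
annuli (retained)            129
annulus half-width           0.5 px
SG window / order         33 / 3
epsilon                    0.001
G_max                          2
R_eff                     121.60 px
S_hat range           [0.5682, 1.0000]
gain range (raw)      [0.9990, 1.7569]
annuli clipped at G_max        0
UniformityMetrics(ris=0.404, cpr=1.429, rnu=0.424, cv=0.147, ...)
UniformityMetrics(ris=0.0005, cpr=1.0004, rnu=0.0004, cv=0.0002, ...)
```

The estimated profile `Ŝ` drops to 0.57 at the rim (the imposed field), the
raw gain tops out at 1.76 (below the 2.0 ceiling), and the self-corrected
phantom is flat: CPR returns to ~1 and RIS/RNU/CV collapse by three orders
of magnitude.

The command-line interface mirrors the library:

```bash
echocorrect simulate --kind calibration --out sim/ --seed 1
echocorrect calibrate-radial --cal sim/phantom.tif --out gain.csv --gmax 2.0
echocorrect correct --mode eccentricity --gain gain.csv --in sim/phantom.tif --out corr.tif
echocorrect metrics --before sim/phantom.tif --after corr.tif --out report.csv
echocorrect physics-curves --sweep rt --out rt.csv
```

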