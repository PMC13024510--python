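# Methods

## Scope and model

`echocorrect` corrects two multiplicative intensity artifacts of
reflection-mode ring-array ultrasound tomography on *reconstructed* images.
It does not model wave propagation, beamforming, or refraction-corrected ray
tracing: the working assumption throughout is that each artifact acts as a
smooth multiplicative field on the linear-amplitude image —

```
I_observed(x, y) = I_true(x, y) · S(ρ(x, y)) · A(θi(x, y))
```

with `S` the radial sensitivity of the ring (eccentricity artifact) and `A`
the interface transmission factor at the local incident angle (inclination
artifact). Both corrections invert their factor independently; the default
pipeline order applies the radial gain first (in-plane uniformity), then the
angle gain (inter-slice consistency). The order is configurable because the
two factors commute exactly under the multiplicative model; on real data the
order can matter only through estimation error.

## Radial sensitivity calibration

* **Annular binning.** Δ = 0.5 px half-width with stride 2Δ, i.e. dense
  1-px annuli with half-open intervals `[ρ−Δ, ρ+Δ)`. This is the finest
  binning that keeps every annulus non-empty on grids of 256² and larger
  with an integer-centred FOV. On even-sized grids the geometric centre
  falls between pixels and the innermost annulus can be empty; empty annuli
  are dropped and the profile is normalised at the innermost *retained*
  radius.
* **Smoothing.** Savitzky–Golay local polynomial regression, order 3,
  window 33 samples (the nearest odd realisation of a 32-sample window —
  the filter requires odd windows). Cubic profiles are reproduced exactly;
  windows that exceed the profile length shrink automatically to the
  largest valid odd size, with a logged warning.
* **Stabiliser and limits.** ε = 1e-3 (relative to Ŝ(0) = 1): negligible
  bias where the profile is of order one, prevents blow-up where Ŝ → 0.
  G_max defaults to 1.75, the midpoint of the typical 1.5–2.0 range, and is
  meant to be raised when the data are clean: the ceiling exists to limit
  noise amplification, so noiseless synthetic studies that need gains above
  2 (a 0.35 edge-ratio field needs up to 1/0.35 ≈ 2.9) run with
  G_max = 3.0. R_eff defaults to 0.95 of the profiled radius, excluding the
  probe's blind region near the array.
* **Evaluation between tabulated radii.** The ceiling is applied to the
  tabulated curve *before* linear interpolation (so clipping stays exact)
  and the R_eff mask is applied *after* it (so the cut-off is sharp).
  Constant extrapolation is used towards ρ = 0 and beyond the last annulus.
* **Centre definition.** All radii are measured from the imaging-circle
  (array) centre, never the object centroid: the artifact belongs to the
  system, so the correction is a pure radial gain and does not recentre the
  object.
* **Reuse across slices.** One gain per acquisition geometry, reused for
  every slice of a stack. Per-slice recalibration is possible by
  constructing one `RadialCalibration` per slice but is not the default.

## Incident-angle estimation and gain

* **Stack orientation.** Slice 0 is the bottom (deepest) slice; "below"
  means smaller indices. A stacked-cone phantom therefore has its largest
  boundary radius at index 0 and shrinks by
  `slice_spacing·tanθ/pixel_spacing` px per slice.
* **Surface contour.** The target slice's foreground comes from its own
  segmentation (Otsu threshold inside the FOV, opening and closing with a
  2-px disk, largest component, hole filling), falling back to the MIP of
  up to `mip_depth = 3` slices below when its own surface echo is too weak.
  The bottom slice has no slices below and falls back to the slices above,
  flagged `filled_from_adjacent`.
* **Angle estimation.** For each of 256 polar sectors the mean boundary
  radius is regressed on the axial position across the target and its lower
  slices; `θi = arctan|dr/dz|`. Averaging boundary pixels within a sector
  gives sub-pixel radii, and any constant quantisation bias cancels in the
  slope. Sectors whose boundary leaves the FOV are filled by periodic
  interpolation from neighbouring sectors and flagged. The sector angles
  are painted on the near-surface band (5 px inward of the boundary),
  smoothed with a mask-normalised Gaussian (σ = 5 px) so interior zeros do
  not bleed into the band, and clipped to [0°, 90°). The flat interior far
  from the surface keeps θi = 0: the physics concerns the entry interface,
  and inventing interior angles would extrapolate beyond the model.
  On the reference cone stacks (8 slices, 4 mm spacing, 110 px base
  radius) the recovered median boundary angle is within 0.1° of the true
  half-angle at 0/10/20/30°.
* **Gain direction.** The default gain is the literal pressure form
  `G(θi) = T(0)/max(T(θi), ε)` with `T` the pressure transmission
  coefficient. For a water→tissue interface `T(θi) ≥ T(0)` below the
  critical angle, so the literal gain *darkens* oblique regions; the opt-in
  `mode="round_trip"` uses the intensity transmission `1 − R_p²`, which
  decays with angle and therefore brightens them. Both directions are kept
  because the physically appropriate choice depends on what the
  reconstruction pipeline has already normalised; each mode is the exact
  inverse of the matching forward model in the phantom generator, and the
  matched-media case is the identity in both.
* **Supercritical incidence.** Snell refraction returns NaN beyond the
  critical angle `arcsin(c_i/c_t)`; coefficients are then evaluated with
  `cosθt = 0` (total reflection). The gain's ε floor and G_max ceiling keep
  the correction finite there, and a warning is logged when more than 5% of
  boundary angles exceed 60°, where contour extraction becomes unreliable
  and under-correction is expected.
* **κ selection.** Grid search over {0, 0.1, …, 1.5} minimising the mean
  overflow rate — the fraction of in-mask pixels outside the display
  window, by default the 1st–99th percentile of the uncorrected slices.
  Ties break towards smaller κ, so the identity wins when nothing
  overflows. The objective is a fraction and always lies in [0, 1].

## Interface acoustics and directivity

Default media: water (c = 1480 m/s, ρ = 1000 kg/m³) coupling into generic
soft tissue (c = 1540 m/s, ρ = 1050 kg/m³), z = ρc. Longitudinal waves
only; shear conversion at the skin is neglected. The intensity convention
satisfies `R_I + T_I = 1` below the critical angle by construction and
`T_I = 0, R_I = 1` beyond it. Element directivity uses the standard
far-field line-aperture pattern `|sinc(w·sinθ/λ)|`; the default element
width is the circumferential pitch of a 222 mm-diameter, 2048-element ring
minus a 10% kerf (≈ 0.31 mm), the only geometry the probe specification
fixes. The module reproduces the qualitative angular curves, not any
specific simulator's field maps.

## Synthetic phantoms

The generator emulates: (a) a uniform cylindrical calibration phantom under
a parametric radial sensitivity field (Gaussian decay by default,
polynomial and DMAS `N_eff²A²` forms as alternatives — the Gaussian's
`edge_to_center_ratio` is a free fixture parameter, referenced to
R_eff = 0.95·FOV, the radius the gain itself operates on); (b) an
eccentricity phantom with circular scatterer targets at graded radii;
(c) stacked-cone inclination phantoms with half-angles 0–30°, the slanted
surface rendered as a 3-px bright annulus attenuated by the interface
factor; and (d) limb-like slices — a disk with a bright 4-px skin rim and
seeded uniform ±5% interior texture, degraded by the sensitivity field and
an optional uniform tilt attenuation.

Generation is deterministic per (spec, seed); speckle noise (multiplicative
Rayleigh, seeded) is available but off by default, so the ground-truth
identity `generated = clean × sensitivity × transmission` holds exactly and
every oracle is exact. What the phantoms deliberately do **not** emulate:
speckle statistics of real reconstructions, refraction-induced geometric
distortion, depth-dependent attenuation, and anatomical heterogeneity.
Passing the synthetic suite therefore demonstrates that the estimation and
compensation machinery is correct under the stated multiplicative model,
not that the model captures every effect in vivo.

## Reference studies and known limitations

The two reference studies (512×512 grids, six limb slices — sizes chosen so
each study completes in seconds while the annular statistics remain dense)
are implemented in `echocorrect.experiments`:

* *Uniform-phantom self-calibration* (edge ratio 0.6, ε = 1e-3,
  G_max = 2.0): the corrected phantom's CPR returns to 1.000 and its RNU
  falls below 0.001.
* *Limb study* (edge ratio 0.35, G_max = 3.0): RIS, RNU and CV drop by
  ~99/99/90%, CPR by ~52%.

**Structural ceiling on the CPR reduction.** CPR of the corrected image
cannot drop below 1 (a perfect correction makes the image flat), so the
attainable percentage reduction is capped at `1 − 1/CPR_before`. Under the
0.35 Gaussian field the uncorrected limb scores CPR ≈ 2.08, capping the
reduction at ≈ 52% regardless of correction quality. Stronger artifact
fields raise the ceiling; the study keeps the stated field strength and
reports the measured value honestly.

Other known limitations: the gain model is 2-D per slice (no slice-coupled
estimation); G_max adaptation to SNR is manual; angle estimation degrades
when the surface echo is weak, the incident angle is large, or fewer than
two usable boundaries exist (errors are raised rather than guessed); and
the inclination correction only compensates transmission loss — it cannot
recover echoes that never reached the array.
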