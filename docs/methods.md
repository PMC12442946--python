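# Methods

## Scope and design

`echopanc` couples two pipelines that share one synthetic data source:

1. **Biomarker screening** — masked-region feature extraction from B-mode
   images followed by univariate statistics against a binary diabetes
   label.
2. **Therapeutic-ultrasound (TUS) thermal simulation** — layered-tissue
   acoustic/bioheat modelling with CEM43 safety dosimetry.

The package is organised as a library (`echopanc.synthetic`, `.images`,
`.features`, `.screening`, `.thermal`, `.pipeline`) with narrative scripts
under `examples/` and a thin `echopanc` CLI for the shell-runnable
simulation/pipeline stages.

## Synthetic B-mode phantom cohort

### Speckle model

A phantom texture is the magnitude of a complex circular-Gaussian field
whose real/imaginary parts are Gaussian-smoothed (correlation length in
pixels) and renormalised to unit variance, so the pointwise envelope is
exactly Rayleigh(1) at every smoothing level. The envelope is
log-compressed through a **fixed** −35…+40 dB window (no per-image
normalisation, so class effects are not silently re-scaled) and quantised
to 8 bits. The wide upper window keeps sparse hyperechoic foci unclipped.

### Region geometry

The pancreas mask is an ellipse with low-order (modes 2–5) Fourier boundary
perturbation — always simply connected, so perimeter and eccentricity are
well defined. Area, depth, lateral position and elongation are sampled per
image; a blob exceeding the frame is retried with a 10% shrink (≤ 10
attempts). Defaults: 160×192 px at 0.4 mm/px; non-diabetic area
420 ± 55 mm², depth 3.6 ± 0.4 cm, aspect 1.8 ± 0.15.

### Class contrasts

The generator's defaults ARE the study conditions; magnitudes are package
choices (not literature-calibrated), chosen once so that the documented
*directions* of every class difference are reproduced with comfortable
margins at n = 40 per class, and then frozen. The diabetic (DM) class
differs from non-DM by:

| knob | non-DM | DM | drives |
|---|---|---|---|
| area multiplier | 1.0 | ×0.8 | area ↓, perimeter ↓ |
| depth shift | — | −0.5 cm | centroid_y ↓ |
| lateral shift | — | −0.3 cm | centroid_x ↓ |
| elongation | 1.0 | ×1.15 | aspect ratio ↑, eccentricity ↑ |
| speckle correlation length | 1.2 px | ×1.5 | LBP energy ↑, entropies ↓ |
| coarse speckle fraction (6 px scale) | 0.65 | 0 | GLCM correlation ↓ in DM, IMC2 ↓ |
| hypoechoic foci (r ≈ 3 px) | density 0.08/mm² | off | intensity entropy ↓ in DM, variance family ↓ |
| hyperechoic spots (r ≈ 0.9–2 px) | weak/broad | few, strong (×e³·⁴) | min–max range stretch ⇒ ASM ↑, IDM ↑, sum average ↓ |
| per-pixel envelope noise | 0.28 Np | 0 | IMC1 ↓ in DM |
| shading amplitude (14 px scale) | 0.3 | 0.15 | large-scale heterogeneity |

Two mechanisms deserve explanation because a single "smoothing" knob cannot
produce the full documented sign pattern (a class cannot be simultaneously
more uniform, less neighbour-correlated, lower in IMC2 *and* lower in IMC1
through one parameter):

* the **coarse speckle mixture** adds a second, longer-scale complex field
  carrying 65% of the non-DM power. Sums of circular Gaussians stay
  circular Gaussian, so the marginal stays Rayleigh while the non-DM
  neighbour correlation and pairwise information rise — this is what makes
  GLCM correlation and IMC2 *lower* in DM even though DM speckle is
  smoother;
* the **DM hyperechoic spots** stretch the in-mask dynamic range with
  negligible probability mass. Because GLCM quantisation is min–max over
  the region, the DM bulk then concentrates into few bins (ASM/IDM up, all
  entropies down) and sits low in its range (sum average down) without any
  change to the underlying speckle.

The per-pixel envelope noise in non-DM raises its marginal entropy without
adding pairwise information, lowering the non-DM ratio MI/H(marginal) that
IMC1 measures. IMC1 and the SIFT count have the smallest standardised class
margins (|d| ≈ 0.4–0.8); all others exceed |d| ≈ 0.9.

Setting every knob equal across classes (`null_spec`) gives exchangeable
classes for type-I-error calibration.

### Seeds and cohorts

Per-image seeds derive from `SeedSequence((master_seed, patient, image))`;
every generator is a pure function of its spec. The cohort builder emits a
metadata table (id, dm_status, age, sex, n_images) mirroring a 22-patient
clinical roster.

### What the phantoms do not model

No point-spread-function convolution of a scatterer map, no attenuation or
focusing gradients within the image, no probe/operator variability, no
anatomical sub-regions (head/body/tail are annotation labels, not separate
blobs). Passing tests therefore demonstrate that the *pipeline* recovers
planted statistical structure at realistic sample sizes — not that real DM
pancreata carry that structure.

## Feature conventions (fixed because values depend on them)

* GLCM: in-mask min–max quantisation to 32 levels; distance 1; the four
  offsets 0°/45°/90°/135° **accumulated** (not averaged per angle), then
  symmetrised and normalised. Pairs are counted only when both endpoints
  are in-mask, which keeps boundary pixels from contaminating texture.
* Entropies in bits (log₂), `0·log 0 := 0`; IMC2 uses
  `sqrt(1 − exp(−2(HXY2 − HXY)))` with bit-valued entropies; level indices
  are 0-based.
* Degenerate (single-level) regions yield limit values (ASM = IDM = 1,
  entropies 0, LBP energy 1) with a flag, keeping cohort tables
  rectangular.
* LBP: rotation-invariant uniform mapping, P = 8, R = 1, computed for
  pixels whose full neighbourhood is in-mask and inside the frame.
* Perimeter: marching-squares contour smoothed by a 5-point circular
  moving average before length summation (the raw staircase overestimates
  smooth boundaries by ≈ 7%; smoothed, a circle is recovered within ~1%).
* Gradient: mean of `hypot(sobel_h, sobel_v)/2` (unit ramp ⇒ 1 gray/px)
  over interior pixels.
* SIFT: difference-of-Gaussians detector (contrast threshold
  0.04-equivalent, edge ratio 10), counted inside the mask; detection runs
  on the padded mask bounding box, which matches full-frame detection for
  in-mask keypoints at much lower cost.
* Centroids are emitted both in pixels and cm; screening uses cm.

## Screening statistics

Pooled-variance Student t (df = n₁+n₂−2; the 24 + 24-region worked example
gives df = 46), oriented DM − non-DM; strict `p < α` retention, no
multiple-testing correction by default (a Benjamini–Hochberg option
exists). Spearman ρ uses midrank ties; mutual information is the k-NN
estimator (k = 3) in nats, clipped at 0. AUC is the tie-corrected
Mann–Whitney probability on the feature's ascending orientation — never
sign-flipped, so anti-predictive features report AUC < 0.5. The univariate
logistic fit (unregularized, on z-scores) supplies coefficients and a
perfect-separation flag; because its link is strictly monotone in the
single predictor, each bootstrap replicate's AUC equals the rank AUC of the
resample, which the stratified bootstrap (resampling within class at the
original class sizes; percentile 2.5/97.5 interval; n = 2000) computes
directly.

## Thermal model

* **Acoustics.** Unfocused: collimated plane-piston beam of the aperture
  size. Focused: O'Neil on-axis gain for a spherically curved radiator,
  `|p/p₀| = 2|sin(kδ/2)|/|1 − z/F|`, with the removable singularity at the
  focus replaced by its limit `kh`. The radial profile is a Gaussian whose
  width conserves the attenuated beam power through each z-plane. For the
  default low-gain geometry (1.5 cm aperture, 2–8 cm focus at 1 MHz) the
  axial maximum sits proximal to the geometric focus — the classical focal
  shift — and this is intentional, not an artefact.
* **Attenuation.** Layer dB/cm values are amplitude coefficients, linear
  in frequency; intensity transmission is `10^(−2·Σαᵢfdᵢ/20)` and heating
  is `q = 2 α_Np I · duty`. Duty gating is time-averaged by default (pulse
  period ≪ thermal time constant); explicit on/off gating integrates the
  exact on-window overlap per solver step so coarse steps cannot alias the
  duty factor.
* **Bioheat.** Explicit finite differences on an axisymmetric (r, z) mesh,
  Δr = Δz = 0.5 mm, radial extent 4 cm, fixed 37 °C boundaries, axis
  symmetry at r = 0, harmonic-mean conductivity at layer interfaces,
  auto-computed stable Δt (safety 0.8). Thermal conductivities are
  literature placeholders (skin 0.37, muscle 0.49, pancreas 0.51, blood
  0.52, bowel 0.55 W/m/K) — they are not part of the published acoustic
  table. Perfusion defaults to 0 (blood is modelled as a layer); a Pennes
  sink is available per layer.
* **Reference solver.** Separately coded ((z, r) layout, ghost-cell rolls,
  fused flux assembly, 0.25 mm mesh, safety 0.7). On the default validation
  protocol the two solvers agree to 0.28 °C RMSE of the on-axis
  temperature histories.
* **Dosimetry.** CEM43 accumulates `R^(43−T)Δt` (R = 0.5 for T ≥ 43 °C,
  0.25 below) trapezoidally over 1 s-sampled snapshots; per-node maxima
  over *all* solver steps back the temperature verdicts.
* **Safety thresholds.** CEM43 < 240 equivalent minutes in every tissue
  and pancreatic peak < 40 °C; duty factors ≥ 75% carry an advisory
  avoid-flag. A "maximum abdominal temperature < 135 °C" criterion that
  sometimes accompanies these limits is physiologically implausible and is
  treated as a typographical artefact — only the CEM43 and pancreatic
  bounds are enforced.

### Default stand-in geometry

Skin 0.2 / muscle 1.2 / bowel 1.8 / blood 0.3 / pancreas 2.5 cm (6 cm
total, pancreas proximal boundary at 3.5 cm — mid-range for pediatric
abdomens, within the 7 cm cap the validation harness imposes). Default
transducer: focused, 1.5 cm aperture, 4 cm focal depth, 1 MHz. The
geometry-sampling module draws layer thicknesses so the pancreas boundary
falls in the observed 2–6 cm band.

With this pancreas-targeted default, the sub-100%-duty protocol grid is
**not** thermally safe in the model: the worst cell (10 W/cm², 75% duty,
5 min) drives the focal region of the pancreas far beyond the 40 °C /
240 CEM43 limits. This is a robust consequence of energy conservation —
a 1.5 cm aperture delivering several W/cm² of time-averaged intensity
through ~5 dB of overburden deposits a pancreatic temperature rise of tens
of kelvin wherever the beam lands, for any focal placement inside a ≤ 7 cm
domain — and the package reports the computed values rather than a
geometry tuned to pass. The 100%-duty single run (5 W/cm², 5 min, focus at
the pancreas boundary) peaks at ≈ 85 °C, confirming the direction that
full-duty focused sonication grossly overheats.

## Problem sizes used by the test suite

Unit oracles run on ≤ 16×16 images (exact, 1e-10). Calibration checks use
200 replicate null cohorts of 8 + 8 small (64×80) phantoms; effect-direction
recovery uses 20 replicate default cohorts of 60 + 60 phantoms; bootstrap
coverage uses 200 Gaussian cohorts of 44 + 46 with 2,000 resamples each.
These sizes make the statistical checks sharp while keeping the default
suite a few minutes long.

## Known limitations

Linear acoustics only (no nonlinear propagation, cavitation or mechanical
index); no 3-D or patient-specific meshing; the speckle phantoms are
stationary textures without imaging physics; screening is univariate by
design — no multivariate models or cross-validation; reported MI values
depend on the estimator family and are not comparable across estimators.
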