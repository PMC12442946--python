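# echopanc

Quantitative image-feature screening of the pancreas in B-mode ultrasound,
and patient-geometry-informed therapeutic-ultrasound (TUS) thermal safety
simulation — built for researchers prototyping ultrasound biomarkers of
diabetes mellitus (DM) and mild-hyperthermia insulin-release protocols.

Pediatric pancreatic ultrasound collections are not publicly deposited, so
the package ships a first-class **synthetic cohort generator**: seeded,
speckle-textured B-mode phantoms containing a pancreas-shaped region whose
size, depth, elongation and texture statistics differ by diabetic class in
the directions reported for real DM pancreata (smaller, shallower, more
elongated, texture more *uniform* — higher co-occurrence uniformity and LBP
energy, lower entropies). Every downstream stage is testable end to end
without any data download.

## What it computes

**Radiomics screening.** From each masked region the package extracts 23
features: morphology (area `A = N·s²`, marching-squares perimeter,
centroid, aspect ratio, eccentricity), first-order intensity entropy
`H = −Σ pᵢ log₂ pᵢ`, mean Sobel gradient, the 13 classical co-occurrence
(Haralick) statistics of a masked-pair, 32-level, distance-1 GLCM
(e.g. ASM `= Σ p²`, IDM `= Σ p/(1+(i−j)²)`, entropy, IMC1/IMC2),
rotation-invariant uniform LBP histogram energy/entropy (P=8, R=1), and a
SIFT keypoint count. Features are screened univariately: pooled-variance
Student t-test gate (`df = n₁+n₂−2`, retain `p < α`), Spearman ρ against
class, −log₁₀(p) ranking, k-NN mutual information (k=3, nats), and a
z-scored univariate logistic fit whose discrimination is the tie-corrected
Mann–Whitney AUC of the feature's **ascending orientation** (no
sign-flipping, so anti-predictive features report AUC < 0.5), with a
stratified-bootstrap percentile 95% CI (2,000 resamples preserving class
proportions).

**Thermal simulation.** A layered abdominal stack
(skin/muscle/bowel/blood/pancreas with literature acoustic properties) is
sonicated by a focused (O'Neil on-axis gain, energy-conserving Gaussian
radial envelope) or unfocused (plane-piston) 1.5 cm circular transducer.
Heating `q = 2αI·duty` drives an explicit axisymmetric Pennes bioheat
solver (`ρc ∂T/∂t = ∇·(k∇T) − w_b c_b (T−37) + q`), and Sapareto–Dewey
thermal dose `CEM43 = Σ R^(43−T) Δt` (R = 0.5 above, 0.25 below 43 °C)
feeds per-tissue safety verdicts (CEM43 < 240, pancreatic peak < 40 °C,
duty ≥ 75% flagged). An independently coded fine-grid reference solver
provides in-repo RMSE validation.

## Worked example

```sh
python examples/03_screen_biomarkers.py
```

builds a 30 vs 30 phantom cohort, extracts all features and prints the
retained screening table; on this machine the head of the output is

```
retained 21/23 features at p < 0.05
      feature  t_value  p_value  spearman_rho  mi_score   auc  auc_ci_low  auc_ci_high
   lbp_energy   28.534    0.000         0.864     0.693 1.000       1.000        1.000
 haralick_idm   28.436    0.000         0.866     0.693 1.000       1.000        1.000
 haralick_asm   27.469    0.000         0.866     0.702 1.000       1.000        1.000
```

Here `t_value` is oriented DM − non-DM, so texture-uniformity features
(LBP energy, Haralick IDM/ASM) are *higher* in the diabetic class and
separate it almost perfectly at the generator's default effect sizes, while
entropy-family features carry negative t — the documented direction
pattern. `mi_score` is in nats (ln 2 ≈ 0.69 is the maximum for a balanced
binary label); an `auc_ci_low` above 0.5 marks a stable univariate
discriminator.

```sh
python examples/04_thermal_safety_simulation.py   # bioheat + CEM43 verdicts
python examples/05_dual_solver_validation.py      # dual-solver RMSE (0.28 °C)
echopanc demo --out run_demo --seed 1             # full pipeline, all artifacts
```

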