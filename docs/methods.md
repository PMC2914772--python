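# Methods

## Measurement model

`eatq` measures structures traced on short-axis cardiac image stacks. A
tracing is an ordered planar polygon in millimetres; a structure on one
slice may consist of several disjoint outer contours and excluded holes
(epicardial fat in particular often forms disjoint patches, and a
circumferential fat ring is encoded as an outer contour with the
epicardial border as a hole). Areas are computed as shoelace magnitudes
(via `shapely`), so they are orientation-, translation- and
rotation-invariant; self-intersecting or degenerate polygons are rejected
at load time with an error naming the slice and structure.

Volumes use the stacked-slab form of Simpson's rule: the net area of each
slice times the effective slice spacing, summed over the stack. The
spacing is **thickness + inter-slice gap**, not thickness alone: cine
acquisitions with 5 mm slices and 5 mm gaps tile the ventricle only if the
gap is attributed to the adjacent slice, and thickness-only integration
would halve every volume. No end-correction is applied at the base or
apex; slices without tracings contribute zero. Mass conversion is exact
linearity: fat at 0.92 g/ml, myocardium at 1.05 g/ml. The myocardial
density is a standard literature constant; it is recorded in
`AnalysisConfig` and in every report bundle. LV mass from contours is
(epicardial − endocardial volume) × 1.05 at end-diastole.

Derived subject-level quantities: BMI = weight/height²; BSA by DuBois,
0.007184·w^0.425·h^0.725 (kg, cm); EF = 100·(EDV−ESV)/EDV; indexed
measures divide by BSA; the remodelling index LVRI = LV-EDM/LV-EDV (g/ml,
≈1.03 in healthy hearts); the fat ratios EAT/LVM and indexed-EAT/LVRI;
scar (LGE) extent = 100·LGE mass/LV mass. Ventricular diameters (LV-EDD,
RV-EDD) are caliper inputs and are never computed from contours. Internal
computation keeps full precision; printed-table rounding (integers for
volumes/masses, 1 decimal for LVRI, 2 for ratios) happens only at the
report layer.

## Phantom

The phantom nests three confocal-axis ellipsoids: endocardium (a, b, c),
epicardium (a+w, b+w, c+w) for wall thickness w, and a fat shell adding a
further uniform thickness to each semi-axis. A basal truncation plane
perpendicular to the long axis removes a stated fraction of the outer
z-extent. The end-systolic cavity is the end-diastolic cavity scaled by
`es_scale` about the centre (truncation plane included), so ground-truth
EF is exactly 100·(1 − es_scale³) for an untruncated cavity. All reference
volumes come from the closed-form truncated-ellipsoid integral
V = π·a·b·(z − z³/3c² + 2c/3) evaluated at the cut height.

Slices sample the geometry at mid-slab planes from the basal plane
downward, matching the slab-summation volumetry (mid-plane sampling makes
the slab sum a midpoint rule, second-order accurate in the spacing).
Contours are regular parametric-angle polygons; at the default 128
vertices the polygonal area deficit is ≈0.04%, far below the 2%
volumetric tolerance. An optional fat wedge restricts the shell to a
parametric-angle range; because an elliptical sector subtends an exact
area fraction Δt/2π, the wedge ground truth stays closed-form while
producing partial, hole-free fat contours.

Observer variability is simulated by displacing every vertex radially
(about its contour centroid) by zero-mean Gaussian noise. Radial noise of
sd σ inflates expected areas only by O(σ²/r²) (≈3·10⁻⁴ at σ = 0.5 mm on
ventricular radii), so paired noisy observers are unbiased relative to
one another — which is what the Bland–Altman checks exercise.

## Cohort simulator

Primitives (age, weight, BMI, BSA, ventricular volumes and mass,
diameters, fat volume, scar extent) are drawn per group from a truncated
multivariate normal; physiologic feasibility (positivity, ESV < EDV, scar
within 0–100%) is enforced by rejection sampling with a 10% acceptance
floor. Everything else — EF, stroke volume, fat mass, indexed values,
LVRI, the fat ratios — is computed per subject through the index
formulas, never sampled. Group summaries of derived quantities are
therefore means of per-subject values, and the published group values of
those quantities act as emergent checks rather than inputs.

The default calibration is a 32/36/30 cohort (controls, ischemic,
dilated cardiomyopathy) with the published primitive means/SDs. Three
modelling choices deserve note:

* **BSA is a sampled primitive**, not recomputed by DuBois, because the
  published control BSA (1.7 ± 0.1 m²) is inconsistent with the published
  control weight and BMI under DuBois (≈1.96 m²). The simulator does not
  force agreement; the DuBois operation remains available and exact.
* **The published control LV-ESV SD (85 ml)** is implausible beside its
  mean of 75 ml (it would imply a large negative-volume mass) and is
  treated as typographical; 25 ml is used instead. Control EF then emerges
  near (141−75)/141 ≈ 47%, reflecting a second internal inconsistency of
  the published summary rows (printed EF 58%) that the simulator inherits
  rather than hides.
* **Latent vs observed correlations.** The published correlations concern
  BSA-indexed quantities. Dividing fat mass and LV mass by a shared noisy
  BSA inflates the observed correlation above the latent one between the
  unindexed primitives. The latent fat–mass correlations were therefore
  calibrated once, through the full simulation path at large n, so the
  derived indexed correlations recover the published values: latent 0.44
  (pooled CHF, target r = 0.59) and 0.315 (controls, target r = 0.36).
  The published inverse EAT–EF associations are encoded as positive
  latent correlations with end-systolic volume (0.31 LV, 0.32 RV), which
  produces the inverse relation through the EF formula.

The published study reports univariate r values only, so the off-diagonal
completion of the correlation matrix is a modelling choice. Rather than
projecting an inconsistent matrix to the nearest positive-definite one
(which would silently move the calibrated entries), the default spec adds
physiologically motivated structural correlations — EDV–ESV 0.9 within
each ventricle, volume–diameter and volume–mass couplings, body-size
couplings, and the small fills (EAT–LV-EDV 0.35, EAT–RV-EDV 0.25) they
imply — which makes the assembled matrix positive-definite as written.
User-supplied specs with a non-positive-definite matrix either raise an
error naming the offending eigenvalue or, with `repair_correlation`, are
projected and flagged in the output metadata.

What the simulator does *not* emulate: measurement error on the
primitives, non-normal tails, missing data beyond the structural absence
of scar tracings outside the ischemic group, any longitudinal structure,
or the real joint distribution beyond second moments. Passing recovery
tests therefore show that the statistics are implemented correctly and
calibrated under the stated moments — not that the original cohort's data
were distributed this way.

## Statistics

Agreement uses Bland–Altman: mean difference d of paired measurements and
limits d ± 1.96·SD (sample SD, n−1), by default on a percent-of-pair-mean
scale, the convention for volumetric observer studies. Published agreement
summaries can be expanded to limits with `limits_from_summary` (an exact
algebraic identity). Group comparisons are two-sided: pooled-variance
Student's t by default (Welch behind a flag), Mann–Whitney U, chi-square
on count tables. Simple regression is ordinary least squares with Pearson
r and the t-distribution p at n−2 df. The multivariable analysis enters
all predictors simultaneously (block entry) into a multiple *linear*
regression of the continuous outcome; a literal logistic variant
(median-split outcome) is available behind a flag for users who want to
dichotomise. Sample sizes for a two-sided two-sample t-test are solved
with the noncentral-t power function (statsmodels), then stepped to the
smallest integers meeting the target power; required sizes above 10⁷
raise rather than loop.

## Numerical conventions and problem sizes

All randomness flows through `numpy.random.default_rng` seeds; identical
spec + seed reproduces byte-identical tables and reports. Validation
errors are raised early and name the offending slice/structure/variable.
Absent measurements are explicit nulls end to end — a subject without a
scar tracing has no LGE extent, not 0%.

Validation problem sizes were chosen so the whole suite runs in about a
minute and a half: phantom convergence at 1–2 mm spacing against
closed-form volumes; observer-agreement simulation over 100 phantom
pairs; moment recovery at n = 2·10⁴ draws; correlation recovery over 200
cohort seeds and comparison significance over 1000 seeds at the study's
own group sizes; t-test calibration over 10⁴ null replicates.

## Known limitations

* Slab volumetry carries the usual base/apex partial-slab error; no
  slice-profile or partial-volume modelling is attempted.
* The phantom's fat layer is a uniform (or wedge-restricted) shell, not
  the anatomic depot distribution in grooves and over the right
  ventricular free wall; it validates volumetry, not segmentation.
* The simulator reproduces published summary moments including their
  internal inconsistencies (see above); it cannot recover the original
  per-patient data.
* "EAT" is whatever the contour labels say; no attempt is made to
  distinguish epicardial from paracardial fat.
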