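# eatq

Quantification of epicardial adipose tissue (EAT) and ventricular
volumetry from short-axis cardiac MR contour stacks, with the derived
indices and statistics used to compare heart-failure patients against
healthy controls.

EAT — the visceral fat between the myocardium and the visceral
pericardium — is metabolically active and tracks left-ventricular mass in
healthy hearts; in congestive heart failure its relation to ventricular
remodelling changes. Studying that quantitatively requires a chain from
manual tracings to cohort statistics: slice-wise areas → volumes →
masses → body-size-indexed measures → remodelling indices → observer
agreement and group inference. `eatq` implements that chain as a tested,
reusable library plus CLI, for imaging researchers who have contour data
(or want validated synthetic stand-ins) rather than raw pixels.

## Core model

For a structure traced on slices i = 1…N with net areas Aᵢ (mm²) and
effective slice spacing Δz = thickness + gap (mm), the stacked-slab
(modified Simpson's rule) volume and tissue mass are

    V = Σᵢ Aᵢ · Δz / 1000   [ml],     m = ρ · V   [g]

with ρ = 0.92 g/ml for fat and 1.05 g/ml for myocardium. Derived
subject-level measures:

    EF   = 100 · (EDV − ESV) / EDV            [%]
    BSA  = 0.007184 · w^0.425 · h^0.725       [m²]  (DuBois; w kg, h cm)
    LVRI = LV-EDM / LV-EDV                    [g/ml]
    indexed X = X / BSA,   EAT/LVM,   indexed-EAT/LVRI

Observer agreement is Bland–Altman: mean difference d of paired
measurements (percent of pair mean by default) with limits of agreement
d ± 1.96·SD of the differences.

The package ships two synthetic-data generators that make every stage
testable: an analytic truncated-ellipsoid phantom (closed-form volumes,
masses and EF) and a cohort simulator calibrated to the published
demographics, CMR summary moments and indexed-EAT correlations of a
32-control / 66-patient heart-failure study.

## Worked example

Generate a phantom with a 10 mm wall and a 4 mm fat shell around an
endocardial ellipsoid of semi-axes 30×25×20 mm, then measure it:

```sh
eatq phantom --slice-thickness 2 --inter-slice-gap 0 \
     --out ph.json --truth-out truth.json
eatq quantify ph.json
```

```
subject_id  lv_edv_ml  lv_esv_ml  eat_volume_ml  eat_mass_g   lv_edm_g  lv_ef_pct ...
   phantom  62.885131  21.597628       68.44206   62.966695 118.724668  65.655431
```

The analytic truth is 62.83 ml cavity volume (4/3·π·abc), 68.46 ml fat
shell and EF 65.7% (end-systolic scale 0.7 ⇒ 100·(1−0.7³)): the slab
volumetry lands within 0.1% of the volumes and 0.05 EF points. Absent
structures (here, scar) report as empty, never as zero.

Simulate the calibrated cohort and run the comparison battery:

```sh
eatq simulate-cohort --seed 1 --out cohort.csv
eatq analyze --cohort cohort.csv --out results.json
eatq report --results results.json
```

```
variable                 control (mean±SD)       chf (mean±SD)         p
lv_edm                      113.68 ± 23.27      207.89 ± 54.06    <0.0001
indexed_lv_edm               66.75 ± 14.02      108.70 ± 30.19    <0.0001
eat_volume                   66.77 ± 9.98        44.36 ± 13.57    <0.0001
indexed_eat_mass             36.08 ± 5.57        21.34 ± 6.80     <0.0001
eat_lvm_ratio                 0.56 ± 0.14         0.20 ± 0.06     <0.0001
...
```

Heart-failure patients carry *less* epicardial fat (indexed EAT mass
≈21 vs ≈36 g/m²) despite twice the LV mass, so the fat-to-myocardium
ratio collapses (0.20 vs 0.56) — the cohort-level signature the simulator
is calibrated to reproduce. Note the ratio rows are means of per-subject
ratios, not ratios of the group means.

The same operations are importable directly:

```python
from eatq import dubois_bsa, lvri, bland_altman, simple_regression
dubois_bsa(80, 172.1)          # 1.93 m²
lvri(207, 294)                 # 0.70 g/ml
```

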