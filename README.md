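# wristqct

Quantitative assessment of osteoporosis-related bone properties from
calibrated cone-beam CT (CBCT) wrist volumes — an end-to-end, fully tested
re-implementation of the complete computational chain:

1. **Calibration** — CBCT scanners report vendor grey values, not Hounsfield
   units. A holder phantom with air, polyoxymethylene (POM, 300 HU) and
   polytetrafluoroethylene (PTFE, 950 HU) inserts is imaged with every scan;
   an OLS line through the three (ROI grey mean, reference HU) points gives
   the scan-specific map `HU = a·grey + b`. HU is converted to
   hydroxyapatite-equivalent mineral density via the additive mixture rule at
   a 48 keV effective energy: `rho = HU · mu_w / (1000 · mu_HA)` with mass
   attenuation coefficients interpolated from the NIST XCOM tables.
2. **Geometry** — alignment of the forearm long axis to +z by the principal
   axis of the bone's second-moment tensor, then extraction of the
   standardized distal-radius VOI (10 mm of slices starting 9.5 mm proximal
   to the endplate reference line; 80 and 76 slices at 125 µm voxels).
3. **Segmentation** — a fast two-list level set (piecewise-constant two-phase
   energy) separates bone from background; the endosteal boundary splits the
   bone into cortical / transitional / trabecular compartments; automated
   region growing (ARG) with an iteratively looser homogeneity threshold
   binarizes the trabecular network, keeping the iteration with the lowest
   combined class inhomogeneity; cortical voxels below 600 mg/cm³ HA are
   flagged as pores.
4. **Morphometry & densitometry** — BV/TV, Tb.Th, Tb.Sc (sphere-fitting
   local thickness), Tb.Nd (skeleton junction density), C.Th, TV, TBV, mean
   cross-sectional area, and compartment-wise vBMD/vBMC.
5. **Micro-FE** — each bone voxel becomes a linear hexahedral element
   (E = 15 GPa, ν = 0.3); axial compression with the proximal face fully
   constrained and −0.1 mm prescribed distally; matrix-free
   Jacobi-preconditioned CG on the regular grid. Stiffness = F/u; the
   maximum force scales the linear solution to the Pistoia criterion (2 % of
   elements beyond 0.7 % effective strain, `ε_eff = sqrt(2U/E)`); strength =
   F_max / mean area.
6. **Cohort statistics** — Pearson r with Fisher-z 95 % CIs, regression R²,
   Bland-Altman limits of agreement, Mann-Whitney U (exact for small
   samples), Shapiro-Wilk, and normality-gated summaries
   (mean ± SD or median [Q1 ; Q3]).

Because clinical scan data cannot be redistributed, the package ships a
first-class synthetic-phantom module (`wristqct.phantom_synth`): analytic
wrist phantoms (cortical shell + plate/rod/gyroid trabecular lattice +
calibration inserts, affine grey transform, optional capping artifact and
noise) with exact ground truth, so every stage is testable without any
download.

## Worked example

```python
from wristqct import (PhantomSpec, SubjectConfig, make_wrist_phantom,
                      run_subject)

spec = PhantomSpec(grid_shape=(64, 64, 64), noise_sd=10.0, seed=9)
grey, gt = make_wrist_phantom(spec)
cfg = SubjectConfig(voi_offset_mm=0.5, voi_length_mm=6.0)
res = run_subject(cfg, grey, gt)
row = res.to_row()
print(f"BMD whole  {row['BMD_CBCT_whole']:.3f} g/cm3")
print(f"C.Th       {row['C_Th']:.3f} mm")
print(f"BV/TV trab {row['BVTV_trab']:.1f} %")
print(f"stiffness  {row['Stiffness']:.0f} N/mm")
print(f"Fmax       {row['Fmax']:.0f} N")
```

prints

```
BMD whole  1.298 g/cm3
C.Th       1.338 mm
BV/TV trab 39.0 %
stiffness  40271 N/mm
Fmax       1596 N
```

i.e. for this 8 mm-cube desk phantom: whole-bone volumetric BMD of
1.3 g/cm³, a cortex measured at 1.34 mm (designed 1.25 mm plus the
voxel-scale overestimation inherent to sphere-fitting thickness), a
trabecular bone volume fraction of 39 %, and an axial stiffness of 40 kN/mm
scaled by the Pistoia criterion to a 1.6 kN failure load. A clinical-size
wrist cross-section produces stiffness and failure loads roughly two orders
of magnitude larger, in proportion to the bone cross-sectional area.

The same chain is scriptable from the shell:

```bash
wristqct synth --out phantom/ --seed 1
wristqct segment --volume voi.nii.gz --out masks/
wristqct fe --mask masks/bone.nii.gz --out fe.json
wristqct stats --table cohort.csv --out report/
```

## Layout

```
src/wristqct/
  phantom_synth.py   synthetic phantoms, cohorts, ground truth
  calibration.py     grey->HU->density calibration
  geometry.py        long-axis alignment, VOI extraction
  segmentation.py    level set, compartments, ARG, porosity
  morphometry.py     structural + densitometric parameters
  microfe.py         voxel hexahedral FE, Pistoia criterion
  cohort_stats.py    correlation/agreement/test layer
  pipeline.py        per-subject + cohort orchestration
  cli.py             `wristqct` command-line interface
docs/methods.md      models, assumptions, parameter choices, limitations
```
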