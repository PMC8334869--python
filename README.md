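# torsiongait

Subject-specific femoral torsion changes how muscles pull on the hip.
`torsiongait` is a desk-scale, fully synthetic re-implementation of a
torsion-personalized gait analysis pipeline for musculoskeletal
biomechanics: it generates cohorts of walkers whose femoral torsion
spans retro- to antetorsion, builds a torsion-morphed lower-limb model
per subject, estimates hip contact forces (HCFs) during gait via
inverse dynamics and polynomial muscle recruitment, maps where the
force vector crosses the acetabulum, and tests torsion effects over the
gait cycle with one-dimensional statistical parametric mapping (SPM).
It is written for biomechanists and methods researchers who want a
tested, reproducible reference implementation of this analysis chain
without access to motion-capture or radiographic data.

## What it computes

**Femoral torsion** is measured with the radiographic convention: the
angle between the femoral neck line and the posterior condylar line,
projected perpendicular to the shaft axis (antetorsion positive).
Morphing to a target torsion applies a smooth axial twist about the
shaft axis — distal landmarks fixed, proximal structures rotated, with
a C^1 monotone blend in between — so that re-measuring the morphed bone
returns the target exactly.

**Hip loading** comes from a bottom-up Newton-Euler recursion
(foot → shank → thigh) driven by the ground reaction force, followed by
static optimization with the third-order polynomial recruitment
criterion

    min Σᵢ (fᵢ/Sᵢ)³   s.t.  R f = m,  0 ≤ fᵢ ≤ Sᵢ,

where `R` is the tendon-excursion moment-arm matrix (−∂L/∂q) and `m`
the net generalized moments. The HCF closes the femur force balance
(intersegmental force plus hip-spanning muscle pulls), reported per
body weight (BW) in the pelvis frame, and is intersected with a
standardized acetabular hemisphere (45° inclination, 20° anteversion,
54 mm diameter) to trace the contact pathway.

**Statistics** over the 101-node gait cycle use random field theory:
scalar regression SPM{t}, vector-field canonical correlation SPM{X²}
with Bartlett's statistic, paired Hotelling SPM{T²}, Bonferroni post
hocs at α/k, and cluster-level p-values; clusters spanning ≤ 2 %GC are
dropped from reports.

## Worked example

```python
from torsiongait.study import RunConfig, TorsionGaitStudy

results = TorsionGaitStudy(RunConfig(n_subjects=37, seed=1)).run()
print(results.summary())
```

prints (exact output for this seed):

```
torsion-gait study  (n = 37, seed = 1)
  torsion: mean 16.6 deg, sd 9.4 deg, range [-10.9, 37.4]
  peak cohort-mean HCF: 5.20 BW
  SPM hip_kinematics_cca: X2* = 13.25, clusters: [40-64]%
  SPM foot_progression_regression: t* = 3.09, clusters: [54-60]%
  SPM hip_moments_cca: X2* = 15.11, clusters: none
  SPM hcf_cca: X2* = 15.13, clusters: none
  SPM hip_flexor_cca: X2* = 18.53, clusters: [59-64]%, [66-69]%, [71-82]%
  SPM hip_extensor_cca: X2* = 18.55, clusters: [55-63]%
  SPM hip_abductor_cca: X2* = 15.74, clusters: [19-26]%, [60-63]%
  SPM hip_adductor_cca: X2* = 14.12, clusters: [60-63]%
  SPM hcf_generic_vs_personalized: T2* = 22.31, clusters: [0-22]%, [26-37]%, [44-55]%, [65-72]%, [87-100]%
```

Reading this: the cohort's torsion distribution matches the configured
truncated normal (mean 16.2°, SD 10°). The vector-field CCA of the 3-D
hip angles finds a suprathreshold cluster where the generator injected
the torsion–rotation coupling (around 40–64 %GC), and the foot
progression angle correlates with torsion in late stance — subjects
with higher antetorsion walk more in-toed. Replacing each subject's
torsion-personalized femur with the generic 5.5° bone changes the
predicted HCFs significantly over most of the gait cycle (the paired
T² row), and the per-subject RMSD between the two model variants
tracks the deviation from the generic torsion (Spearman ρ = 0.91 for
this seed). The cohort-mean contact pathway crosses the acetabulum
mostly in its anterior/superolateral quadrant.

The same study runs from the shell, writing tidy CSV fields, the RMSD
table, the pathway, SPM JSON and a reproducibility manifest:

```bash
torsiongait study run --config configs/study_defaults.yaml --seed 1 --out out/
torsiongait cohort generate --n 5 --seed 2 --out cohort/
torsiongait spm run --fields-csv fields.csv --covariates-csv subjects.csv \
    --components hip_rotation --out spm.json
```

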