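# Methods

`torsiongait` implements a desk-scale version of a subject-specific
femoral-torsion gait analysis: a synthetic cohort with heterogeneous
femoral torsion is processed through torsion-morphed musculoskeletal
models, bottom-up inverse dynamics with polynomial muscle recruitment,
hip-contact-force (HCF) assembly and acetabular pathway mapping, and
one-dimensional statistical parametric mapping (SPM) of torsion effects.
This note records the model, its assumptions, the parameters that
matter, and the choices made where the design was genuinely open.

## Femoral geometry and torsion

Femoral torsion is the transverse-plane angle between the femoral neck
line (the midline between the neck cortices through the caudally
projected head centre) and the posterior condylar line, both projected
onto the plane perpendicular to the diaphyseal axis; antetorsion
(proximal femur rotated anteriorly) is positive, and the sign is
side-aware so left and right femurs with the same anatomy report the
same value.

Morphing a femur to a target torsion applies an axial twist about the
shaft axis. Each point rotates by `w(s) * (target - current)` where `s`
is its normalized shaft coordinate (0 distal, 1 proximal) and `w` is a
C^1 monotone smoothstep, 0 below `s = 0.4` and 1 above `s = 0.7`.
Because each transverse plane rotates rigidly, the morph preserves
every point's distance to the shaft axis, is exactly composable, leaves
the posterior condyles bit-identical, and commutes with rigid motions.
The blend stations are configuration; any C^1 monotone blend satisfying
the round-trip and distal-invariance properties would be equivalent for
everything downstream, because all modeled attachment sites sit either
fully proximal (trochanters, `w = 1`) or in the blended/distal shaft.

The template femur is parametric (neck elevation 35 deg, neck length
70 mm, shaft length 340 mm, condylar half-width 25 mm) and is
constructed by twisting a zero-torsion canonical bone, so
`measure(generate(t)) = t` holds to machine precision by construction.

## The musculoskeletal model

A pelvis-thigh-shank-foot chain: 3-DOF ball-and-socket hip (flexion
about the pelvis Z axis, adduction about the floating axis, internal
rotation about the femoral long axis; adduction/internal rotation
positive toward the midline on both sides), hinge knee, hinge ankle,
and an oblique-axis subtalar joint; the patella is a knee-flexion-indexed
via point for the knee extensors. Segment lengths scale with stature
(thigh 0.245 H, shank 0.246 H, foot 0.152 H), masses with body mass
(pelvis 0.142 M, thigh 0.100 M, shank 0.0465 M, foot 0.0145 M), and
inertia from standard radii of gyration (Winter's tables). Pelvic width
is scaled so the inter-hip-joint-centre distance matches the subject's
radiographic measurement.

Muscles are polyline fascicle paths through segment-fixed points
(28 fascicles, 20 muscles), with via points at the pelvic brim
(iliopsoas), the malleoli (tibialis posterior, peroneus) and the
patella; there are no wrapping surfaces. Femoral attachment sites come
from the (possibly morphed) femur geometry, mapped into the thigh frame
by a torsion-invariant anchor (the head centre of the bone at the
baseline torsion) so that morphing moves muscle lines of action but
never joint centres or axes — matching the modeling convention that
torsion personalization does not alter joint kinematics.

Per-fascicle strengths `S_i` are configuration constants. Because the
roster is reduced, hip-spanning strengths are *lumped-group
equivalents*: each fascicle also stands in for the unmodeled muscles of
its compartment (pectineus, gracilis, adductor brevis, the short
external rotators, deep gluteal fibres), so values exceed single-muscle
PCSA-based estimates by roughly 50%. They were fixed once by requiring
moment-balance feasibility of the whole synthetic cohort (an LP scan
over 888 cohort-model runs) and are not fitted to any output.

Moment arms use the tendon-excursion definition `r = -dL/dq` by central
differences (default step 0.25 deg). For straight-line paths this
equals the cross-product moment of the muscle line about the
instantaneous coordinate axis, which the test suite uses as an
independent geometric oracle. Lever-arm sweeps report per-muscle means
over fascicles on a 1-deg grid across hip sagittal (-20..90),
frontal (-50..30 adduction) and transverse (-40..40) ranges.

## Synthetic cohort and gait trials

Subjects carry a truncated-normal torsion (default mean 16.2 deg,
SD 10.0 deg, support [-20, 50] deg), sex-conditional stature, BMI-derived
mass, stature-scaled inter-HJC distance, and self-selected speed around
5.2 km/h. Joint-angle trials (200 Hz) are smooth periodic templates
(low harmonics plus wrapped Gaussian bumps) shaped like normative adult
gait; the vertical ground reaction force (1000 Hz) is a double-bump
profile peaking at 1.12 body weight with smooth 5%-of-stance ramps and
exactly zero force in swing; gait events are stored as the generated
force's own 20 N threshold crossings.

The centre of pressure is not an independent template: it rolls from
the heel marker to the second-metatarsal marker of the generator's own
forward-kinematic foot trajectory. This keeps force placement and joint
motion mutually consistent, which the bottom-up inverse dynamics needs;
without it, template mismatch produced non-physiological net moments.

The torsion-kinematics coupling adds `slope * torsion` (deg per deg) to
the transverse-plane hip rotation inside two gait-cycle windows with
raised-cosine tapers (default 3 %GC): a hip-rotation window (default
57-63 %GC, slope 0.3) and a foot-progression window (default 39-56 %GC,
slope 0.2). Both act on hip rotation because it is the chain's only
transverse degree of freedom; the foot progression angle inherits the
second window through the marker-level geometry. The magnitudes are
free parameters of the generator (the real-world coupling size is not
established); 0.2-0.3 deg/deg spans the clinically reported in-toeing
range. Smooth channel noise (Gaussian-kernel-filtered periodic white
noise, default SD 2 deg, FWHM 20 %GC) models between-subject curve
variability; frontal-plane channels (hip adduction, pelvis list,
subtalar) receive half the sagittal amplitude, matching the smaller
frontal variability of normal gait — at full amplitude the open-loop
force templates turn frontal noise into crossover foot placements with
frontal hip moments beyond 3 N m/kg, which real (co-adapting) walkers
do not produce.

What the generator does *not* emulate: pathological or pain-avoidance
gait, the contralateral limb, soft-tissue artifact, marker labeling
errors, and any forward-dynamic consistency between forces and
accelerations. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline*, not claims about real cohorts.

## Signal processing

Kinematics are low-passed at 10 Hz and forces at 20 Hz with
fourth-order Butterworth filters applied forward-backward (zero phase;
the effective order doubles — a documented choice, since causal
filtering would shift events). Heel strike is the first sample of each
> 20 N run of the vertical force, toe-off the first sample below, with
a 50 ms debounce. All cycle quantities are linearly interpolated to 101
nodes from heel strike to ipsilateral heel strike. The foot progression
angle is the transverse-plane angle between the heel-to-MT2 axis and
the cycle's gait direction (heel positions at consecutive heel
strikes), in-toeing positive on either side. Optional marker-based
inverse kinematics is a per-frame Levenberg-Marquardt least-squares fit
of the 12 chain coordinates to the synthetic marker clusters; with
noise-free markers it recovers coordinates to < 1e-6 deg, and with 2 mm
isotropic noise to about 1 deg RMS (axial rotations sit at the
information limit of the cluster geometry).

## Dynamics, recruitment, and hip contact force

Net joint loads come from a bottom-up Newton-Euler recursion
(foot -> shank -> thigh) at the capture rate, with linear accelerations
by second-order central differences of the forward-kinematic positions
and angular rates from the rotation-matrix series. Because the
recursion starts at the measured force, pelvis residuals never enter
hip quantities. Hip net moments are reported in the pelvis frame per
body mass; the six generalized moments (3 hip, knee, ankle, subtalar)
are the projections on the instantaneous coordinate axes, which makes
them virtual-work-consistent with the tendon-excursion moment-arm
matrix.

Muscle redundancy is resolved per gait-cycle node by the third-order
polynomial criterion:

    minimize sum_i (f_i / S_i)^3
    s.t. R f = m, 0 <= f_i <= S_i

a smooth convex program solved by SLSQP (warm-started along the cycle)
after an LP feasibility check; infeasibility raises an error naming the
worst-violated coordinate. Equality tolerance is 1e-6 N m; optima are
verified in tests against an independent trust-region solver and the
two-muscle closed form `f1/f2 = (S1/S2)^(3/2)`. The upper bounds are
part of the model (they provide the infeasibility diagnostic); in
normal gait they are rarely active.

The hip contact force closes the femur force balance: the
intersegmental hip force minus the pull of each hip-spanning fascicle
on the leg along its hip-crossing path segment. It is reported as the
force the femur transmits to the acetabulum, in pelvis coordinates, per
body weight. Peak magnitudes in the synthetic cohort are 5-8 BW —
higher than instrumented-prosthesis walking values (~3-4.5 BW), as
expected for a reduced-roster polynomial-recruitment model without
force-length-velocity properties; all cohort-level analyses use
directions, correlations and paired differences, which the tests
calibrate, not absolute magnitudes.

## Acetabular frame and pathways

The acetabular frame sits at the hip joint centre with y perpendicular
to the acetabular opening plane (positive out of the socket), x
anterior and z superolateral, standardized at 45 deg inclination and
20 deg anteversion. It is built from the permuted pelvis triad by
rotating first by anteversion about the pelvis cranial axis, then by
inclination about the pelvis anterior axis — the composition order is
not uniquely determined by the radiographic definitions, so this order
is a documented package convention; left/right frames mirror. The
contact pathway intersects the force ray through the joint centre with
a 54 mm-diameter hemisphere (exact for a concentric socket; off-centre
rays are not supported). Forces in the opening plane (polar angle
90 deg) count as the inside boundary. The cohort-mean pathway averages
force vectors across subjects first (left hips mirrored to the right
convention) and intersects the mean.

## Statistical parametric mapping

Scalar fields use node-wise linear regression (SPM{t}, n-2 dof,
two-tailed by default since associations of either sign are of
interest). Vector fields use canonical correlation against the scalar
regressor; with one regressor the first canonical correlation is the
multiple correlation of the k components, and the statistic field is
Bartlett's `X2 = -(n - 1 - (k + 2)/2) ln(1 - r^2)`, treated as a
chi2(k) random field (the exact statistic variant used with vector-field
CCA in gait work is not standardized; Bartlett's form calibrates well at
n = 37). Paired model comparisons use Hotelling's T2 on the paired
differences, thresholded through the exact monotone map to an
F(k, n-k) field.

Family-wise thresholds solve `alpha = P0(u) + resels * EC1(u)` with
`resels = (Q - 1)/FWHM` and the 1-D Euler-characteristic densities of
Worsley (1994). Note the prefactor: Gaussian and t fields carry
`sqrt(4 ln 2)/(2 pi)`, while chi2 and F fields carry
`sqrt(4 ln 2/(2 pi))` because their derivative variance grows with
field height — Monte-Carlo calibration on constructed random fields
distinguishes the two sharply (family-wise error 0.11 vs 0.05 at
nominal 0.05). Smoothness is estimated from the variance-normalized
residual gradients, pooled over subjects and vector components; cluster
p-values use the standard 1-D expected-cluster approximation
(exponential-type extent with `P(s >= k) = exp(-beta k^2)`,
`beta = (Gamma(3/2) E[N]/E[S])^2`). Constant residuals degrade
gracefully to the infinite-smoothness limit, where the family-wise
threshold equals the pointwise quantile. Post hoc per-component
regressions run at the Bonferroni level alpha/k. Following the
reporting rule, clusters spanning <= 2 %GC are dropped from summaries.

Rank-deficient node-wise component covariances raise an error naming
the node by default; the study orchestrator opts into a reduced-rank
policy (pseudo-inverse on the non-degenerate subspace) for muscle-group
force fields, where the recruitment bounds make inactive muscles
exactly zero at some nodes.

## Problem sizes and determinism

The packaged study conditions are n = 37 subjects, one cycle per
subject, 101 nodes, both model variants per subject; SPM calibration
checks use 1000 null replicates and the coupling-detection check 100
replicates. These sizes keep the full test suite and the acceptance
script in the range of a few minutes on one CPU while preserving the
statistical behaviour of interest. Every random draw flows from
explicit integer seeds (cohort seed, plus per-trial seeds derived from
seed + 1); fixed seeds give bit-identical artifacts, recorded in each
run's manifest together with the configuration hash.

## Known limitations

- Via-point muscle paths cannot de-wrap: the reduction of the iliacus
  and rectus femoris flexion lever arms with antetorsion (which
  requires wrapping over the proximal femur) does not reproduce; the
  abductor mechanism and adductor insensitivity do.
- No muscle force-length-velocity properties; recruitment uses strength
  constants only, so absolute forces and HCF magnitudes are
  model-relative.
- The contralateral limb is not modeled; double support is handled
  implicitly by the instrumented limb's own force record.
- GRFs are template-based, not forward-dynamically consistent;
  kinematic noise therefore maps directly into moment variability.
- Subtalar and knee joints are single-axis idealizations; the hip is a
  perfect ball-and-socket, so socket morphology (coverage, version)
  cannot influence the mechanics.
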