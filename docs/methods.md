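# Methods

`vjms` is a quasi-static digital replica of a 6-DOF joint motion simulator
carrying a cruciate-retaining (CR) total knee arthroplasty. It exists to
answer one class of question: how do small femoral component rotational
malalignments (±1.5° about the surgical 3°-external target) change knee
kinematics, ligament tensions and compartment loading during passive laxity
testing? Because the commercial implant and subject-specific bone surfaces
such studies are run on cannot be redistributed, the package generates its
own parametric surrogate geometry; everything downstream (ligament model,
contact, solver, study protocol) operates on that surrogate exactly as it
would on real surfaces.

## Simulator architecture

The machine being replicated splits the six tibiofemoral DOFs between the
two bodies: the femur can flex–extend and ad–abduct only; the tibia can
translate in AP / ML / IS and rotate about its long axis. Each DOF is either
displacement-controlled (prescribed) or force-controlled (driven to a target
generalized load). A laxity protocol prescribes flexion and leaves the other
five DOFs force-controlled — at zero for neutral flexion, or at the test
load (100 N posterior, ±8 N·m varus–valgus, ±4 N·m internal–external).

Pose parameterization (right knee; x anterior, y proximal, z lateral, mm):

- femur: `T_f = R_x(α_AA) · R_z(θ_FE about (0, R_c, 0))`, with the flexion
  axis through the condylar centers;
- tibia: `T_t = Trans(AP, IS, ML) · R_y(θ_IE)`.

Kinematic read-out is a Grood–Suntay joint coordinate system (femoral fixed
flexion axis, tibial fixed long axis, floating ad–abduction axis). With the
axis assignments above, the relative rotation factorizes exactly as an
intrinsic z–x–y matrix, so `to_jcs`/`from_jcs` round-trip to machine
precision. Signs: flexion +, varus +, tibial external rotation +, anterior
translation + (posterior −). Both anatomical origins sit on the flexion axis
so all six coordinates vanish at the reference pose (full extension).

## Ligament system

Thirteen point-to-point nonlinear fibers: five superficial MCL bundles (all
wrapping the proximal-medial tibia), five LCL bundles, three PCL bundles.
Cruciate/capsular structures routinely released or resected at CR-TKA
surgery (ACL, ALL, POL, deep MCL) are not modelled.

**Force law.** Quadratic-toe/linear ("Blankevoort-type"):

    f(ε) = 0                    ε ≤ 0
         = k ε² / (4 ε_t)       0 < ε ≤ 2 ε_t
         = k (ε − ε_t)          ε > 2 ε_t

with ε_t = 0.03 and per-bundle stiffness k in N per unit strain, the
standard law for knee ligament bundles reported with those units. It is C1
and monotone, which the solver exploits.

**Reference strains.** Each bundle's published parameter pair is (k, ε_r),
where ε_r is the strain at full extension: ε_r = (l_r − l_0)/l_0 × 100 %.
The reference length l_r is *measured* on the synthetic geometry at the
reference pose (wrapping included) and the zero-force length back-computed,
l_0 = l_r/(1 + ε_r/100). This transfers the published recruitment pattern
onto any surrogate geometry: at extension, every bundle carries exactly the
tension its printed (k, ε_r) imply, regardless of where the insertions sit.

**Bundle augmentation.** The packaged parameter table prints the full
five-bundle collaterals but only the anterior and posterior PCL bundles. The
middle PCL bundle is generated by the augmentation rule — insertions at the
midpoints of its neighbours', reference strain the mean of its neighbours' —
and all three PCL stiffnesses are then rescaled by a single factor so the
ligament's total tension at a distracted pose that engages every bundle
matches the two-bundle original. The distraction magnitude is found by
bisection as 1.25× the smallest pure-inferior translation that engages the
slackest bundle (the anterior PCL, at −28.6 % reference strain, needs well
over 10 mm, so no fixed small distraction would do). Uniform scaling also
preserves the ligament's anterior/posterior force distribution exactly.

**Wrapping.** The sMCL wraps the proximal-medial tibial flare, modelled as a
sphere patch (centre (0, −14, −24), radius 12 mm, tibia frame). When the
straight fiber penetrates the sphere, the path is bent at one via point: the
intersection of the two in-plane tangent lines, which is the shortest
single-bend path with *zero* residual penetration. (A bend point constrained
to lie on the sphere itself cannot clear both sub-segments whenever the
chord actually penetrates — the tangent conditions are mutually exclusive at
a single surface point — so the bend point is pushed just beyond the
surface, which is also how the replicated simulator describes its wrapping.)
The construction is smooth in the poses and is the constrained minimizer of
path length, so fiber forces remain exact energy gradients. Fiber loads
resolve to the two bodies by two-body statics of the massless fiber: force
on femur = T·û at the femoral insertion, tibia takes the exact opposite
force and moment (bend reactions on the tibia-fixed sphere included).

## Contact

Contact between the rigid femoral component and insert follows the
replicated simulator's convention: penetration is tested along the tibia's
inferior–superior axis. Sample points are the barycentres of the insert's
upward-facing triangles; per-point normal pressure is penalty stiffness ×
depth (default 100 N/mm per mm², keeping equilibrium penetrations below
0.1 mm); per-point force acts over the projected tributary area along the
component's local surface normal scaled to unit IS component — exactly the
gradient of the quadratic penalty energy with respect to sample motion. The
pressure ramps in quadratically over the first 0.01 mm of depth so the
contact stiffness is continuous at activation; slope magnification on
near-vertical walls is capped at 1/0.15. Medial/lateral compartment forces
split the IS components of the per-point forces about the insert midline
and sum to the net compression by construction.

Two engines produce identical fields: an analytic torus engine (the
synthetic component records its condylar torus parameters; ray–torus
intersection by vectorized bisection, normals from the implicit — smooth to
machine precision and ~20× faster) and a generic Möller–Trumbore first-hit
ray caster for arbitrary meshes. The test suite cross-checks them against
each other.

Friction: the laxity protocols are quasi-static, so equilibrium states
involve no sliding and the µ = 0.04 Coulomb term contributes nothing at
rest; `contact_loads` exposes it for completeness (tangential force µ|N|
opposing a given sliding direction) but the solver runs frictionless, which
the energy bookkeeping requires.

## Equilibrium solver

Ligaments + penalty contact form a conservative system, so equilibrium of
the force-controlled DOFs is found by minimizing the total potential
(elastic energy minus applied-load work): Newton steps from a
finite-difference Jacobian of the residual, Levenberg regularization when
the Hessian is indefinite, an Armijo backtracking line search on the
potential, and steps capped at 2 mm / 2°. Angles are scaled by a 25 mm
lever so rotational and translational coordinates are commensurate.
Convergence means every force-controlled DOF balances its target within
0.5 N / 50 N·mm; every solution reported by the study satisfies this
contract (asserted in the tables). Neutral flexion uses continuation with
≤7.5° sub-steps; laxity loads ramp in four equal increments from the
neutral equilibrium. There is no randomness anywhere: repeated runs are
byte-identical.

The generalized loads are exact analytic gradients of the total elastic
energy (verified to 1e-3 relative by finite differences in the tests);
the flexion channel accounts for the flexion axis riding the outer
ad-abduction rotation, and contact reactions on the femur act at the
ray-hit points.

## Synthetic geometry: what it emulates and what it does not

The surrogate is a single-radius CR design: two toroidal condyles
(sagittal radius 24 mm, coronal 12 mm, centres 46 mm apart) articulating
with a deep-dished insert (sagittal dish radius 24.5 mm — 0.5 mm clearance —
with 9 mm walls; coronal radius 18 mm; intercondylar eminence capped at
4 mm). The deep-dish sagittal conformity is deliberate: with the ligament
preload the published reference strains produce (~90–100 N of passive
compression), a dished surface must be able to react a 100 N drawer within
the published ~1 mm laxity class, which requires wall slopes near 45–50°
at the preload level; a shallower dish lets the condyle ride over the lip
and drawer laxity runs away to several millimetres.

The femur surrogate's posterior condyles are internally rotated 2.5°
relative to the epicondylar (flexion) axis — the native posterior condylar
axis twist that motivates external component rotation in the first place.
Component placement measures both posterior condylar axes exactly as the
study protocol describes (posterior-most point of each condyle, sub-facet
refined) and rotates the component about the proximal axis through the PCA
midpoint; external rotation for a right knee carries the medial condyle
anteriorly, opening the medial flexion gap. The three conditions share
bones, insert and tray bit-for-bit and differ only in this one transform.

Ligament insertions are configurable anatomical defaults: sMCL from the
medial epicondyle (slightly anterior of the flexion axis, so its anterior
fibers recruit with flexion as the native superficial MCL's do) to a broad
antero-medial tibial footprint 55 mm distal; LCL from the lateral
epicondyle to the postero-lateral fibular head; PCL from the antero-distal
medial notch wall to the posterior intercondylar fossa, placed so the
ligament lengthens ~40 % between extension and 90° flexion and engages
under posterior drawer in deep flexion, like a native PCL.

What the surrogate does *not* reproduce: real implant surface topology
(variable femoral sagittal radii, asymmetric compartments, trochlea),
subject-specific insertion footprints, menisci/capsule, and any
viscoelasticity. Passing tests therefore demonstrate that the *method* —
strain-referenced multifiber ligaments, IS-penetration contact, hybrid
control — reproduces the published directional physics on a plausible knee,
not that it predicts any individual patient.

### Known limitation: posterior laxity of the internally rotated condition

On the default surrogate, the internally rotated component couples
posterior drawer with axial rotation: its neutral pose sits internally
rotated (screwed home against the dish) with the medial compartment
carrying nearly all load, and the drawer pulls the tibia back to the
wall-aligned rotation about a medial pivot. The extra AP travel from that
yaw puts the internal condition's posterior laxity at ~1.4 mm, above the
published ≤1 mm class that the baseline and external conditions meet
(0.3–0.6 mm here). Reducing the compartmental imbalance removes the excess
but simultaneously destroys the medial-compartment dominance the study
reports for all conditions; with the published tension/stiffness ratios
(~1.5 % strain headroom above the toe), both properties cannot be met
simultaneously on a two-trough conforming surrogate. The design favours
the directional findings; the laxity excess is confined to the internal
condition and is reported as-is.

## Study pipeline and problem sizes

`run_study` builds the geometry once, assembles and calibrates the ligament
set once (conditions share all soft tissue), then per condition runs
neutral flexion at 0/15/30/60/90° and all five laxity tests at each angle:
90 recorded equilibria (plus continuation/ramp sub-solves), about two
minutes on one CPU at the default mesh resolutions (72×20 condyle
parameterization, 2.5 mm insert sampling — chosen so the condyle facet sag,
~3 µm, stays far below the equilibrium penetrations). Outputs are tidy
CSVs (kinematics, laxities, bundle tensions, compartment forces, deltas
relative to the baseline neutral trajectory) and the scalar summary
(max posterior laxity, neutral AP spread, VV laxity spread) that
`scripts/acceptance.py` recomputes from scratch.

## Numerical choices

- Tolerances 0.5 N / 50 N·mm; kinematic outputs stable to <0.01 mm/° under
  tolerance halving.
- FD step 0.02 (mm or deg) for the residual Jacobian; contact is C1 so the
  forward difference is consistent.
- Ties/degeneracies: the via-point construction falls back to a
  deterministic perpendicular plane if the insertions are collinear with
  the sphere centre; the PCA search refines the posterior extremum by a
  local quadratic fit and errors if no intercondylar gap (≥2 mm) exists.
- Degenerate inputs (slack calibration pose, insertion inside a wrap
  surface, dislocated joint, gimbal lock at |VV| = 90°) raise typed errors
  rather than returning garbage.
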