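# Methods

## Model

The tibiofemoral joint is modeled as a quasi-static five-degree-of-freedom
mechanism. The femur is fixed; the flexion angle of the tibia is
prescribed, and the remaining five Grood–Suntay coordinates (varus/valgus,
internal/external rotation, and the mediolateral, anteroposterior and
superoinferior clinical translations) settle into static equilibrium of
three force systems: the sixteen ligament bundles, the elastic-foundation
cartilage contact, and the externally applied test loads. Gravity and
inertia are excluded — time only parameterizes the load schedule, so each
sample is an independent root-finding problem. This is the appropriate
idealization for slow joint-simulator protocols (a 25 s flexion cycle,
10 s load holds), where inertial forces are negligible against ligament
and contact forces.

### Joint coordinates

Body frames: x anterior, y superior, z lateral (right knee), coincident at
the full-extension reference pose. The rotation of the tibia relative to
the femur is the intrinsic sequence femur-fixed flexion → floating
varus/valgus → tibia-fixed axial rotation, which for these axes is the
Euler decomposition `R = Rz(−flexion)·Rx(varus)·Ry(−external)`. The
translations are resolved along the same three (generally non-orthogonal)
joint axes. The gimbal singularity of the sequence sits at varus/valgus
= ±90°; configurations beyond ±89° raise an explicit error, far outside
anything physiologic.

One sign deserves emphasis: the superoinferior translation is positive in
the joint-*opening* (distraction) sense. This matches the load-table
convention in which the compressive force on the vertical axis is written
as −50 N, and makes applied loads and reported coordinates conjugate
without hidden sign flips. A `mirror` flag converts the convention for
left knees (off by default).

The 6×6 joint Jacobian maps coordinate rates to the spatial twist of the
tibia; its transpose projects any spatial wrench onto generalized forces
per coordinate (N·mm per radian on rotations, N on translations). It is
assembled analytically from the joint axes and checked in the tests
against central finite differences of the pose map and the virtual-work
identity.

### Ligaments

Bundles are straight lines between attachment points — no wrapping around
bone or soft tissue, no interaction between bundles, no viscoelasticity.
The tension-only law has a quadratic toe up to twice the linear-limit
strain ε_l = 0.03 and a linear region beyond; stiffness k carries units of
force (strain-based formulation). Slack lengths derive from the tabulated
reference lengths and reference strains, l₀ = l_r/(1+ε_r); a negative
reference strain means the bundle is slack at reference (e.g. the
posterior cruciate bundles, engaging only in flexion). The law is C¹ at
both branch points, which matters for Newton convergence.

The default 16-bundle parameter table (k: 1000–4000 N; ε_r: −25 % to
+10 %; l_r: 22.9–94.4 mm) is stored as data in `ligament_model` and
serializes to CSV. Resection deactivates whole groups — ACL, PCL, LCL, or
MCL (superficial + deep) — and is idempotent; the posterior oblique,
arcuate popliteal, oblique popliteal and capsular structures are modeled
as separate entities and are never cut by the MCL group, mirroring how
sectioning protocols name only the collateral proper.

### Cartilage contact

The elastic foundation treats cartilage as a bed of independent springs on
rigid bone: per-element pressure p = K·d with
K = E(1−ν)/((1+ν)(1−2ν)h), the confined-compression modulus of the layer.
Defaults E = 5 MPa, ν = 0.45, h = 4 mm (combined femoral + tibial layer)
are typical articular-cartilage magnitudes; all are configurable, and
ν = 0.5 is rejected (infinite foundation stiffness). The pressure law is
linear and purely elastic — no damping, friction, or fluid effects.

The foundation is discretized on the tibial side (the flatter surface,
hence stabler normals): for every tibial face a ray is cast from the face
center along the inward normal; a hit on an opposing-oriented femoral face
within 6 mm is an interpenetration of that depth, and the element
contributes force p·A along its normal, pushing the bodies apart.
Medial and lateral compartments are separate mesh pairs whose wrenches are
summed. Degenerate triangles are skipped with a warning. The ray query is
an exact vectorized ray-triangle intersection over KD-tree-pruned
candidates, built once per femoral mesh (the femur is static) and reused
across all solver iterations. The 6 mm depth cap bounds the candidate
search; penetrations beyond the cartilage layer thickness would be
unphysical long before that.

### Equilibrium solver

The residual is the 5-vector of generalized forces on the free
coordinates: ligament and contact wrenches projected through the Jacobian
transpose, plus the applied loads, which enter directly as generalized
forces on their own axes (the joint simulator controls forces/torques per
clinical axis). Convergence requires every force row below 0.1 N and
every torque row below 10 N·mm.

The solver is a damped Newton iteration with a forward-difference Jacobian
(step 10⁻³ deg/mm — large enough to average over element-entry kinks in
the contact force), backtracking line search on the scaled residual norm,
and a Levenberg–Marquardt fall-back from the best point when Newton
stalls; Newton and least-squares rounds alternate while they improve.
Trial configurations outside the coordinate workspace (gimbal region)
return a large residual so the search steers away. Non-convergence after
the iteration budget (200) is *reported* — `converged=False` with a
diagnostic — never raised: an unstable joint (e.g. after resection) is a
scientific outcome. A converged zero-residual state with a vanishing
Jacobian (no contact, no taut ligament) is flagged `indeterminate`.

Protocols use continuation: passive flexion solves 0° first and marches
the 51 samples with warm starts; laxity tests march passive solutions up
to each angle, then warm-start the +load and −load legs from passive,
falling back to stepwise load ramping (25/50/75/100 %) if a leg fails
directly. Where multiple equilibria exist, the warm-start path selects
the branch — this is deliberate and mirrors the continuity of a physical
test. The laxity protocol always applies the full load magnitudes
(±40 N, ±5 N·m, ±2.5 N·m); reduced loads in hardware tests are machine
workspace artifacts, not model features.

## Synthetic knee generator

The generator replaces subject-specific imaging geometry with a parametric
idealization chosen once for physiologic plausibility:

* femoral condyles: two convex sphere patches, medial 22 mm / lateral
  21 mm radius, centers 45 mm apart on the flexion axis; the lateral
  center is offset 3 mm posteriorly. Because a sphere centered on the
  flexion axis is rotation-invariant, this cam offset is the *only*
  articular mechanism coupling flexion to axial rotation — the tests
  isolate it with a mirror-symmetric ligament set (no offset → no axial
  rotation; offset → rotation), reproducing the screw-home tendency.
* tibial plateaus: two concave spherical dishes, medial 35 mm (conforming,
  the "medial pivot" of real knees) and lateral 60 mm (flatter), with a
  0.05 mm joint space at reference so surfaces start separated.
* attachments: anatomic template sites — cruciates crossing in the
  intercondylar notch (the ACL femoral footprint posterior on the lateral
  wall, which is what makes the ACL slacken with flexion), collaterals
  from the epicondyles to the fibular head / anteromedial distal tibia
  with their real oblique fiber directions, and the oblique popliteal,
  posterior oblique, arcuate and capsular structures posteriorly. Every
  femur/tibia pair is then scaled along its own line about its midpoint so
  the bundle length at the reference pose equals l_r exactly; reference
  strains are therefore exact by construction.
* the reference pose is *declared* to be full extension with the joint
  centered under zero load. This is the central geometric assumption of
  the package: real specimens are imaged in an arbitrary (e.g. supine CT)
  pose, so a subject-specific model built from literature reference
  lengths can carry large pretension that a self-calibrated model cannot.

Meshes are structured grids (≈2 mm edges; ~700–800 femoral and ~440
tibial faces per compartment), oriented with outward normals and built
deterministically; optional vertex jitter is seeded and off by default.

### What the generator does *not* emulate

Real articular topography (non-spherical condyles, the intercondylar
eminence, plateau slopes), menisci, the patellofemoral joint, cruciate
wrapping, and subject-specific anatomic frame conventions. Consequently,
passing tests demonstrate the *mechanics pipeline* — coordinate algebra,
force laws, equilibrium, protocol logic, qualitative ligament-function
trends — not agreement with any particular specimen's kinematics.

In particular, absolute laxity magnitudes are geometry-sensitive. With
exact reference calibration the ligament pretension stays at the
tens-of-newtons scale and the model's laxity lands near values measured
on cadaver knees (a few mm of anteroposterior drawer, ~2° varus/valgus,
tens of degrees of axial rotation, growing with flexion as the posterior
capsule slackens). Subject-specific multibody models whose literature
reference lengths mismatch their imaged attachment geometry can be far
stiffer — cruciate tensions of hundreds of newtons compress laxity to
~1–3 mm and ~1.5°. Both regimes are reachable with this package by
editing the ligament table or attachments; the shipped default is the
self-consistent calibrated knee. Axial rotation is the most permissive
direction here because the main physical restraint at deep flexion —
the cruciates wrapping around each other — is outside the model class,
and the deep-internal-rotation leg at 90° flexion sits in a genuinely
unstable region that the solver reports as a flagged leg.

## Numerical and design choices

* Internal units N, mm, N·mm; protocol torques in N·m are converted on
  entry (×1000).
* Residual scaling equates 10 N·mm of torque to 0.1 N of force (a 100 mm
  moment arm), so the convergence test is a single scaled max-norm.
* Passive flexion uses 51 samples of the 25 s cycle; the trace must be
  symmetric under time reversal (no hysteresis) because nothing in the
  model carries history — the suite asserts ascending/descending
  agreement to 0.05 mm/deg and observes ≈0.007.
* RMSE between traces resamples both onto a uniform time grid (linear
  interpolation, 200 points) over the overlapping range — the natural
  comparison for cyclic time traces.
* Butterworth smoothing for imported 100 Hz recordings: 4th order, 6 Hz
  default cutoff (a common biomechanics choice; the cutoff is
  configurable), applied zero-phase (filtfilt) so DC gain is exactly 1.
  Simulated traces are noise-free and never filtered.
* Laxity envelopes label legs by signed load rather than "upper/lower",
  avoiding ambiguity about which direction a bar end refers to;
  non-converged legs propagate as missing values, never as zeros.
* Serialization is text only: OBJ meshes, CSV ligament tables and traces
  with a `# key: value` metadata header, YAML configs.

## Known limitations

Single-specimen-free by design: nothing constrains the synthetic anatomy
to any individual, so quantitative validation against a given experiment
requires importing that subject's geometry and frames. The contact law is
linear-elastic (no biphasic/fluid effects, no damping); ligaments are
line elements without wrapping; the patellofemoral joint and menisci are
absent. The solver finds one equilibrium per warm-start path; it does not
enumerate coexisting branches. Deep internal rotation under full axial
torque at 90° flexion is unstable for the default knee and is reported as
a non-converged leg.
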