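# Methods

`lumbocal` models a lumbar motion segment (and an L2–S1 chain) as rigid
vertebrae coupled by nonlinear force elements, and calibrates the disk and
ligament constitutive laws from stepwise-reduction range-of-motion (ROM)
data by running that experiment backward.  This note records the model, the
algorithms, the numerical choices, and the limits of what the synthetic
validation shows.

## Model

**Kinematics.** Each mobile vertebra carries six degrees of freedom
relative to its caudal neighbour: a rotation vector `phi` (radians) about
the disk centre and a translation `r` (metres) of that centre, expressed in
the caudal body's frame.  Axes: `x` medio-lateral (flexion/extension,
flexion positive), `y` antero-posterior (lateral flexion; dorsal positive),
`z` cranio-caudal (axial rotation).  A chain stacks segment transforms
above a fixed sacrum.

**Intervertebral disk.** A six-DOF bushing at the disk centre.

* Rotations: `T_spring(phi) = p1 tanh(phi^3 / p2) + p3 phi` per direction,
  with separate flexion and extension rows (sagittal asymmetry) and single
  odd rows for lateral flexion and axial rotation.  Angles in radians,
  torques in Nm.  With the packaged flexion row (`p3 = -1.685 < 0`) the
  curve dips slightly negative below ~0.018 rad, rises monotonically to a
  ~10.19 Nm peak at ~0.273 rad, and rolls over beyond it — the saturation
  is intended (torque plateau at large flexion), but it means equilibria
  near 10 Nm flexion sit close to a fold, and a second, non-physical root
  exists on the descending branch.  All protocol drivers therefore sweep
  torques in ascending order with warm starts.
* Axial: a compression-only quadratic spring,
  `F = 690,234,060 c^2 + 659,748 c` (c = compression in m); zero spring
  force in axial tension — the disk transmits no traction.
* Shear: linear springs, 260,000 N/m.  This value is a documented
  placeholder: no calibrated shear characteristic is published, and the ROM
  protocol (pure moments) barely excites shear.
* Damping: 400,000 Ns/m translational, 100 Nm s rotational.  All damping is
  linear in rate and vanishes at equilibrium; statics results are
  damping-independent (asserted by test).

**Ligaments.** Point-to-point cables with the softplus force–strain law
`F_spring(eps) = a ln(exp((eps+b)/d) + 1) + c` (eps in percent, F in N):
a smooth toe zone turning into a quasi-linear region of slope `a/d`.
Negative `d` yields a concave, decreasing curve (the packaged flaval row).
The supraspinous ligament carries a separate branch for negative strain;
the two branches agree at zero strain to < 0.1 N.  The total force is
clamped non-negative (cables cannot push), and damping is force-
proportional (`10 F_spring` applied to the strain rate as fraction/s).
Rest length derives from the neutral length and the declared prestrain,
`L0 = L_neutral / (1 + prestrain/100)`, so the neutral-pose strain equals
the prestrain by construction (ALL 8%, PLL/FL/ITL/CL 10%, ISL 4%, SSL
−6%).  The intertransverse ligament is carried in the model but has no
derivable characteristic from this protocol; it defaults to zero force.

**Facet joints.** Each facet is a convex cubic regression surface
`f(x,y) = p30 x^3 + p03 y^3 + p20 x^2 + p02 y^2 + p00` fitted by linear
least squares to nine landmarks per articular process (facet-local
millimetre coordinates); the contact surface is the coefficient-wise mean
of the superior and inferior fits.  Contact is a penalty spring–damper
(~12,000 N/m, 4,000 Ns/m) acting along the local surface normal at finitely
many probe points of the opposing process.  Penetration is measured with
the shallow-slope foot-point approximation
`depth = (f(x,y) − z) / sqrt(1 + fx^2 + fy^2)`; probe points outside the
fitted landmark domain are extrapolated with a warning.

**Muscles.** Constant-pull, length-independent wire cables (40 N per cable,
80 N per mirrored pair) anchored at body points with fixed global
directions, emulating the five experimental cable groups.

**Intradiscal pressure.** `IDP = 1.68 F / CSA`, the published
pressure-to-mean-stress correlation, applied to the compressive axial disk
spring force of the monitored segment.

## Equilibrium solver

The residual stacks, per mobile body, the torque (about the posed centre of
its supporting disk) and force of all elements plus the applied pure
moment.  A damped Newton iteration with a central finite-difference
Jacobian (step 1e-7) and line search solves it; rotation coordinates are
clipped to the rotation-vector chart.  On stagnation the solver falls back
to dynamic relaxation (damped explicit integration with near-critical
per-coordinate damping until the kinetic energy drops below 1e-9 J), then a
Powell-hybrid polish, and — for warm-started solves — a cold restart with a
full load ramp.  Loads are ramped in up to five warm-started increments.
Default convergence: max residual 1e-6 N and 1e-8 Nm.  Individual pose
coordinates can be pinned (used by the calibration's constrained solves).

Slack-taut ligament transitions, contact onset and the axial
tension/compression boundary are continuous but kinked; near such kinks the
line search can stall at residuals of order 1e-4 N.  One extreme chain
scenario (all ten cables plus lateral bending) sits near a snap-through and
may fail to converge; protocol drivers log such scenarios and report them
as missing rather than aborting the batch.

## Backward calibration

Stage order (most reduced first): disk ← "w/o ALL"; ALL ← "w/o PLL"; PLL ←
"w/o VA"; facet stiffness ← "w/o CL"; CL ← "w/o FL"; FL ← "w/o ISL"; ISL ←
"w/o SSL"; SSL ← intact.  Each step freezes its element before the next.

**Disk.** In the disk-only stage each record is directly a point
(ROM in radians, applied torque) on the rotational law; the origin is
appended, flexion/extension stay separate, signed lateral/axial rows fold
onto one odd set.  The tanh-cubic law is fitted by multi-start trust-region
least squares with `p2` bounded to 0.05 rad³ — beyond that the tanh never
saturates within the physiological range and the law degenerates into a
cubic alias whose in-range curvature is wrong under noise.

**Deficit-torque attribution.** For each record of the stage that
introduces an element, the loading-axis rotation is pinned to the stage's
0 Nm reference plus the recorded mean ROM, the free DOFs are equilibrated,
and the moment the known elements fail to supply is attributed to the new
element; dividing by its moment arm yields one force–strain sample.  The
procedure is iterated to self-consistency (the estimate participates in
the reference and constrained solves of the next pass) until the fitted
curve stops moving.  Three refinements proved necessary:

1. *Slack rule.*  Records that do not strain the new ligament at least
   0.5% beyond its strain at the stage's neutral pose are skipped: their
   deficit is dominated by reference-pose error, not ligament force.
2. *Cross-side correction.*  In asymmetric (lateral/axial) loading only
   the more strained side of a bilateral pair is credited with the
   deficit, but the other side still carries prestrain tension; its
   current-estimate contribution is subtracted first.
3. *Neutral-force basin scan.*  The stage's 0 Nm reference depends on the
   uncalibrated element's neutral tension, and the fixed-point iteration
   has gain `k(record)/k(neutral)` in that scalar — above one whenever the
   segment is stiffer at the recorded poses than at neutral (usual, the
   disk law being soft near zero).  A cold start can then converge to a
   self-consistent but unphysical solution.  The physical basin is
   recognisable from the samples themselves: in it every record yields a
   non-negative force and the forces vary smoothly with strain, whereas a
   reference error imprints the segment's stiffness profile on them.  The
   neutral force level is scanned (coarse grid, then local refinement)
   with an affine provisional law and scored by usable-record count, then
   by the residual of a straight line through the reliable samples.
   Ligaments with declared negative prestrain are slack at neutral and
   start at zero force.

Samples are weighted by the moment arm they were inferred through (their
force error scales as 1/arm).  The softplus fit is multi-start trust-region
least squares including negative-`d` starts; among fits within 25% of the
best residual the widest transition (largest `|d|`) is preferred, then the
smaller `|b|` — sharp-knee aliases of a quasi-linear point cloud otherwise
fit the samples equally well but extrapolate disastrously, while a genuine
sharp knee inside the sampled range keeps every smooth candidate far
outside the 25% window.  Fits degrade gracefully: near-zero sampled forces
yield the zero curve, and under noise an element whose usable records fall
below the fit preconditions keeps its provisional estimate with a warning
instead of aborting the pipeline.

**Facet stiffness.**  Extension and axial records of the "w/o CL" stage
are pose-constrained; the deficit moment is regressed through the origin
against the facet moment per unit stiffness at that pose (deep-contact
records thereby carry proportionally more information), iterated as above.

Calibration solves use loosened tolerances (1e-4 N, 1e-6 Nm): deficit
samples are only needed to ~1e-3 Nm.

## Synthetic study conditions

The generator builds a bilaterally symmetric, explicitly **non-anatomical**
functional unit: vertebral bodies 40 mm apart, ligament insertions 10 mm
above/below the disk plane at dorsoventral offsets ALL −26, PLL +15,
FL +13, ISL +42, SSL +58, CL ±20/+28, ITL ±42/+4 mm (±5% seeded jitter),
disk cross-section 1.8e-3 m².  Facets are gently curved convex patches
(p20 = −0.05, p02 = −0.04 mm⁻¹ scale) whose normals tilt 30° medially so
that extension, lateral bending and axial rotation all engage contact; the
landmark sets sample the patches exactly and the stored surfaces are their
least-squares fits.  Probe points hover 0.3 mm above the surface at
neutral.  The chain stacks four such segments with five mirrored
placeholder cable pairs.  The ground-truth characteristic set is the
packaged calibrated parameter table.

`simulate_eds1` runs the full stepwise forward protocol (192 cells), adds
seeded Gaussian noise to the loaded means and generates ranges as
mean ± max(0.1°, 0.15·mean); `simulate_eds2` runs the 49-cell pressure
protocol with SD = max(0.02 MPa, 0.15·mean).  Defaults: noise 0.25°,
halfwidth 0.15.

What the synthetic conditions do **not** emulate: anatomical insertion
coordinates and facet shapes, specimen-to-specimen variability (ranges are
synthetic halfwidths, not observed min/max over specimens), the nucleus
removal stage, and the experimental lordotic-angle jump at arch removal
(which the source experiment itself attributes to specimen handling).
Passing round-trip tests therefore demonstrate the *method* — that the
backward procedure identifies the constitutive laws that generated a
consistent data set — not anatomical fidelity.

## Verified behaviour (noise-free study conditions, seed 7)

All numbers below are computed by the test suite / acceptance script at run
time; none are inputs.

* Disk rows recovered to better than four significant digits; ligament
  curves within a few percent RMSE (of in-range peak force) of the
  generating curves over their engaged strain ranges; facet stiffness
  within 1%.
* Forward re-simulation of all 192 protocol cells within 0.014° of the
  generated table; 0 of 160 loaded scenarios outside the generated ranges.
* The supraspinous ligament never engages inside the protocol's strain
  range in this geometry (its knee sits near 23% strain); its recovered
  curve is the zero curve, which is also its true in-range behaviour.

## Known limitations and documented tolerances

* **Stage monotonicity.**  ROM referenced to the per-stage 0 Nm pose is
  *not* monotone across the flaval-removal step: the concave flaval row
  (force falling with strain) shifts the neutral reference by more than it
  shifts the loaded pose, for any insertion geometry.  Monotonicity is
  asserted for every other transition, and fully (all transitions) for a
  resistive-variant characteristic set with a monotone flaval curve and
  zero prestrains — the premise under which the property actually holds.
* **Noise robustness.**  The generated ranges are centred on the *noisy*
  means; with noise SD 0.25° the halfwidth max(0.1°, 15%) is smaller than
  the noise at small ROMs, so even the generating model misses ~11% of
  ranges in expectation (measured 7–14% over seeds).  The calibrated model
  roughly triples that (measured 30–42%): the weak posterior elements'
  signals (0.05–0.2 Nm) sit below the per-record torque noise
  (k·sigma ≈ 0.1–0.3 Nm), and the per-stage neutral levels are then only
  weakly identified.  The robustness test asserts the documented tolerance
  of 45% per seed over three seeds (scaled down from five for suite
  runtime; the per-seed behaviour is seed-stable).
* **Problem sizes.**  The test suite runs one noise-free round trip
  (8 stages × 4 directions × 6 torques), three noisy round trips, and one
  49-cell chain pressure protocol — a few minutes each on one CPU.
* The calibration is sequential; errors made early (disk, longitudinal
  ligaments) propagate into later elements.  The iterative
  self-consistency and basin scan keep this in check in the noise-free
  case but are the dominant error source under noise.
* Quasi-statics only: no creep, no poroelasticity, no friction, no true
  dynamics; damping exists solely to stabilise the relaxation fallback.
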