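# Methods

## Geometric model

The midsagittal abdominal outline is modelled as the hexagon T–X–P–S–Ai–As
(anterosuperior edge of T12; xiphoid process; superior edge of the pubis;
anterosuperior corner of the sacrum; inferior and superior osteotomy
apexes).  The inner quadrilateral X–P–Ai–As carries the prediction: sides
*a* (P–Ai), *b* (Ai–As), *c* (As–X) in cm and hinge angles *β* at Ai, *γ*
at As in degrees.  A two-level closing-wedge pedicle subtraction osteotomy
hinges on the anterior vertebral cortex, so its effect is modelled as two
rigid rotations: the caudal block (P, S) about Ai by α₁ and the cranial
block (X, T) about As by α₂.  Under this model:

- the seven peripheral segments XT, XAs, TAs, AiAs, PAi, PS, SAi keep
  their lengths exactly;
- the hinge angles open to β + α₁ and γ + α₂;
- the two peripheral triangles translate/rotate rigidly, so the hexagon
  area change equals the quadrilateral area change;
- the postoperative quadrilateral area follows from the law-of-cosines
  closed form evaluated at the opened angles, and
  ac-AMSP = S(β+α₁, γ+α₂) − S(β, γ),
  CR = ac-AMSP / S(hexagon, preop) × 100%.

The rigid-rotation picture is an idealization: real postoperative CT shows
small changes in the peripheral segments (soft tissue, measurement error,
remodelling).  The model treats those as noise around an exact geometric
core.

Three independent routes to the area are implemented and held to mutual
agreement of 1e-9 relative: the radical closed form, the shoelace area of
explicitly reconstructed vertices, and the sine identity
S = ½|ab·sin β + bc·sin γ − ac·sin(β+γ)|.  The diagonal representation
(m = |AC|, n = |BD|, angle θ between them, S = ½·m·n·sin θ) is exposed as
well and checked against the same oracle.

## Conventions and numerical choices

- Angles are degrees at every interface; radians exist only inside
  computations.  β and γ are measured on the ventral side — the side where
  the hexagon interior lies — with the hexagon's orientation (sign of its
  shoelace area) fixing the sense.  This makes reflex hinge angles
  (> 180°) representable and every measurement invariant under rigid
  motions *and* reflections of the landmark frame.  β + γ above 180° is
  routine (the cohort means already sum to 191.5°), so no quadrant
  assumption is made anywhere.
- Vertex reconstruction uses a canonical frame: Ai at the origin, As on
  the positive x axis, the interior above the axis.  The frame is a
  convenience; nothing downstream depends on it.
- The radicand of the closed form is non-negative for any realizable
  geometry; a negative value beyond 1e-12 of its scale signals mutually
  inconsistent measurements and raises an error rather than being clamped,
  so measurement errors are not silently hidden.
- Extreme inputs can produce a *crossed* (self-intersecting)
  quadrilateral.  The closed form remains algebraically defined but no
  longer equals a simple-polygon area, so the value is returned with an
  explicit warning.  Crossing is detected by a strict segment-pair test of
  the two non-adjacent edge pairs with a relative tolerance, so a
  quadrilateral collapsing to a triangle (coincident vertices) does not
  count as crossed.
- The preoperative quadrilateral area used in the subtraction defaults to
  the computed value for internal consistency; a directly measured value
  can override it (planimetry tools measure it routinely), in which case a
  discrepancy above 5% relative to the computed value is logged.  Both
  values are reported.
- Geometric identities are held to a fixed documented tolerance of 1e-9
  relative; it is a constant, not a configuration knob.

## Synthetic cohort generator

The generator emulates the published cohort statistics: each scalar is an
independent truncated normal with the reported mean ± SD — sides
a 17.5 ± 2.60, b 6.1 ± 1.16, c 13.5 ± 3.03 cm; hinges β 128.4 ± 24.09°,
γ 63.1 ± 17.42°; peripheral segments XT 14.0 ± 2.94, TAs 3.8 ± 1.31,
SAi 8.2 ± 1.66, PS 11.4 ± 0.87 cm; planned wedge angle (POVA) 38.4 ± 9.43°
per osteotomy; spinopelvic covariates GK/LL/TK/SVA with their reported
pre- and postoperative moments (descriptive only; they feed nothing
computational but give the validation report its full clinical shape).
Lengths are truncated to positive values and hinge angles to (5°, 355°).

The actual wedge angle is modelled as AOVA = POVA − bias with
bias ~ N(0.8°, 2.0°) floored so AOVA ≥ 0: the reported planned-vs-actual
mean difference is 0.8° with a 95% CI of −0.1–1.7° over 22 osteotomies,
implying a paired-difference SD near 2°.  "Measured" postoperative hexagon
areas add Gaussian planimetry noise with SD 5 cm², about 3% of the mean
preoperative hexagon area — a realistic scale for workstation planimetry.

Patients are assembled by reconstructing the quadrilateral in the
canonical frame and closing the two peripheral triangles (T against edge
X–As from the drawn XT/TAs; S against edge P–Ai from PS/SAi) on the dorsal
side.  Draws are rejected until the triangles close, the hexagon is a
simple polygon, the hexagon area decomposes into quadrilateral plus the
two triangles, and the drawn hinge angles round-trip through measurement.
Each patient consumes an independent, counter-indexed substream of the
root seed, so cohorts are bit-reproducible and order-independent.

What the generator deliberately does **not** emulate:

- Correlations between parameters — the source statistics are marginal
  moments only; all draws are independent.  Consequently the feasibility
  rejections condition the accepted population: side means shift down
  slightly (< 0.25 cm; a can never exceed PS + SAi) and hinge-angle means
  shift up by ~2–3° (low-angle sliver quadrilaterals rarely admit a simple
  hexagon).  The unconditioned scalars recover their configured moments to
  within 3 standard errors at n = 5000.
- Violations of the rigidity assumption seen in real postoperative CT
  (e.g. a measured postoperative shortening of c).  The simulator is a
  model-faithful world by design: with zero bias and zero noise the
  closed-form prediction reproduces every simulated patient's actual area
  change to 1e-9.  Passing tests in this world validate the mathematics
  and the code, not the clinical adequacy of the rigidity assumption.

## Validation report

The report mirrors the clinical validation design: two-sided paired t
tests (difference direction: first − second, i.e. pre − post and
planned/predicted − actual), 95% CIs from the t distribution with n − 1
degrees of freedom, significance flagged at 0.05, and no multiple-testing
correction (faithful to the original design).  Wedge angles are pooled
over both osteotomies (2 per patient, df = 2n − 1).  Zero-variance
differences degenerate explicitly: p = 1 for identically zero differences,
p = 0 with a flag for a non-zero constant difference.  The paired test is
assembled from its defining formulas with the t distribution from scipy;
scipy's own paired test serves as an independent cross-check in the test
suite only.

## Problem sizes

The property and acceptance checks use 10,000 random states for the oracle
equivalence, 1,000 geometries for the zero-wedge identity, a 1,000-patient
noise-free cohort for model faithfulness, 10,000 null replicates (n = 11)
for the t-test calibration, 200 replicate 11-patient cohorts for the
change-rate agreement rate, and n = 5000 for distributional recovery —
sizes at which the Monte-Carlo standard errors are comfortably below the
asserted bounds.

## Known limitations

- The model is two-dimensional by construction; it says nothing about
  abdominal volume beyond the midsagittal section.
- No inverse planning (choosing α₁, α₂ to hit a target area change) is
  provided.
- Hinge angles pushed past 180° by the wedge are handled by the same
  formula; the crossed-quadrilateral warning is the only guard in that
  regime, because a reflex postoperative hinge has no simple-polygon
  interpretation to validate against.
- The generator's independence assumption overstates the frequency of
  borderline-infeasible anatomies relative to a real correlated
  population; the rejection machinery exists to absorb exactly that.
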