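# Methods

## Model and assumptions

A metatarsus is represented as one beam chain per ray (three for unfused
and partially fused morphotypes, one for a fused cannon bone), clamped in
all six degrees of freedom at the proximal end node of every ray and struck
distally by an analytic rigid plane. Cross-sections are circular annuli:
outer radius and cortical (wall) thickness are piecewise-linear functions
of the fractional axial station, with flared epiphyses and metaphysis
shoulders around a uniform diaphysis (default segment split 0.10 / 0.15 /
0.60 / 0.15 of length for proximal epiphysis / metaphysis / diaphysis /
distal epiphysis). The trabecular interior is ignored — hollow-tube
mechanics is the point of the exercise — and sections are never
non-circular. Partial fusion is modelled as solid circular link elements
("columns") joining adjacent rays at prescribed stations, with a
configurable column radius.

Elements are two-node 3D Euler–Bernoulli frames (axial, torsion, two
bending planes; no shear deformation, geometric linearity, small strain)
with linear-elastic material. This is a deliberate fidelity boundary: all
claims the package makes are at the beam scale (stiffness, section
mechanics, peak outer-fiber stress), not at the scale of real bone
geometry, so solid/shell modelling of scanned surfaces is out of scope and
STL input is used for measurement only.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| Young's modulus E | 20 | GPa | typical mammalian cortical bone |
| Poisson ratio ν | 0.3 | – | typical cortical bone |
| density ρ | 2000 | kg·m⁻³ | cortical bone |
| ultimate (fracture) stress | 205 | MPa | failure criterion for peak von Mises stress |
| plate speed | 1 | m·s⁻¹ | empirical foot-contact kinematics |
| plate displacement | 3 | mm | reference collision (scaled models) |
| initial gap | 1 | mm | plate–bone separation at start |
| inclination | 45 | ° | bone long axis to plate surface |
| contact penalty | 10 × E·Ā/L | N·m⁻¹ | see numerical choices |
| contact damping ζ | 0.6 | of critical | see numerical choices |
| dt_safety | 0.9 | – | fraction of the exact critical time step |
| elements per ray | 100 | – | see problem sizes |

In **unscaled** runs the 3 mm displacement is multiplied by the ratio of
the species' limb geometric mean to the reference geometric mean — linear
dimensions scale as mass^(1/3), so the geometric mean of limb element
lengths is a transparent size proxy that assumes no allometric exponent.
In **scaled** runs anatomy is first scaled isometrically to the reference
metatarsal length, then the cortical-thickness profile is multiplied by a
single factor anchored at midshaft so the midshaft wall matches the
reference; outer surfaces and length are untouched by the second step, and
walls are capped at solid where the factor would exceed the outer radius.
The reference species is untouched by both transforms, so it is identical
in the two suites by construction.

The plate's total travel is the initial gap plus the stated displacement:
the displacement is interpreted as post-contact bone deformation (it
derives from deformation measured during substrate contact), and the
alternative convention — total travel includes the gap — is available via
`SimulationConfig.travel_includes_gap` but would leave the smallest
unscaled morphotypes out of the plate's reach entirely. After its travel
the plate dwells for one travel duration so the post-peak interval is
observable. All distal-epiphysis nodes of every ray are contact candidates
("multiple node" load distribution); as the bone wraps onto the plate the
contact patch migrates proximally, which shortens the effective lever and
is the main nonlinearity in the force response.

## Synthetic morphotypes

The five shipped fixtures emulate the study species' *roles* — smallest
unfused, mid-size unfused, partially fused with trans-medullary columns,
fused reference, largest fused — spanning masses 3 g to 320 g (two orders
of magnitude) and metatarsal lengths 9–48 mm. Two masses are
literature-sourced (3 g, 31 g); the rest are plausible estimates. Radii
and cortical thicknesses are *calibrated*, not measured: they were chosen
once, by running the default suites at design time, so that (a) the
calibrated reference's peak GRF lies in (2, 4] N, (b) every default
simulation stays below 4 N peak GRF and 205 MPa peak stress, and (c)
unscaled peak GRF is rank-monotone in body mass. The resulting sections
are more slender than real jerboa bones because a beam wrapped onto a
rigid plate with distributed node contact is stiffer than a real foot with
compliant joints and soft tissue; the fixtures therefore demonstrate the
mechanics without claiming anatomical accuracy. What passing tests show is
that the *pipeline* reproduces the study's structural patterns (stress
location, timing, force–size scaling, bounds) on geometry with the right
topology and proportions — not that any real species experiences these
exact stresses.

`random_morphotype(seed)` draws property-test inputs uniformly from
documented ranges (length 6–50 mm, diaphysis radius 0.12–1.5 mm, relative
wall thickness 0.15–0.6, all three fusion states) and always satisfies the
morphotype invariants.

## Numerical choices

* **Time stepping.** Central difference with lumped mass at
  `dt_safety × 2/ω_max`, where ω_max comes from the exact generalized
  eigenproblem (dense for small systems, Lanczos with a fixed start vector
  for determinism otherwise) combined with the contact-spring frequency of
  the lightest contact node. An element-wise acoustic bound `l/c` is
  available as a conservative alternative.
* **Lumped rotary inertia** per node half is `m/2 · max(l²/12, (I_y+I_z)/2A)`:
  the rod term for slender elements, the section polar radius of gyration
  for stubby ones. This keeps rotational modes physical (first two
  cantilever frequencies within 2% of the closed form at 100 elements)
  without letting them control the stable time step.
* **Contact** is node-to-plane penalty with stiffness 10 × the bone's
  characteristic axial stiffness E·Ā/L — penetrations stay below ~0.1% of
  the prescribed displacement — plus a dashpot at ζ = 0.6 of critical per
  contact node, clamped so the total normal force is never tensile.
  A stiffer penalty (100×) and no dashpot make peak force and stress
  discretization-sensitive: undamped touchdown transients ring
  indefinitely and the maximum over a long weakly-damped oscillation does
  not converge under mesh or time-step refinement. With the dashpot the
  peak is the first overshoot after maximum plate displacement and moves
  <1% under element doubling or time-step halving. Mass-proportional
  damping exists but defaults to zero.
* **Energy ledger.** External work is the trapezoidal integral of GRF
  against plate motion; dashpot dissipation is integrated trapezoidally
  against relative displacement; kinetic energy uses velocities centred to
  integer steps. The reported `energy_error` is the maximum ledger
  imbalance normalized by the run's total external work (a fixed energy
  scale — normalizing frame-by-frame makes the instant of first contact,
  where work is ~1e-11 J, spuriously dominant). Integration is treated as
  diverged if the imbalance exceeds ten times the 1% tolerance.
* **Stress recovery** samples 16 equally spaced outer-fiber points per
  section (including the bending-plane extremes), takes the element
  maximum over both end sections, and assigns nodes the maximum over
  adjacent elements. Transverse shear is neglected (slender beams).
  Fracture is flagged only strictly above the ultimate stress.
* **Statics and modes.** Quasi-static solves (point force or prescribed
  tip displacement) and eigenfrequencies use the same assembly and are the
  package's closed-form verification modes: tip deflection within 1% of
  FL³/3EI, first eigenfrequency within 2% of the cantilever closed form,
  and exact invariance of the quasi-static stress field under co-scaling
  of geometry and prescribed displacement. Degenerate bending pairs of
  circular sections are collapsed when indexing distinct mode frequencies.

## Problem sizes

Default discretization is 100 elements per ray (303–308 nodes for three-ray
morphotypes), chosen as the point where peak stress changes <2% on element
doubling; a full collision is ~10⁵–10⁶ explicit steps and runs in seconds
on one CPU. The ten-simulation suite pair plus calibration completes in a
few minutes.

## Hypothesis outcomes on the default fixtures

The decision rules are strict-inequality set comparisons (H1: every
smaller-bodied unfused species' unscaled peak stress strictly below the
fused reference's; H2: every fused/partial scaled peak strictly below
every unfused scaled peak). On the shipped idealized fixtures H1 is
supported and H2 is not: under displacement-controlled loading the peak
outer-fiber stress of an annular beam scales with its outer radius, so
three slender rays brought to the reference length develop *lower*
stresses than the single wide cannon bone. The fusion benefit appears
under force-controlled loading (the 9× stiffness and 1/3 stress ratios of
the section-mechanics module), and in published solid-element studies it
also appears under displacement control through geometric detail —
curvature, asymmetric sections, local thinning — that circular-annulus
beams deliberately omit. The hypothesis evaluator is exercised against
published per-species stress rankings in the unit tests; the suite outcome
on synthetic fixtures is reported as-is and should not be read as a
biological conclusion.

## Known limitations

Linear elasticity (no plasticity or damage), isotropic material, no
friction or self-contact between rays, no trabecular structure or
growth-plate anatomy, straight bone axes, circular sections, rigid plate.
The body-size covariate in regressions is log₁₀ of a nominal body mass,
not a phylogenetically derived relative mass, and regressions on five
fixtures are illustrative, not inferential.
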