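# Methods

`coroflow` simulates blood flow and distal (outlet) pressure in single,
non-bifurcating coronary segments with a mild-to-moderate stenosis, under
the four modelling variants used in invasive validation studies of virtual
pressure assessment: rigid or deformable (fluid-structure coupled) wall,
each with steady or pulsatile flow. This note records the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Flow model

Blood is incompressible and Newtonian (density 1060 kg/m^3, dynamic
viscosity 0.0035 Pa·s), laminar throughout: with the default geometry
(radius 1.5 mm) and hyperemic distal velocities of 0.1–0.4 m/s, the
Reynolds number stays within the 126–883 band of the clinical cohort the
boundary conditions emulate. The Navier-Stokes and continuity equations
are discretized with equal-order trilinear (Q1-Q1) hexahedral elements,
stabilized with SUPG/PSPG. The stabilization parameter uses the *minimum
edge length* of each element:

tau = [ (2|a|/h_min)^2 + (4 nu/h_min^2)^2 ]^(-1/2)  ( + (2/dt)^2 transient ),

a deliberately conservative choice: with a streamline-based h on the
anisotropic boundary-layer/axially-stretched cells, the stabilization
residual (which cannot carry the viscous term on trilinear elements)
injects a spurious tau·(a·grad phi)·grad p force that visibly biases the
pressure drop of pressure-driven flow. With h_min the bias is below the
verification tolerances (see below). No grad-div/LSIC term is used; it
degrades the linear solver far more than it helps these low-Reynolds
flows.

Boundary conditions follow the measurement setup being emulated:

* **Inlet** — the measured (or synthesized) aortic-side pressure enters
  as a normal traction, mu dv/dn − p n = −p_in n. A *tangential*
  directional-do-nothing term, rho (a·n)_- (v_t, phi_t) on the inlet
  face, suppresses the transverse inflow modes that a pure traction
  condition leaves unconstrained. The term vanishes identically for
  axial flow, so it does not bias the imposed pressure (verified by the
  Poiseuille check below); without it the nonlinear iteration limit-cycles
  at ~0.5% velocity amplitude.
* **Outlet** — a fully developed Dirichlet profile (paraboloid
  v = 2 v_mean (1 − (r/R)^2), or a caller-supplied profile) scaled so its
  discrete area mean equals `velocity_ratio × v_measured`. The three
  study scenarios map the wire velocity to the profile mean with ratios
  1.0, 0.76 and 0.5.
* **Wall** — no-slip (equal to the mesh velocity in coupled transient
  runs).

The convective nonlinearity is resolved by Picard iteration (relative
increment < 1e-6; typically 6–20 iterations, with adaptive
under-relaxation engaging when the stenotic jet makes the plain
fixed-point map cycle). Each linearized system is
solved by GMRES with a block upper-triangular preconditioner: exact
(sparse-LU) solves of the component-shared scalar
convection-diffusion velocity block, and a pressure-convection-diffusion
(PCD) approximation M_p^-1 F_p L_p^-1 of the Schur complement, with the
constant pressure mode (determined by the traction inlet, not by the
Laplacian) handled by viscous mass scaling. After the Picard loop
converges, one deep warm-started solve (rtol 1e-13) is done so the
discrete continuity rows — and therefore global mass conservation —
hold to ~1e-9 relative.

Time integration is an implicit theta-scheme at the measurement step
dt = 0.05 s: backward Euler by default, Crank-Nicolson (theta = 0.5,
pressure kept implicit) where temporal accuracy matters. Transient runs
start from the steady solution at cycle-mean boundary values, which
removes multi-cycle spin-up for the cycle-mean pressure comparisons.

**Verification.** On a straight tube (R = 1.5 mm, L = 30 mm,
v_mean = 0.2 m/s; in-plane face size 0.3 mm, axial spacing 1.2 mm —
axial resolution is deliberately coarse because the solution is axially
invariant) the computed pressure drop is within 2% of the Hagen-
Poiseuille value 74.7 Pa and the sectional wall shear stress within 5%
of 4 mu v/R = 1.867 Pa; global mass conservation holds to ~1e-9. Under
single-harmonic oscillatory flow at Womersley number ~2.3 the mid-length
axial velocity profile stays within 5% of the analytic Womersley series
(Crank-Nicolson, dt = 0.025 s, second simulated cycle).

## Wall model

The wall is isotropic, homogeneous and hyperelastic with the
nine-parameter Mooney-Rivlin energy: a cubic polynomial in the deviatoric
invariant excesses (I1bar − 3), (I2bar − 3) plus a volumetric penalty
(1/d)(J − 1)^2 with d = 2/K. Nonzero coefficients: c10 = 0.07 MPa,
c20 = 3.2 MPa, c21 = 0.0716 MPa; small-strain shear modulus
2(c10 + c01) = 0.14 MPa.

The bulk modulus printed in the source material, K = 1e-5 (no units), is
physically untenable as a stiffness — it would make the wall essentially
a gas. We interpret arterial tissue as nearly incompressible and default
to K = 70 MPa, the value giving a Poisson ratio of ~0.499 against the
model's shear modulus; the literal value remains selectable through the
configuration for anyone wishing to reproduce the original solver's
input verbatim.

Discretization is total-Lagrangian hex8 with selective reduced
integration (the volumetric stress at a single central point) to avoid
locking at near-incompressibility; the consistent tangent is obtained by
forward-differencing the element internal force (24 columns per
element, vectorized across elements), and equilibrium is found by Newton
iteration. The interface traction is applied as a dead load on the
reference configuration — adequate at the ~10% strain of a pressurized
coronary wall, and consistent with the small interface displacements of
the coupled problem. Wall ends are fixed in all directions. Wall density
(1120 kg/m^3) enters only when the inertial term is enabled
(`quasi_static=False`, second-order backward differences); the default is
quasi-static because the validation quantity is a cycle-mean pressure.

**Verification.** A pressurized thick-walled cylinder (100 mmHg inside,
R 1.5→2.0 mm) matches an independent 1D radial-equilibrium shooting
solution of the same energy to 5%; volumetric strain stays below 1%;
scaling all stiffness coefficients by 10x scales displacement by 1/10
(linear regime).

## Fluid-structure coupling

Partitioned Dirichlet-Neumann iteration per (pseudo-)time step: fluid
solve on the current domain → interface traction
(−pI + mu(grad v + grad v^T))·n per wall face → wall solve → interface
displacement, relaxed with Aitken's dynamic under-relaxation (initial
factor 0.5, clamped to [0.05, 1]) until the relative interface-
displacement residual is below 1e-6 (≤ 25 outer iterations). The fluid
mesh follows the interface by harmonic (Laplacian) extension with
element-inversion guards, and the ALE convective term uses velocity
relative to the mesh velocity w = dx/dt. Fluid and wall meshes are
node-matched at the interface by construction (built from one
cross-section layout), so the transfer maps are exact; a
nearest-neighbour projection validates the match at build time (1e-6 mm).

**Verification.** With wall coefficients scaled 1000x the coupled steady
outlet pressure agrees with the rigid-wall solution to well under 0.5%,
and a zero-flow uniform-pressure case reproduces the standalone wall
solve.

## Geometry and meshing

Vessels are parametric tubes: base radius, optional linear taper,
optional circular-arc centerline, and a cosine-squared stenotic dip
reaching a fractional *diameter* reduction `stenosis_severity` at the
throat (C1 along arclength — hex meshing needs slope continuity). The
published study reconstructed real lumens from intravascular ultrasound
and angiography; no per-patient dimensions are available, so the
synthetic defaults (R = 1.5 mm, 30 mm length, severities 0.3–0.5) span
the mild-to-moderate range described there.

The lumen cross-section is a butterfly O-grid: a central square block
(corners at half the local radius) and a body-fitted band whose radial
spacing is geometrically graded toward the wall (ratio 1.2, first cell a
quarter of the face size) and capped at half the face size in the
interior — radial resolution controls how well the parabolic shear
profile is resolved, and this anisotropy buys accuracy at fixed cost.
The circumferential count is derived from the face size (multiple of 4);
the inscribed-polygon area deficit ~2 pi^2/(3 n^2) is the leading
geometric error, which is why tube-volume and patch-area checks carry 1-2%
tolerances. The wall shell reuses the same boundary rays: `n_layers`
structured brick layers of `layer_thickness` (defaults 15 × 0.03 mm) at
the interface, hexahedral fill outward. The final-resolution face-size
range used for production runs is 0.09–0.12 mm
(`meshing.DEFAULT_FACE_SIZE`); the study configuration defaults to
desk-scale sizes (0.3–0.45 mm), with the mesh-sensitivity protocol (<5%
WSS change vs the finest ladder rung) available to justify any chosen
resolution.

## Synthetic boundary data

The waveform generator replaces the combo-wire recordings: one cardiac
cycle (0.8 s) sampled at 0.05 s, a truncated 4-harmonic Fourier shape
with a systolic-weighted phase template (single dominant peak, diastolic
decay), exact prescribed cycle mean (aortic pressure 100 mmHg, pulse
amplitude 40 mmHg; distal velocity 0.2 m/s mean, 0.2 m/s excursion under
hyperemia), optional seeded additive Gaussian noise, velocities clipped
at zero. What it does *not* emulate: beat-to-beat variability, the wire's
actual noise spectrum, ECG timing, non-hyperemic baselines, and any
pressure-velocity phase relation beyond the shared template — so passing
consistency checks on synthetic data says the *solvers* are consistent,
not that patient-level agreement statistics are reproduced. The
published per-vessel pressures (the four simulation variants, the
velocity-ratio study, and both mesh ladders) ship as package data and are
the inputs to the statistics layer.

## Statistics layer

Ordinary least squares (computed/measured), Bland-Altman with the n−1
standard deviation and 1.96·SD limits, relative differences with the
"vs finest" denominator for mesh ladders (this convention exactly
reproduces all published non-selected difference cells) and with the
second-named approach as denominator for cohort comparisons (reproduces
the published 0.26% rigid-vs-coupled figure at two decimals). The
published 0.44% steady-vs-transient cohort mean is *not* recoverable from
the published per-vessel values under any simple denominator convention
(they give ~0.26–0.30%); the implementation computes the stated
definition and reports what it yields rather than targeting the printed
number. Computed-vs-measured series are aligned by resampling the
computed series onto the reference grid.

## Problem sizes and degenerate inputs

Verification and acceptance runs use desk-scale meshes (8k–15k elements,
1–15 s to 3 min per solve) chosen so every check runs on a single CPU;
the contracts being checked (closed-form oracles, consistency limits)
are resolution-verified rather than resolution-dependent. Degenerate
inputs fail loudly: zero wall thickness, stenosis extents outside the
vessel, face sizes that cannot resolve the throat, brick layers
exceeding the wall thickness, inverted elements during mesh motion, dt
not dividing the period, negative velocities in a velocity waveform, and
non-laminar Reynolds numbers all raise typed errors naming the violated
bound.

## Known limitations

Single unbranched segments only (no bifurcation outflow split); Newtonian
rheology; isotropic homogeneous wall without residual stress or
perivascular support; dead-load traction transfer (no follower-load
correction); Picard (not Newton) convective linearization; the pressure
inlet's tangential stabilization is a modelling regularization of an
ill-posed open boundary, standard but not unique; and the synthetic
geometry/waveforms stand in for patient data, so clinical agreement
metrics (r^2 against wire traces and per-patient pressures) are not
reproducible here by design.
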