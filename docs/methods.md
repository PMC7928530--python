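# Methods

`vesselflow` simulates blood at the scale of individual cells: a smoothed
dissipative particle dynamics (SDPD) fluid, triangulated elastic cell
membranes coupled to it by a particle-particle immersed-boundary (IBM)
scheme, a Morse surface potential for cell-cell interaction, and a
stochastic receptor-ligand bond model for tumor-cell adhesion to the
vessel wall.  This note records the model equations as implemented, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the desk-scale experiments do and do not show.

## Units

All internal quantities are dimensionless.  The characteristic scales are
the SDPD kernel cut-off radius `l' = 2 um`, the fluid particle mass
`m' = 1e-15 kg` and the thermal energy `e' = k_B * 300 K = 4.142e-21 J`,
so the dimensionless fluid temperature is 1.  Derived factors (time,
velocity, viscosity, surface moduli, kinetic rates, ...) are exact
functions of the three; `units.table1_dimensionless()` reproduces the
reference parameter table from its SI column at full precision.  The two
unstressed bond-rate rows are the one known inconsistency: dividing the
physical rates by the derived rate factor `sqrt(e'/m')/l' = 1017.6 1/s`
gives 1184 and 349 where the conventional printed values are 1205 and
355 (a ~1.7% discrepancy).  The package reports the computed values and
offers the printed convention as an explicit override.

## Fluid

The plasma and cytosol are one weakly compressible SDPD fluid at number
density 8 per cut-off cube (particle mass 1, rest density 8).  Pairwise
forces use the Lucy kernel with compact support at the cut-off:

* conservative: `F_C = m_i m_j (P_i/rho_i^2 + P_j/rho_j^2) F_ij r_ij`
  with the linear equation of state `P = c_s^2 (rho - rho_0)`; the sound
  speed is chosen per run so the Mach number stays below ~0.1, which
  keeps density fluctuations under ~2%;
* dissipative (Espanol-Revenga shear form):
  `F_D = -a_ij (v_ij + e (e.v_ij))`,
  `a_ij = (5 eta / 3) F_ij m_i m_j / (rho_i rho_j)` — its continuum
  shear viscosity is the input `eta` (verified to 0.25% against a
  reverse-body-force flow);
* random: the exact fluctuation partner of the pair friction tensor
  `Gamma = a_ij (I + ee^T)` at temperature `kBT`, with amplitude
  `sqrt(2 kBT) Gamma^{1/2}`.  The variates are variance-matched uniforms
  (standard dissipative-particle practice: only the first two moments
  enter the hydrodynamics); equipartition holds to <1% at the default
  time steps.

All three forces are antisymmetric per pair, so an isolated fluid
conserves linear momentum to round-off each step.  Thermal noise is a
counter-based stream keyed by `(seed, step, i, j)`: runs are
bit-reproducible and resumable regardless of pair iteration order.

## Walls

Vessel walls are particle scaffolds: *repulsive* particles on the nominal
surface and two *ghost* layers outside it, both entering the density and
viscous sums (ghosts carry the prescribed wall velocity).  Three
discretization choices place the hydrodynamic no-slip plane at the
nominal surface, calibrated once against the analytic Poiseuille profile
and then frozen:

* ghost layers are offset outward by half a wall spacing;
* fluid-wall pairs closer than half a cut-off get a short-range friction
  enhancement (x3 at contact, quadratic taper) that pins the boundary
  layer without adding bulk drag;
* a short-range quadratic repulsion keeps fluid and membrane particles
  off the surface, and membrane vertices are additionally hard-projected
  back into the lumen if they would cross it (a no-penetration
  constraint; the soft repulsion sets the actual standoff).

With these, a body-driven tube flow at diameter 10 cut-offs matches
`v(r) = rho g (R^2 - r^2)/(4 eta)` to ~3% L2; the residual error is the
kernel-smoothing bias of the velocity field (O((h/R)^2) at the profile
peak), which decays with tube radius.  A Morris-type extrapolated
ghost-velocity condition is implemented (`wall.morris_ghosts`) but off by
default: the antisymmetric extrapolation assumes fluid right up to the
surface and overshoots for curved profiles at this resolution.

## Membranes

Cell membranes are closed triangulated networks (icosphere tessellations;
the resting red cell is an Evans-Fung biconcave discocyte of maximum
diameter 3.91 cut-offs).  The deformation energy is

    U_def = U_s + U_b + U_a + U_v

with worm-like-chain (WLC) + inverse-length repulsion springs on edges
(each edge's contour length is `l_0 / x_0`, `x_0 = 1/2.2`, and its
repulsion coefficient balances the WLC tension at the stress-free length,
so the reference mesh is force-free edge by edge), dihedral bending
`K_B [1 - cos(theta - theta_0)]` with spontaneous angles from the
reference mesh, quadratic global/local area penalties and a quadratic
volume penalty.  The macroscopic moduli satisfy

    E_S = (sqrt(3) kBT / (4 p l_0)) [x_0/(2(1-x_0)^3) + 1/(2(1-x_0)^2)
          + 3 x_0 - 1/2]
    E_B = (2/sqrt(3)) K_B
    E_D = 2 E_S + K_AG + K_AL

and `calibrate_from_moduli` inverts them (persistence length from E_S;
the dilation surplus split K_AG:K_AL = 2:1 by default; the volume
constant set so fractional volume stiffness matches the area stiffness).
Every analytic force equals the central finite difference of its energy
to 1e-6 relative (the master oracle), and the network strain-hardens, as
a WLC network must.

Two numerical guards matter at coarse resolution.  (1) Inside the
time-stepping loop the WLC tension is held constant beyond 90% of the
contour length (a yield-like continuation), so a transiently extreme
stretch produces a large finite restoring force instead of a
singularity; the public `inplane_force` keeps the strict divergence
error.  (2) The dilation
modulus is a numerical restraint whose only job is to keep area and
volume within a few percent; the margination experiment halves it, which
keeps membrane area within ~3% at moderate flow (up to ~6% on the most
deformed cell at the strongest drive) while removing a stiff instability
of the membrane-fluid coupling.

## Fluid-membrane coupling

Membrane vertices carry no momentum: vertex k is advected with the
kernel-interpolated fluid velocity, and all membrane forces (deformation,
aggregation, adhesion, wall repulsion) are spread to the fluid with the
same kernel weights.  Both directions use weights normalized per vertex
(the spreading in the model statement is unnormalized; normalizing both
sides guarantees exact force conservation between the Lagrangian and
Eulerian representations and exact advection in uniform flow, and is the
package's deliberate choice).  Weights are recomputed every step.

Because a 162-vertex cell has vertex spacing (~0.64) larger than the
fluid spacing (0.5), fluid particles can leak through the faces; a
short-range (0.4 cut-off) fluid-vertex repulsion seals the membrane,
with its reaction spread back through the coupling so total momentum is
conserved.  An isotropic vertex-vertex excluded-volume repulsion between
different cells (range 0.3) prevents membrane interpenetration, which
the normal-projection-weighted aggregation term cannot do once surfaces
cross.

## Aggregation

Cell-cell interaction follows the Morse surface-element model: facing
triangle elements of different cells within a cut-off contribute

    phi(r) = E_I [e^{2 beta (r_0 - r)} - 2 e^{beta (r_0 - r)}]

weighted by `(n_m . k)(n_m' . k')` (outward normals projected on the
line between the cell centroids) and the mean element area.  Defaults
follow the weak-aggregation literature calibration `De = 0.3 uJ/m^2`,
`r_0 = 0.49 um`, `beta = 3.84 um^-1` (dimensionless 289.7, 0.245, 7.68);
no published value pins them for this exact system, so they are exposed
in the configuration.  The interaction cut-off defaults to 0.7 cut-offs,
where the potential has decayed to ~3% of its well depth.  Negative
projection products contribute with their sign (literal reading); a
clamp-to-zero variant is available.  Forces are the analytic gradient
through the element distance, areas and normals; the projection
direction k is held fixed during differentiation, since it varies on the
cell scale rather than the element scale.  The grid implementation
matches an O(N^2) double loop exactly, and forces satisfy action-
reaction per cell pair.

## Adhesion

Receptors are the membrane vertices of receptor-bearing cells; ligands
are fixed points on the wall.  A bond is a Hookean spring (strength
`E_A`, equilibrium length `lambda`), formed and broken by per-step
Bernoulli trials with `p = 1 - exp(-k dt)` and strain-dependent rates

    k_f = k_f0 exp(-sigma_f (x - lambda)^2 / 2 kBT)
    k_d = k_d0 exp(+sigma_d (x - lambda)^2 / 2 kBT)

plus forced rupture at the reactive distance `l_r`.  A receptor holds at
most one bond (candidates tried nearest-first); a ligand may hold
several unless forbidden; a bond broken in a step may re-form only in
the next step, which makes the static-receptor occupancy exactly the
two-state chain value `p_f/(p_f + p_d)`.  All draws are keyed by
`(seed, step, receptor, ligand)`.  The bond-kinetics temperature can be
set independently of the fluid temperature: a coarse-grained bond stands
for tens of molecular bonds and carries a correspondingly larger
effective strain compliance.

## Time integration

Velocity-Verlet: half-kick, drift (fluid positions and membrane
vertices), boundary bookkeeping (periodic wrap per axis, whole-cell
wrapping, outflow recycling in open geometries), full force recompute
(densities, SDPD pair forces, membrane forces, aggregation, adhesion
kinetics at post-drift positions, wall repulsion, coupling spread,
external drive), half-kick, and interpolation of the new fluid
velocities onto the membrane for the next drift.  Dissipative forces use
half-step velocities (the standard DPD-Verlet choice).  Neighbor lists
carry a 0.2 skin and rebuild when the largest minimum-image displacement
exceeds half of it; pair lists are kept in canonical order so a resumed
checkpoint accumulates forces bit-identically.  `timestep_bounds()`
reports the acoustic, viscous and bond-kinetics limits for a
configuration; the experiment defaults (5e-4 to 1e-3) sit below all
three with margin.

In the Y-bifurcation, fluid particles crossing the outlet plane re-enter
the inlet disk (count-preserving recycling) and a cell that fully exits
is re-injected at the inlet with its template shape; the drive is a body
force restricted to the inlet segment.  The aggregation and adhesion
interactions do not wrap across the periodic seam of a tube; at the tube
lengths used (>= 10 cut-offs against an interaction range of <= 1) the
missed pairs are a boundary-region effect.

## Desk-scale experiments

Problem sizes were chosen so the full validation battery runs on one
core in tens of minutes.

**Capsule on a plate** (`experiments.plate_adhesion`): a spherical capsule
of radius 1.25 cut-offs (one third the linear resolution of the
full-size benchmark, 642 membrane vertices) in a compact Couette channel
(6R x 3R x 4R).  The controlling dimensionless groups keep their
benchmark values: `Re = 0.1` at the low-shear case, `Ca` in
{0.005, 0.015} swept through the shear rate at fixed `E_S` (the
benchmark describes Ca as its shear-rate proxy), `K_SP = 250`,
`K_f = 10`, `K_d` in {1.0, 0.01}, `sigma_f = 0.02 E_A`,
`sigma_d = 0.98 E_A`, `E_B = 0.02 R^2 E_S`, `E_D = 100 E_S`.  The bond
lengths cannot keep the physical 50/375 nm (far below the particle
spacing); `lambda = 0.15` and `l_r = 0.3` are set by the discrete wall
standoff, the ligand density is 8 per unit area with site-limited
binding (one bond per ligand, so steady counts are set by the ligand
sites under the contact patch), and the bond-kinetics temperature is
1.8 (dissociation strain window ~40% of `l_r - lambda` at low shear).  At this scale the low-dissociation case arrests
("firm"), the low-shear case translates steadily with persistent bond
turnover ("rolling"), and the steady bond counts order firm > rolling >
detachment.  The detachment *end state* — all bonds gone, the cell
convecting freely — is not reachable here: the reactive distance is a
large fraction of R, the wall standoff keeps receptors in range, and
thermal membrane flutter re-captures the cell regardless of `K_d`; the
high-shear high-dissociation case appears as fast rolling instead.
That is a resolution limit of the scaled-down apparatus, not of the
model equations.

**Tube margination** (`experiments.margination_tube`): one spherical
tumor cell (diameter 4.5) on the axis of a periodic tube (diameter 8,
length 10) with ten red cells at ~19% hematocrit, seeded preferentially
in the outer annulus; microcirculation membrane moduli, fluid viscosity
50 (reduced from 197 so the flow develops within the run), drive tuned
to a wall shear rate of ~0.3 in rate units.  The tumor cell's centerline
deviation grows by an order of magnitude over the run, and the sign of
the radial aggregation force from the red cells agrees with the sign of
the deviation increment for the large majority of snapshots — the
mechanism linking aggregation to margination.  The red-cell mean radial
position does *not* shift inward here: a 4.5-diameter cell in an
8-diameter tube blocks the core wherever it sits, so no cell-free core
can form; that signature needs the full-size geometry (diameter ~11 with
~50 red cells).

**Y-bifurcation** (`experiments.bifurcation_flow`): a short smoke-scale
run; the tumor cell rides the parent axis into the wedge between the
daughter branches (diameters from the optimal-transport cube law) and
forms bonds in the junction region.

What passing these desk-scale runs shows: the coupled model produces the
qualitative phenomenology — state-dependent adhesion, aggregation-driven
margination, junction binding — under the published dimensionless
groups.  What it does not show: quantitative bond counts, margination
rates or network-scale statistics, which belong to the full-resolution,
cluster-scale configuration.

## Known limitations

* No membrane viscosity, no nucleus, no platelets.
* Near-wall hydrodynamics is accurate to the half-spacing scale; forces
  within the repulsion range are model terms, not resolved lubrication.
* The membrane impermeability barrier and inter-cell contact repulsion
  are coarse-resolution guards with ranges tied to the vertex spacing.
* Serial execution only; the production-scale network runs the model was
  designed for require distributed parallelism outside this package's
  scope.
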