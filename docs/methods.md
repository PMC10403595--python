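# Methods

`fontanflow` simulates passive (pump-stopped) flow through an idealized
total cavopulmonary connection (TCPC) carrying a cavopulmonary assist
device housing, and quantifies the hydraulic and thrombosis-surrogate
endpoints used to judge whether a stopped device obstructs the Fontan
circuit.  This note records the models, the numerical choices, and what the
synthetic geometry does and does not represent.

## Geometry model

The test section is a planar cruciform junction: two coaxial caval inlets
along ±y (SVC above, IVC below), two coaxial pulmonary outlets along ±x
(RPA right, LPA left), all of internal diameter 1.91 cm, meeting in a
housing that bulges biconically to a maximum diameter of 3.4 cm around the
junction center.  Arms extend 6 cm from the origin so that measurement
planes 4 cm out lie in straight tubing.  The optional obstacle is a
suspended biconical rotor stand-in (outrunner-style hub carrying
blade-like fins of height 1.09 or 1.62 mm, four per side, supported by six
radial struts at the equator).  The device's true cone angles, hub
diameter, strut cross-section and fillet radii are not public; the
stand-in exposes them as parameters (`hub_radius` 1.1 cm,
`hub_half_length` 1.6 cm, `strut_radius` 0.8 mm by default) chosen to
preserve the qualitative feature that matters for passive flow: a
low-resistance annular passage between rotor and housing.  Results on the
obstacle-bearing geometry therefore characterize the stand-in, not the
proprietary CAD.  The thin-film secondary flow path through the rotor
interior is absent by default and available only as a parameterized
annular gap (`secondary_gap`).

Blade fins of ~1 mm are below practical surface resolution at desk scale;
the `resolve_blades` flag removes them from the level set (the hub bicone
remains), and desk-scale case configurations run with blades unresolved.
The wetted-area comparison between blade heights is computed from the
parametric surface itself (`obstacle_surface_area`), independent of any
mesh.

## Mesh generation

Pipes and cone frustums use a structured disk-triangulation extruded along
the axis (prisms split into tetrahedra with index-ordered diagonals, which
makes the split conforming).  The junction is meshed from its level-set
description: surface points are projected onto the zero set, interior
points are seeded on jittered BCC lattices banded by a local size field,
and a Delaunay triangulation is filtered by the level-set sign at element
centroids.  Port rim circles (port plane ∩ wall) are sampled explicitly
because smooth-surface projection never lands on a crease.

Mesh quality is driven by four mechanisms, in order: Lloyd-style
relaxation passes (move-and-retriangulate, with surface nodes constrained
tangentially and re-projected), random-restart hill-climbing on nodes of
sub-gate elements (accepted only if the global count of bad elements does
not increase), bounded node deletion for stubborn sliver configurations,
and a final fixed-topology optimization that greedily moves each bad
element's nodes to the trial position maximizing the minimum dihedral
angle of its incident elements.  Flat "cap" elements riding the curved
wall (all four nodes on the surface, centroid depth a small fraction of
the local size) are filtered during triangulation, with a repair pass that
restores any cap whose removal would pinch the boundary.  Generation
retries with a shifted seed and fails loudly if the quality gate (minimum
dihedral angle above 10 degrees) cannot be met.

The x = 0 plane is an exact mirror of the geometry, so points are
generated in a half domain and the tetrahedra are reflected; the vertex
set is exactly symmetric, which also symmetrizes the discrete flow-split
problem.  For the blank housing, the y = 0 plane is mirrored too.  The
obstacle breaks equatorial symmetry (blade phasing, strut tangency), so
obstacle meshes mirror only in x.

Boundary layers follow the halving rule: with n layers, the target size of
the n-th innermost layer is h/2^n of the isotropic size h.  The grading is
realized as an isotropic near-wall refinement band of the volume size
field rather than as anisotropically compressed prism-like sheets; explicit
offset sheets of points parallel to the wall proved to be a reliable
source of degenerate (near-coplanar) tetrahedra under Delaunay meshing.
The reference sizing (h = 0.2 cm, tubing surface 0.09 cm, impeller 0.03
cm, strut 0.06 cm, 3 central / 1 peripheral layers) reproduces the
published mesh parameters of the study this pipeline emulates; desk-scale
work uses `MeshSizing.desk_scale()` (0.40 / 0.28 / 0.15 / 0.18 cm, one
layer), giving junction meshes of ~4,500-6,000 nodes that a laptop solves
in minutes.  Mean aspect ratio at desk scale is ~2.0 with minimum dihedral
above 10 degrees.

## Flow solver

Incompressible Newtonian flow (blood analog: density 1.06 g/cm^3,
viscosity 0.035 P) with equal-order P1-P1 tetrahedra and residual-based
SUPG/PSPG stabilization, plus an optional grad-div (LSIC) term.  The
stabilization parameters are stated explicitly because the literature has
many variants:

    tau_M = ( c_t/dt^2 + v^T xi v + C_I nu^2 (xi : xi) )^(-1/2)
    tau_C = 1 / (tau_M tr xi)

with xi the covariant element metric of the iso-parametric map,
c_t = 4 (`tau_dt_term` disables it), C_I = 3 (matching the coefficient in
the scalar-transport stabilization below), and nu the kinematic
viscosity.  The momentum stabilization weight is `rho (v . grad w) tau_M`
applied to the strong momentum residual (viscous term absent on linear
elements); the continuity weight is `(grad q) tau_M / rho`.

Boundary conditions: parabolic Dirichlet velocity profiles at the inlets,
flux-rescaled so the imposed discrete influx equals the prescribed flow
rate exactly even after no-slip zeroing of shared rim nodes; no-slip
walls; resistance outlets with traction h = -R Q n, where Q is the
instantaneous discrete outlet flux.  The flux coupling is implicit: it
adds a rank-one block R b b^T per outlet (b the boundary flux vector),
handled in the linear solver by a Woodbury correction around the sparse
LU.  Outlets also carry the standard convective backflow penalty
`-rho beta (v.n)_- w.v` with beta = 0.2.  Resistances reference zero
distal pressure; the 7.5 mmHg atrial offset of the physical loop is not
added, so absolute pressures are gauge relative to the distal bed.

Time integration is generalized-alpha for first-order systems
(alpha_m, alpha_f, gamma from the spectral radius rho_inf = 0.5; the
trapezoidal limit at rho_inf = 1).  Each step solves the nonlinear system
by Newton iteration with LU reuse: the factorized tangent is kept across
iterations and steps and rebuilt mid-step when the iteration stalls.  Two
tangents exist: an exact one obtained by complex-step differentiation of
the element kernel (machine-accurate, including the tau(v) dependence;
this is what `assemble_residual_jacobian` returns and what verification
tests difference), and a cheaper analytic Picard tangent (advection and
stabilization coefficients frozen) used by default for stepping, where it
only affects the Newton path, never the converged solution.  On Newton
divergence a step is retried once at half the step size, then aborts with
a partial-result status.

Steady cases are reached by marching the transient equations; the run is
declared stationary when the windowed means of the outlet flux/pressure
monitors drift by less than 1% between window halves.  Desk-scale runs use
dt = 0.025-0.05 s over 4-5 s of physical time; the reference settings
(dt = 1 ms, 5 s, saves every 20 ms, averaging window 2-5 s) remain the
defaults of `SolverParams`.  At the highest cardiac output the flow is
physically transitional; the coarse desk meshes and the damping of
generalized-alpha suppress vortex shedding, which is the expected behavior
of this problem size and is reported by the stationarity monitors rather
than hidden.

Pressure is gauge; conversions to mmHg (1333.22 dyn/cm^2) and mW
(10^4 erg/s) happen only in reports.

## Dye transport and washout

A virtual dye phi (0..1) is released as a 3.5 cm cube at the junction
center and advected through the frozen converged velocity field (one-way
coupling).  The weak form carries SUPG stabilization with

    tau_m    = ( 4/dt^2 + v^T xi v + 3 (kappa + kappa_DC)^2 xi:xi )^(-1/2)
    kappa_DC = |L(phi)| / (2 sqrt(grad phi^T xi grad phi))

where L is the advection-diffusion operator; on linear elements its
diffusive part vanishes element-wise, and the element value of |L| is the
signed mean over the quadrature points (it cancels on resolved smooth
fields, so the added diffusion localizes to under-resolved fronts).  The
molecular diffusivity kappa is not a measured quantity here; the default
0.01 cm^2/s keeps the Peclet number far above one so washout is
advection-dominated and the exact value immaterial at the reported
timescales.

kappa_DC makes the system stiffly nonlinear exactly at the discontinuous
initial front, so each time step runs one or two frozen-coefficient outer
passes: kappa_DC (and with it tau_m) is held fixed while the then-linear
system is solved by Newton with LU reuse, and refreshed from the first
converged pass.  The initial rate phidot(0) is obtained from a lumped-mass
solve of the spatial residual, which removes the startup ringing of
generalized-alpha on the discontinuous initial condition; transport uses
rho_inf = 0.2.  Transport steps (default 2 ms, desk scale 5-10 ms) are
independent of the flow step because the scheme is implicit.

The washout time T(x) is the interval from the nodal concentration peak to
the first decay below 1% of that peak, with linear interpolation between
snapshots.  The peak time is the first attainment within 0.5% of the
maximum: bounded ripples on a concentration plateau otherwise push the
recorded peak arbitrarily late.  Nodes that never cross the threshold
within the simulated window are right-censored, flagged, and excluded from
volume-weighted means (the censored volume fraction is reported, never
extrapolated).  Overshoot beyond [-0.05, 1.05] is tracked on the series
and warned about, not clipped.

## Endpoints

Wall traction comes from the single adjacent element's constant velocity
gradient (sigma = -p I + 2 mu strain rate), with the normal component
projected out, so tau . n = 0 holds exactly; no superconvergent patch
recovery is attempted, and the Poiseuille suite demonstrates convergence
of this simple recovery.  TAWSS is the magnitude of the time-averaged
traction vector (not the average of magnitudes); OSI is
(1/2)(1 - |int tau| / int |tau|), clipped to [0, 1/2] with zero-traction
faces assigned 0.  The low-WSS area fraction uses the conventional
empirical threshold of 5 dyn/cm^2 (configurable).  Mean TAWSS values are
area-weighted; whether the original figures weight by area is unstated,
and this choice is documented rather than hidden.

Cut-plane pressure drops average static pressure over circular sample
grids on planes 4 cm from the origin (area-weighted static pressure, the
quantity a liquid-filled catheter reads, rather than flow-weighted total
pressure), time-averaged over the analysis window, reported per
inlet-outlet pair in mmHg.  Power loss is the net energy flux
`sum (p + rho |v|^2 / 2) (v . n)` over the ports.  Flow splits are
windowed mean outlet fluxes normalized to 100%.

## Comparison utilities

Reference (mock-loop) measurements are not public; the Bland-Altman /
correlation utility consumes any user CSV of labeled values, and the test
suite exercises it with a clearly labeled synthetic table.  Limits of
agreement use the sample standard deviation (n-1).  Reynolds numbers are
reported from Re = 4 rho Q_ivc / (pi D mu) with D = 1.91 cm; the reference
values reported for the original experiments (674...2250) are attached as
an annotation column because they are not consistent with this formula at
the stated fluid properties and flow split (CO = 3 L/min gives ~606), and
the table deliberately reports its own numbers.

## What the synthetic setup does and does not show

The generator reproduces the printed geometric, fluid and boundary
parameters of the bench experiment (tube diameter, housing Dmax, blade
heights, 60/40 caval split, 204.51/222.49 dyn s/cm^5 outlet resistances,
cardiac outputs 3-11 L/min), but not the proprietary rotor shape, the
physical loop's compliances and impedance networks, pulsatile or
respiration-dependent inflow, vessel distensibility, or non-Newtonian
rheology.  Desk-scale meshes are two to three orders of magnitude smaller
than the reference meshes (millions of elements), so pointwise WSS and the
fine structure of separation zones are not converged; the bound-type
claims (pressure drop below 2 mmHg at 7 L/min, washout within 2 s at
3 L/min, resistance-set flow split) are robust at this scale, and the
verification suite (Poiseuille, plug-flow washout, Jacobian and temporal
order checks) establishes correctness of the discrete operators rather
than fidelity to the physical device.

## Known limitations

* Mesh-convergence of the obstacle-case pressure loss at desk scale is
  slow: the baseline and 0.7x-refined desk meshes still differ by well
  over the few-percent level that the reference-scale mesh study reports;
  the sensitivity check measures this honestly instead of imitating the
  asymptotic result.
* The port-adjacent boundary triangulation is ragged at coarse sizing;
  port-disc areas carry a few percent error (flux imposition is exact by
  rescaling, and outlet fluxes integrate the same discrete surface).
* Backflow stabilization and resistance coupling are implicit, but the
  lumped (nodal) quadrature of the backflow term is first-order on the
  boundary.
* The washout 1% threshold sits near the discretization's oscillation
  floor; washout statistics at desk scale carry a few percent of bias
  either way, as quantified by the plug-flow verification.
* On junction meshes the dye release (a cube whose faces cut through the
  near-wall refinement band) can overshoot the [-0.05, 1.05] band locally
  during the first few steps; the series records and warns about the
  excursion.  The washout means are robust to it (peaks are per-node and
  the censored fraction is reported), but pointwise concentrations near
  the release boundary should be read with that caveat.
* Desk-scale junction endpoints carry mesh-realization scatter: the same
  sizing with a different seed moves the worst-pair pressure drop by a few
  percent, which dominates coarse-vs-refined comparisons (see the
  mesh-sensitivity discussion above).
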