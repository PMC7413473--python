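# Methods

`cathflow` models the hemodynamics of hemodialysis catheter tip side-holes at
desk scale: a two-dimensional planar analog of a symmetric-tip catheter
inserted along a vein, solved with a finite-volume SIMPLE scheme, traversed
by Lagrangian platelets, and scored with shear-exposure and platelet-lysis
metrics. This note records the model, its assumptions, the numerical choices,
and what the desk-scale analog can and cannot say about the 3D device.

## The 2D toy domain

The vessel is a rectangular channel (x axial, y transverse; defaults
50 mm x 20 mm, the width matching a 20 mm superior-vena-cava bore). The
catheter runs along the top boundary: a 3 mm open slot lumen under the top
wall — the height of one semicircular lumen of a 5 mm-bore symmetric-tip
catheter — separated from the vessel by a 2 mm wall, inserted 30 mm, and
closed distally by an end cap. Blood enters the lumen through a 5 mm tip
opening next to the cap and through up to two side-holes cut in the wall;
hole edges are square (`straight_cut`, a drilled circular hole) or chamfered
at 45 degrees widening outward (`angled_cut`, a skived oval hole). Side-hole
distal edges sit 16.5 mm from the tip end in every compared design, so
designs differ only in the feature under study.

Boundary conditions follow the study conditions: uniform 0.3 m/s vessel
inflow, gauge pressure 0 at the vessel outlet, no-slip walls, and a suction
pressure at the lumen outlet (the catheter base at x = 0) that is *adjusted*
— by a secant iteration on the outlet pressure — until the lumen extracts
the pump flow target. Volumetric targets are converted between 3D mL/min and
2D per-depth flux using the lumen height as the out-of-plane depth; all
reported mL/min values are therefore "2D-equivalent". The default target is
the 400 mL/min dialysis pump rate (2.22e-3 m^2/s per unit depth).

A "parallel" dual-hole arrangement (two holes side by side around the
circumference) has no 2D analog; only `single` and `dual_linear` (two holes
along the axis) exist here. This is a documented limitation of the planar
analog.

## Blood rheology

Blood is shear-thinning; the asymptotic Carreau law is used with the
whole-blood constants mu_inf = 3.45 mPa s, mu_0 = 25 mPa s, lambda = 25 s,
n = 0.25:

    mu(g) = mu_inf + (mu_0 - mu_inf) * [1 + (lambda*g)^2]^((n-1)/2),

where g = sqrt(2 D:D) is the shear-rate magnitude of the strain-rate tensor
D. The scalar shear stress reported everywhere is tau = mu(g) * g, the
conventional viscous stress magnitude for laminar non-Newtonian reporting.
Setting n = 1 degenerates the law to a constant viscosity mu_0, which is how
the Newtonian verification cases are run.

## Flow solver

Steady incompressible laminar flow on a uniform staggered (MAC) grid:
pressure at cell centers, velocity components on faces, SIMPLE
pressure-velocity coupling with under-relaxation (defaults 0.7 velocity /
0.3 pressure; automatically reduced and retried if a coarse grid diverges).
The Carreau viscosity is re-evaluated from the local shear rate every outer
iteration (Picard linearization, relaxed by 0.7).

Convection is implicit first-order upwind plus an explicit deferred
correction to a minmod-limited linear-upwind (second-order) flux. The
correction is enabled once the first-order iteration has pre-converged
(residual < 1e-3) — switching it on from a cold start destabilizes the
transient — and its source is relaxed in pseudo-time (factor 0.5). The
limiter matters: the unlimited second-order flux sustains wiggle-driven
limit cycles in the hole-jet shear layers; minmod suppresses them at the
cost of locally first-order behavior at extrema. Diffusion is central, with
the half-cell no-slip correction at transverse walls. Geometry is rasterized
cell-by-cell (a cell is solid if its center lies in catheter material);
chamfers come out stair-stepped at the requested slope to within one cell.
Every fluid opening must be resolved by at least three cells; a solid wall
is watertight on a staggered grid at one cell, so walls only require one.

The vessel outlet and lumen outlet are fixed-pressure cells excluded from
the pressure-correction system; boundary faces copy the interior
(zero-gradient). The pressure-correction (SPD) system is solved by CG
preconditioned with a sparse LU factorization that is reused across outer
iterations and refreshed periodically or whenever CG degrades; CG runs at
rtol 1e-6 — the correction need not be machine-exact because the convergence
residual is measured on the momentum solution before correction. Momentum
systems get a few red-black Gauss-Seidel sweeps per outer iteration.

Convergence requires both (a) the scaled continuity residual — the sum of
absolute cell mass imbalances over the inlet mass flux — below 1e-5, and
(b) the recovered lumen outflow within 0.25% of target (the analog of
400 +/- 1 mL/min). The residual scaling is a package choice; commercial
codes scale their published residuals in unstated ways, so absolute residual
values are not comparable across codes. Everything is deterministic:
identical configuration gives bit-identical fields and reports.

The converged staggered solution is exported to a node-centered rectilinear
field (averaging face values; nodes on any wall surface carry exactly the
no-slip zero). All downstream consumers — interpolation, gradients, metrics,
tracking — read this node field, and it round-trips through VTK legacy ASCII
(RECTILINEAR_GRID, point data `velocity`, `viscosity`, `mask`) at full
double precision.

## Platelet tracking

Platelets are dilute rigid 2 um spheres, density 1060 kg/m^3 equal to the
carrier fluid (platelet and blood densities are not independently
constrained here; the neutrally-buoyant default also makes gravity moot).
Coupling is one-way. Forces per unit mass:

* Schiller-Naumann drag: a_D = 18 mu/(rho_p d_p^2) * (C_D Re/24) (u - u_p),
  with C_D = 24(1 + 0.15 Re^0.687)/Re for Re <= 1000 and 0.44 beyond; the
  Re -> 0 singularity never arises because only C_D*Re (-> 24) is used.
* Generalized Saffman-Mei shear lift with K = 2.594, proportional to the
  strain-rate tensor acting on the slip, normalized by (D:D)^(1/4); it
  reduces to the classical Saffman formula in simple shear (verified in a
  test by hand reduction) and is defined as zero when the strain rate
  vanishes.

The drag response time rho_p d_p^2/(18 mu) is about 7e-8 s — far below any
affordable time step — so each step integrates the drag analytically
(exponential integrating-factor update for velocity and its exact integral
for position, holding local fluid quantities frozen over the step). Steps
are sized to advance about one target spatial step (default 0.5 um, the
recording resolution at which the damage dose is accumulated); each records
time, position, particle and fluid velocity, local shear rate and scalar
stress, and the step duration. Termination: leaving the domain through the
lumen outlet or vessel outlet, a residence-time cap (default 1 s), or
stagnation (speed below 1e-6 of the reference speed for 10^4 consecutive
steps). A step-count cap (2e6) bounds memory on pathological paths and is
reported as a time-cap termination.

Seeding mirrors the study protocol: platelets start on a plane 1 mm outside
the catheter surface spanning each side-hole opening, on a uniform
deterministic layout, at the local fluid velocity. The per-plane seed count
is a configuration parameter (default 20; no value is externally
constrained). Excluded physics: Brownian motion, near-wall lift
corrections, particle-particle interaction, adhesion, activation-state
dynamics, two-way coupling.

## Damage metrics

The platelet lysis index accumulates the power-law dose
A t^0.77 tau^3.075 (A = 3.31e-6) step by step along each path line: each
recorded step contributes A dt^0.77 tau^3.075, per-line doses are summed,
and the ensemble score is the arithmetic mean of per-line sums (no velocity
weighting). Because dt^0.77 is sub-additive the per-line sum depends on the
recording step; the 0.5 um default is therefore part of the metric's
definition, not a numerical knob — halving it changes the score. An
alternative `per_step` reading (grand dose sum over grand step count) is
provided as a switch. Platelet shear statistics (mean stress, percent of
exposure above the 10 Pa activation threshold, mean shear rate) are
time-weighted by default, with a step-weighted (path-length-like) switch;
the two differ where speed varies along the path.

Eulerian "tip volume" statistics are evaluated over a fixed rectangle at
the inflow lumen (default: the lumen band from the distal tip 24 mm
proximally, covering the side-hole region) so competing designs are scored
over identical territory: maximum speed, fluid-area-averaged scalar shear
stress, and the percent of the region above threshold. Opening flow rates
(per side-hole and tip opening) are signed sums of face fluxes across the
opening on the lumen-surface row of the staggered solution, positive into
the lumen; their sum balances the lumen outflow to within the continuity
tolerance.

## Grid-convergence study

The study solves the same design on successively finer grids (halving
spacings) and monitors the maximum tip-region speed and the average
tip-region shear rate, flagging the first level at which both change by
less than 0.5% from the next-coarser level. Two definitions matter for a
fair comparison across grids:

* the average is a cell-trapezoid *integral* average over the region's
  fluid area — a plain mean over fluid nodes drifts O(h) simply because
  refinement places nodes ever closer to the walls, where shear peaks;
* the maximum is taken over a fixed probe lattice (0.25 mm spacing)
  interpolated from each level's field, so the sampling set never changes.

Study levels run to continuity residual 1e-4 rather than 1e-5; the
monitored metrics differ by about 2e-6 relative between the two tolerances
(measured), while the final decade of residual costs roughly 40% of a
level's iterations. Each level warm-starts from the previous one (bilinear
prolongation of velocity, pressure and outlet suction). Levels carry
optional outer-iteration budgets; a level that exhausts its budget ends the
sequence gracefully with the completed levels reported, and a sequence that
never flags is returned unflagged rather than raised as an error.

### What the study shows at desk scale

On the default toy design at the study's boundary conditions the monitored
metrics change by 13.6%/23.5% between the 1.0 and 0.5 mm levels and by
6.8%/14.8% between 0.5 and 0.25 mm — a roughly first-order decay. The flow
sets an intrinsic resolution scale: the hole jet and tip shear layers are
O(sqrt(nu L / U)) ~ 0.1-0.3 mm thick, so sub-half-percent metric stability
extrapolates to ~0.03 mm spacing (over 10^6 cells), far beyond a
single-CPU Python SIMPLE solver. Clinical-scale 3D studies of this kind
reach such criteria with meshes of tens of millions of body-fitted
elements solved on HPC clusters. The study *procedure* is verified
independently: on closed-form fields refined the
same way it flags immediately, and the flag logic is exercised in the test
suite. At desk scale the sequence documents how far from mesh-independence
the affordable grids are, which is itself the honest output of the
procedure.

## Problem sizes used by the tests and the acceptance script

Solver verification uses a 40-cell-across Newtonian channel (Poiseuille to
within 2%); the toy-design solves run at the default 0.5 mm spacing
(100 x 40 cells); the refinement study runs 1.0/0.5/0.25 mm in the test
suite and attempts a fourth 0.125 mm level under an explicit iteration
budget in the acceptance script. Tracking verification uses analytic
fixtures with spatial steps of 1e-5 to 1e-4 m, where closed forms provide
exact oracles; the 0.5 um default applies to production scoring runs.
These are the package's desk-scale choices and are stated here so results
can be reproduced exactly.

## Known limitations

* Planar 2D analog: absolute values (speeds, stresses, flows, PLI) are not
  comparable to 3D device values; only within-family comparisons under the
  identical protocol are meaningful — and at affordable grids even those
  carry the discretization uncertainty quantified by the refinement study.
* Only the inflow (arterial) lumen is modeled; the return lumen and its
  outflow jet are outside the domain, so outflow-side shear is not scored.
* No pulsatility, vessel compliance, clot/fibrin growth, or in vitro
  validation; the laminar steady assumption follows standard comparative
  catheter CFD practice.
* The synthetic fixtures (uniform, Couette, Poiseuille, stagnation) validate
  transport, interpolation and scoring machinery exactly, but contain none
  of the separated, recirculating flow structure of real tip hemodynamics;
  passing fixture tests demonstrates correctness of the machinery, not
  fidelity of the toy flow to a real catheter.
* Stair-step rasterization perturbs chamfered edges by up to one cell;
  achieved opening lengths are reported by the rasterizer.
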