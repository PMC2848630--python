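# Methods

`mesobd` is a mesoscopic, particle-based Brownian-dynamics simulator for
reaction-diffusion systems of multi-state molecular complexes. This note
describes the model it implements, the numerical choices behind it, what
the bundled synthetic models emulate, and the limits of what the test
suite demonstrates.

## Molecular representation

Molecules are represented on three levels. **Particles** are the geometric
building blocks: each carries a hydrodynamic radius, a diffusion-landscape
tag and any number of three-point **reaction sites** (centre point, a
second point defining the outward normal vector, a third defining the
in-plane plane vector; the two vectors fix binding geometry).
**Entities** are permanent molecules assembled from particles; they never
decompose at run time and carry user-defined, enumerated **feature
states** (phosphorylation, ligand occupancy, gating, ...).  **Clusters**
are the mobile objects: one or more entities connected by bonds, moving as
a rigid body.

A cluster's hydrodynamic radius is that of a sphere whose volume equals
the sum of its member particle sphere volumes, `r = (sum r_i^3)^(1/3)`.
Positions are nested (site in particle frame, particle in entity frame,
entity in cluster frame, cluster relative to the centre of the cubic
volume); orientations are unit quaternions (right-handed, active
convention), entered in the model file as axis-angle-free three-point
sites.  When clusters merge, the merged centre of mass is the
hydrodynamic-volume (`r^3`) weighted mean of the former centres — masses
are never modelled, `r^3` is the universal mass proxy — and every entity
keeps its world pose exactly, re-expressed in the new frame.

## Diffusion

Each time step of length `dt`, every non-static cluster receives a
displacement whose active components are drawn from `N(0, 2 D dt)`
(solution of Fick's second law over one step).  The diffusion coefficient
depends on the cluster's *effective landscape*, the most limiting tag
among its particles (`static > membrane > above/below membrane >
unrestricted`):

* 3D landscapes: Stokes–Einstein, `D = kB T / (6 pi eta r)`;
* membrane: Saffman–Delbrück for a cylinder of radius `r` spanning a
  membrane of thickness `h` (default 5 nm) and viscosity `mu` bounded by
  fluid of viscosity `eta_w` (default 1e-3 Pa s):
  `D = kB T/(4 pi mu h) * (ln(mu h/(eta_w r)) - gamma)`, valid only while
  the logarithm exceeds Euler's constant `gamma`; outside that regime the
  model is rejected with guidance;
* static: `D = 0`, no translation or rotation ever.

Because rotational diffusion is much faster than translational diffusion
at these scales, clusters assume a fresh random orientation every step:
uniform over SO(3) for 3D landscapes, a uniform rotation about the
membrane normal (+y) for membrane clusters.  Circular membrane domains
may locally override the membrane viscosity; the innermost (smallest
radius, then lexicographic id) containing disc wins, and a point exactly
on a circumference counts as inside.

## Boundaries

Crossing detection is endpoint-based: a cluster interacts with a boundary
only if its end-of-step position is on the far side, matching the
mesoscopic step model (a path that exits and re-enters within one step is
not a crossing).  Each boundary carries a set of (interaction,
probability) pairs summing to one; one interaction is drawn per crossing:
open (pass; on an outer face of the volume this drops the cluster from
the tracked system), absorbing (remove), periodic (translate across the
volume), reflective (mirror about the plane).  Multiple simultaneous
crossings are handled nearest-first along the movement segment, repeating
until the position is valid (bounded at 100 rounds).  Clusters restricted
to a half-space treat the membrane plane as reflective.  Membrane-domain
circles use the same endpoint rule with radial mirroring; periodic
conditions on a circle are rejected at load.  All six outer faces default
to reflective (mass-conserving) unless the model file says otherwise.

## Reactions

**Zeroth order** (k in M/s): the mean number of molecules created per
step in a region of volume `V` is `lambda = k dt V N_A`.  At
initialisation, creation times are drawn as exponential inter-arrival
times with rate `lambda/dt` out to the end of the run and stored in the
event schedule, which makes the per-step counts exactly Poisson(lambda)
and costs no randomness at run time.

**First order** (k in 1/s): when a reactant (entity, or bond for
dissociation) comes into existence, a waiting time is drawn from Exp(k)
by inversion of a uniform variate and converted to the iteration index
`now + ceil(t/dt)`.  Events are stored in an iteration-indexed schedule
with a per-target index; any reaction or state change that invalidates a
pending event removes it, and a fresh event is drawn under the new state.
Guards are re-checked at execution time as a second line of defence.

**Second order** (k in 1/(M s)): the Smoluchowski/Andrews–Bray binding
radius scheme.  Two free sites of matching types react when their centres
end a movement step within a distance `sigma`.  `sigma` is calibrated so
that the *steady-state* rate constant of the diffuse-then-absorb
iteration equals `k` for the reactants' mutual diffusion coefficient
`D_mut = D_A + D_B` and the step `dt`.  In units of the rms relative step
per axis `s = sqrt(2 D_mut dt)`, the absorbed volume per step `kappa` is
a universal function of `sigma/s`; it is computed by solving the radial
steady state of the iteration directly as a linear system (midpoint
quadrature on a non-uniform grid, image kernel about the origin, far
field matched to the harmonic profile `1 - A/r`), and inverted for
`sigma` by bracketed root finding.  The solver reproduces both analytic
limits: `kappa -> 2 pi (sigma/s)` (Smoluchowski) for `s << sigma`, and
`kappa -> (4 pi/3)(sigma/s)^3` (single-step sweep-up) for `s >> sigma`.
Binding radii are cached per (rule, rate, `D_mut` rounded to 4
significant digits); they are pre-computed from template diffusion
coefficients to validate the voxel size, and recalibrated from the
clusters' current coefficients at resolution time.

**Feature-state guards** scale or disable a rule's rate per reactant
state (first matching guard wins, declaration order); a disabled rule
never fires and a scaled rate is used for its own `sigma` calibration.
**Effects** set a feature state or shift it along its declared
enumeration (`advance`/`retreat`, saturating) — the shift form is what
lets one binding rule count occupancy (0 -> 1 -> 2) without separate
rules per state.

**Binding geometry.**  When a bond-forming rule fires, the two clusters
are rigidly transformed so that the site centre points coincide, the
normal vectors become anti-parallel and the plane vectors parallel.  The
rotational and translational burden is split in proportion to
hydrodynamic volume (larger partners move less), within landscape limits:
membrane clusters rotate only about +y and keep their y coordinate,
static clusters do not move.  The final, exact alignment is always
performed by the less restricted partner (free > membrane > static; ties
resolved so the smaller cluster finishes); if the restrictions make exact
alignment impossible (e.g. two incompatible static partners), the
reaction is aborted and counted, not botched.  Dissociation reverses
this: the bond is removed, connected components of the bond graph become
clusters, and the fragments are pushed apart along the former normal so
the freed site centres end up exactly one forward-rule binding radius
apart — without an explicit unbinding radius this makes reversible pairs
geminate-recombination-prone, a known property of the scheme.

**Voxel partner search.**  The volume is divided into `n_v^3` cubic
voxels, each required to be strictly larger than every calibrated binding
radius.  Free reactive sites are re-registered after each movement step;
candidate pairs are sought only within each site's 27-voxel
neighbourhood, which is complete under the size constraint (verified
against an all-pairs oracle).  Occupied voxels are processed in a freshly
shuffled order with random tie-breaks inside a voxel, each unordered pair
emitted once; intra-cluster pairs are never emitted.  The inner scan is a
numba-compiled kernel with an occupancy bitmask (a pure-numpy path is
used when numba is unavailable).

## The iteration cycle

Each executed iteration runs, in order: user events; zeroth-order
creations; scheduled first-order events (schedule order, guards
re-checked); Brownian translation and rotation of all non-static clusters
in a freshly shuffled order; boundary resolution; voxel re-registration;
bimolecular resolution; trace output if the iteration index is divisible
by the output divisor.  Iterations in which nothing can happen (no mobile
cluster, no scheduled event) are skipped wholesale; output is only
written for executed iterations.  Elapsed time is exactly
`iteration * dt`.  A single seeded variate stream drives every stochastic
choice, so identical seed and configuration reproduce traces byte for
byte.  The stream is PCG64-backed; an opt-in pre-computed-list mode
(two lists of 250 000 values, refreshed on exhaustion by shuffling ten
sections and replacing one round-robin) trades statistical quality for
fewer generator calls.

## Synthetic validation models

The generator module builds the models the validation suite runs; their
defaults are the study conditions and are not tuned per test.

* **Free-diffusion tracers**: inert particles whose landscape viscosity is
  solved so the requested `D` holds exactly (for the membrane case the
  Saffman–Delbrück relation is inverted on its physical, decreasing
  branch).  MSD is measured with the standard ensemble/time-origin
  estimator: displacements over non-overlapping 100-step windows of
  1000-step trajectories, 1000 tracers, compared against `6 D t` (3D) or
  `4 D t` (membrane, with the y component identically zero).
* **Creation and decay boxes**: immobile product/reactant species in a
  1 fL volume so that the whole run exercises the event scheduler and
  iteration skipping; creation uses `k0 = 1e-6 M/s`, `dt = 1 ms`
  (`lambda = 0.602`), decay `k1 = 1 /s` over 10 s with 10^4 molecules.
* **Association box**: irreversible A + B -> AB, 1000 + 1000 molecules,
  periodic cube, equal `D = 1e-11 m^2/s` (2 nm radius in a
  cytoplasm-like viscosity), `k = 3e8 /(M s)`.  The time step is set so
  the reduced step `s/sigma` is 0.1 against the Smoluchowski radius, and
  the box side so the mass-action half-life spans 16 000 steps.
* **Membrane assembly model**: membrane receptors R (one binding site,
  normal along +y), scaffolds B and ligands A above the membrane.  B has
  two R sites (normals -y) and one A site whose rule is gated by B's
  `rbound` feature: it only becomes available once both R sites are
  occupied.  All rates 5e6 /(M s), irreversible; default counts
  A=B=1000, R=100 in a 200 nm box (scaled counts shrink the box to keep
  concentrations), `dt = 1 us`.

## Known limitations and expected deviations

* **Smoluchowski transient.**  At `s/sigma = 0.1` the calibrated
  absorbing-sphere scheme is diffusion-limited, so the classical
  time-dependent rate coefficient `k(t) = k (1 + sigma/sqrt(pi D_mut t))`
  applies and the early course is *faster* than the plain mass-action
  ODE.  Because the time step is tied to `sigma` through the reduced step
  length, the integrated excess over a window of M steps is parameter
  free — about `16/sqrt(M)` — and the expected deficit of the
  free-reactant count at the half-life is of order `67/M + 5/sqrt(M)`
  (the first term is the burst of pairs that start within `sigma` of
  each other).  The association box's default window of 16 000 steps to
  the half-life is the longest that keeps the ten-seed validation
  ensemble inside its run-time budget, which leaves an expected residual
  transient bias of roughly 4-5 percent at the half-life: the
  mass-action comparison in the validation suite therefore sits at the
  edge of its tolerance by construction, and the suite records its
  measured value rather than hiding it.  Halving the time step does not
  change the result (the transient is physics, not discretisation),
  which is exactly what the built-in step-halving heuristic verifies.
* Excluded volume between non-reacting clusters is not modelled; complexes
  are rigid; membranes are flat planes.
* Unbinding places fragments at contact (`sigma`), so reversible pairs
  re-encounter more often than a scheme with a larger unbinding radius.
* Bimolecular resolution within one iteration uses the site positions
  computed after the movement step; positions moved by an earlier binding
  in the same iteration are not re-evaluated until the next step.
* The synthetic models use point sites on single-particle entities except
  where geometry is under test; passing tests demonstrate the engine's
  statistical and geometric correctness under the stated conditions, not
  fidelity to any particular biological system.
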