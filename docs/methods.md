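# Methods

`tissuesim` simulates two-dimensional plant tissue as a polygonal mesh of
well-mixed cellular compartments.  Biochemistry is written as compact
reaction "arrows" that compile automatically to per-cell ODEs; cells are
coupled by wall-mediated diffusion, transport and juxtacrine signaling;
tissue shape evolves through spring–pressure vertex mechanics with
irreversible wall growth; and cells divide when a monitored quantity
(area by default) passes a randomly drawn threshold, with the new wall
placed by Errera's rule or a configurable potential model.  This note
records the model equations, the numerical choices, and the design
decisions made where the design was genuinely open.

## Reaction arrows and rate laws

The canonical arrow `e1 X1 + e2 X2 + ... -> f1 Y1 + ...` with rate
constant *k* contributes, by mass action,

    d[U_j]/dt = (f_j − e_j) · k · ∏_i [X_i]^{e_i}

to every species *U_j* in the reaction.  Reversible arrows (`<->`)
expand to two opposed irreversible ones.  Enzymatic arrows expand to
elementary steps with automatically named bound complexes (`X_E`, with a
numeric suffix on collision): the 2-step mechanism `X+E <-> X_E <-> Y+E`
(4 rate constants), the 3-step variant with a bound product complex
(6 constants), double-enzyme forward/backward conversion (8), and
cascades expanded pairwise.  These expansions conserve total enzyme
exactly in the generated ODEs; the test suite checks this identity.

Regulatory arrows (`|->`, inputs not consumed; `=>`, substrate
converted) carry one of the rate laws Hill, GRN, S-System, NHCA,
rational, user-defined, Michaelis–Menten, or MWC; all are evaluated by
one polymorphic routine that serves both the scalar single-compartment
API and the vectorized whole-tissue engine, so the two paths cannot
diverge.  GRN-type laws use a saturating control function: the logistic
`1/(1+e^{−x})` or the algebraic sigma variant

    f(x) = (1 + x/√(1+x²)) / 2,

which is monotone, bounded in (0, 1), and equals 1/2 at 0.  Any
monotone saturating function works here; sigma is the smooth algebraic
choice exposed under the `control="sigma"` keyword.  Stoichiometries
are restricted to positive integers.

## Tissue meshes

A tissue is a vertex list, an edge list (vertex-index pairs), and cells
as ordered edge loops; cell winding is normalized counterclockwise on
load, and validation checks closure, simplicity, positive area and the
1-or-2-cells-per-edge invariant.  Two CSV dialects are supported: VEC
(three tables) and FLAT (one row of x,y pairs per cell, edges
reconstructed with shared walls deduplicated by vertex coincidence
within 1e−9 of the bounding-box diagonal).  Indices are 0-based in
memory and 1-based on disk.

Templates: centered hexagonal arrays (`hex_template`), rectangular
hexagonal slabs, and Voronoi tessellations of uniform random centers
clipped to circular, semicircular, parabolic or user-polygon regions.
Voronoi templates accept Lloyd (centroidal) relaxation rounds and a
minimum-wall-length collapse tolerance: raw random tessellations contain
sliver cells and very short walls whose spring dynamics are needlessly
stiff (a wall of length ℓ → 0 under load makes the equations of motion
singular), and the growth fixtures use `lloyd=4, min_edge≈0.1`.
Curved region boundaries are discretized with `n_arc` segments; the
reported region area is that of the discretized polygon.

## Intercellular coupling

Fickian wall diffusion with permeability β adds
`(ℓ_k/A_i)·β·([X_j] − [X_i])` to cell *i* for each shared wall *k* —
in the amounts basis this operator is a graph Laplacian (symmetric,
non-positive spectrum, uniform null space), which the tests verify.
Boundary walls optionally exchange with a zero-concentration exterior at
a separate permeability `P_O`; omitting `P_O` closes the boundary.
Dirichlet conditions (a species held fixed in chosen cells, e.g. the
boundary layer) are expressed by per-cell fixed species rather than a
nonzero exterior.  Facilitated transport uses directed positive wall
fluxes `f_in`/`f_out`, and IGRN arrows give saturating action at a
distance between adjacent cells, additive over neighbors.  All wall
coefficients may be callables of (cell, neighbor, wall) with read-only
access to the current state, enabling concentration-dependent
permeability.

## Mechanics and growth

Each wall is a Hookean spring with rest length δ and constant k; each
cell pushes outward with pressure P.  Vertex motion is overdamped:

    dx_i/dt = Σ_edges k_r (x_j − x_i)(1 − δ_r/ℓ_r)
            + Σ_(wall, cell) ½ P_a ℓ_r n̂_{a,r},

with each wall's pressure force split evenly between its endpoints.
Extended springs pull inward; this sign convention is the one that
yields bounded sigmoidal growth.  Rest lengths grow irreversibly at
`dδ/dt = μ·max(ℓ−δ, 0)`, and concentrations are corrected for dilution
by `−[X]·(dA/dt)/A` with dA/dt evaluated analytically from the vertex
velocities (time derivative of the shoelace formula).

For a single square cell with uniform k, P, total rest length Δ and
μ = 0, summing the forces gives the exact perimeter law

    (1/L) dL/dt = P − 2k + 2kΔ/L,

so growth is sigmoidal with finite equilibrium L* = 2kΔ/(2k−P) exactly
when P < 2k.  This closed form is the oracle for the mechanics
integration tests (agreement to 1e−4 relative at k=1, P=1, Δ=4 → L*=8).

Pressure, spring constant and growth rate may be constants or callables
of the simulation state; `linear_feedback(base, coeff, species)` builds
the standard constituent feedback `P_i = p0 + p1·[S_i]` (and the
per-wall pair form `μ_r = μ0 + μ1([S_i]+[S_j])`, with boundary walls
using their single abutting cell).  `anti_collapse_pressure` adds a
compression back-pressure `κ·(A_floor/A − 1)_+` that is zero for
normally-sized cells and diverges as a cell's area approaches zero.
This regularization is needed for long growth runs: an edge-spring
tissue has no intrinsic resistance to a cell being flattened at constant
perimeter, and a strongly growing cell otherwise squeezes a
low-pressure neighbor to zero area in finite time, which is both
unphysical and numerically fatal.

## Cell division

Each cell draws its division threshold at birth from N(mean, sd),
truncated below at 1% of the mean (clamped draws are logged).  The
threshold variable is the cell area by default, or any species.

*Errera's rule* (modern interpretation): the shortest straight wall that
bisects the cell area.  Both endpoints are parameterized by perimeter
arc length; for each position of the first endpoint the equal-area
constraint determines the second by monotone root bracketing, the chord
length is scanned at 256 positions, every scan minimum is refined by
bounded scalar minimization, and ties within 1e−6 of the perimeter
(symmetric cells) are broken uniformly at random.  A brute-force
bisector scan at independent resolution serves as the oracle.

*Potential model*: minimize `V = w_A V_A + w_L V_L + w_e V_e + w_g V_g`
over the central angles (θ1, θ2) of the endpoints as seen from the cell
centroid (vertex mean), where V_A = ((A1−A2)/A)², V_L penalizes
deviation from the shortest chord through the center (plus an ε_L Δ²
off-center penalty), and V_e, V_g penalize alignment of the wall with
the axes of maximal extension and instantaneous growth — the principal
eigenvectors of the centered vertex-position and vertex-velocity
covariances.  Both wall orientations ±W are evaluated and the candidate
is scored at the orientation with non-negative alignment, making the
perpendicularity term effectively |v·Ŵ| + ε_⊥Δ/d; this is the reading
under which the term is minimal for walls perpendicular to the axis.
Degenerate axes (isotropic cells) drop their term with a warning.
Minimization is a 64×64 angular grid followed by Nelder–Mead refinement
of every grid basin; equal global minima are tie-broken at random.
Note that V_L targets the shortest *through-center* chord, so with
weights (w_A, w_L) the optimum is the area-bisecting wall closest to
that chord — it coincides with the Errera wall only when the Errera
chord passes near the center (agreement to ~5% on random convex cells).

Mesh surgery inserts the wall endpoints as new vertices (splitting the
boundary walls they land on, including in any neighbor cell that shares
them; endpoints within 1e−7 of the perimeter of an existing vertex snap
to it), adds the straight wall edge, and replaces the mother with two
daughters.  Daughters inherit concentrations unchanged (amounts are
proportional to area), split walls partition their rest length
proportionally, the new wall starts at rest, and each daughter draws a
fresh threshold.  Walls that would create a zero-area daughter abort
the division.

## Engine

`compile(model, tissue, mode)` replicates every reaction into every
cell (vectorized across cells), expands intercellular arrows over the
wall topology, and in growing mode appends the vertex positions and
rest lengths to the state with dilution corrections.  Fixed species are
excluded from the state vector but visible to every rate expression.
Concentrations are clipped at zero inside rate evaluations, with a
warning if the integrator undershoots below −1e−9.

Static runs use LSODA (automatic switching between a non-stiff Adams
method and a stiff BDF method) at rtol 1e−6 / atol 1e−9.  Growing runs
default to the stiff BDF method with a conservatively constructed
sparse Jacobian pattern (chemistry couples species within a cell and
across vertex-sharing cells; mechanics couples each vertex to its
extended neighborhood, incident rest lengths, and the concentrations of
incident cells): growing systems carry hundreds of mechanical state
variables and dense finite-difference Jacobians dominate runtime
otherwise.  The sparsity construction assumes growth-law locality (laws
read the abutting cells only), which holds for all laws the package
ships.

Division events are located by the integrator's root finding on
max_i(variable_i − threshold_i).  At an event, over-threshold cells are
divided one at a time in ascending cell-index order, recompiling
between divisions so geometry, velocities and indicators stay
consistent; a daughter born above its own threshold divides again in
the same stop.  One RNG stream seeded by the run seed supplies all
threshold draws and tie-breaks in event order, so runs are bit
reproducible.  An event storm (more than a configurable number of
divisions per unit time) aborts with a diagnostic.

## Demonstration models and their frozen conditions

Values the underlying network descriptions leave open are package
choices, fixed once and listed here.

**Brusselator** (`brusselator_model`): `0 <-> A (a, β)`,
`2A + B -> 3A (c)`, `A -> B (b)`, with A and B diffusing.  Defaults
a = β = c = 0.1 and b = 0.9, the classic oscillatory value (trace of
the well-mixed Jacobian is b − 0.2, so b > 0.2 oscillates).  The
pattern demonstrations run on a fixed 199-center Voronoi circle
template (radius 7, seed 7).  With D_A = D_B on a closed tissue and a
uniform start, all cells remain identical to round-off while
oscillating; with D_A = 0 and D_B ∈ {0.1, 0.5, 1} the system freezes
into stationary heterogeneous patterns whose strict-maxima count
decreases with D_B (measured 19/4/3 at init seed 1; the counts are
template- and noise-dependent, their non-constancy in D_B is the
robust claim).  Initial conditions perturb the homogeneous fixed point
[A]* = a/β, [B]* = b/(c[A]*) by ±5% uniform noise.

**Stem-cell niche** (`wus_model`): the Brusselator supplies a
patterning activator A; a signal Y is held fixed in the boundary
(epidermal) cells and diffuses inward while decaying, forming an
inward-decreasing ring; Y degrades A (`A + Y -> Y`) and strongly
represses the organizer marker W, which A weakly activates through a
sigma-controlled GRN.  Printed interaction parameters: v = 0.1,
T_WY = −25, T_WA = 0.5, h = 0, k_w = k_y = 0.1, d = 0.5, D_Y = 2,
D_A = 1.5, D_B = 15.  Package choices: b = 0.19, inside the Turing
window 0.174 < b < 0.2 that linearization gives for these diffusivities
on a closed tissue; fixed boundary level Y = 0.1; fixture = semicircular
Voronoi section (radius 10, 160 cells, seed 11); ablation removes the
cells within radius 2 of the section center.  The tissue boundary is
impermeable by default (`open_boundary=False`): with a zero-concentration
exterior at P_O = D_B = 15 the inhibitor B drains and the drained
homogeneous state is linearly stable for every b, so no pattern — and
hence no organizing center — can form.  Wild type yields one connected
high-W domain; the ablated section yields two lateral domains; both
counts use the range-midpoint threshold described below.

**Organizer-maintained growth** (`organizer_growth_model` +
`run_organizer_demo`): U is produced in a graded apex band (cytokinin-
like), V in the epidermal L1 layer (CLAVATA-like); both diffuse with an
impermeable epidermis.  W is activated by U, repressed by V,
self-activating, and degraded in proportion to the mediator Z (produced
at k7, removed at k8·U·Z, hence high wherever U is low) plus an extra
L2 term; X carries W's positive feedback onto V.  W drives the
mechanics: P_i = p0 + p1 W_i and μ_r = μ0 + μ1(W_i + W_j), with
Errera division on an area threshold.  Printed parameters as in the
network description (k1 = 2, k2 = 0.2, k3 = 1, k4 = 0.25, k5 = 1,
k6 = 0.05, k8 = 1.5, k9 = 0.1, D_U = 10, D_V = D_X = 0.5, all v = 1,
all h = 0, T_WX = T_WV = 4, T_UW = 22.5, T_VW = −25, T_WW = 27.5,
p0 = 0.001, p1 = 0.004, μ0 = 5e−6, μ1 = 0.004).  Package choices:

* k7 = 7.0 (not printed).  The W ON-state condition is proportional to
  U: below k7 ≈ 6.5 the ON state is stable everywhere U reaches and
  weak straggler W pockets persist behind the advancing apex; above
  k7 ≈ 7.5 the niche cannot ignite at all.  The operating window is
  narrow because the printed GRN weights make W's bistability margin
  ~±10% in U.
* spring k = 1.0; division threshold ~ N(1.8·A0, 0.09·A0) with A0 the
  mean initial cell area; TIP band = top 20% of the bounding box, as a
  graded logistic profile (a sharp band changes by a whole cell's
  weight when an apex cell divides, which can kill the marginal niche).
* fixture = Lloyd-relaxed semicircular dome, radius 9, 80 cells
  (several U screening lengths √(D_U/k2) deep — a shallower dome cannot
  confine W); W seeded at 8.0 in the cells within 1.8 of (0, 7.2),
  reflecting that the experiment starts from an existing organizer
  distribution and that the W subsystem is bistable per cell;
  anti-collapse pressure κ = 0.05, A_floor = 0.5 (see Mechanics).

With these conditions the high-W domain remains a single connected
component through 100 divisions (the packaged, desk-scale version of
the long-run maintenance claim; `scripts/organizer_long_run.py` runs
the 500-division version), reproducibly across run seeds.

## Pattern summaries

A strict local maximum is a cell whose value exceeds all wall-sharing
neighbors'.  A high-expression domain is a connected component of
{value ≥ threshold} in the cell-adjacency graph; the default threshold
sits a configurable fraction (0.5 by default) of the way from the field
minimum to its maximum, so it remains meaningful for fields with a
nonzero baseline.  Organizer W fields are bimodal (OFF ≈ 0 against a
graded ON plateau), and their domain counts use the 0.25 fraction,
which falls in the gap between the modes.

## What the synthetic fixtures do and do not show

All inputs are generated: hexagonal and Voronoi templates stand in for
segmented tissue geometry, and initial conditions are uniform states
with seeded noise or explicit seeds.  Passing tests show that the
compiler, the coupling operators, the mechanics and the division
machinery implement their equations correctly (against symbolic, closed
form and brute-force oracles), and that the three demonstration
networks reproduce their qualitative claims on the packaged fixtures.
They do not show that any parameter set is calibrated to real meristem
measurements, that the pattern counts would survive on a real
segmented-tissue geometry (maxima counts are template-dependent), or
that the vertex-spring mechanics quantitatively matches plant cell-wall
rheology.

## Known limitations

* No wall compartments as reaction-bearing spaces; no stochastic
  kinetics; no cell death or removal; no curved division walls; no 3D.
* The edge-spring mechanics admits mesh folding under extreme force
  imbalance; the anti-collapse pressure mitigates the common
  area-collapse mode but shear folding is not detected or repaired
  (no T1 transitions).
* Voronoi boundary discretization (`n_arc`) trades geometric fidelity
  of curved templates against mechanical state size; growth fixtures
  use a coarse boundary.
* The organizer demonstration operates in a narrow k7 window, a
  property of the printed GRN weights rather than of this
  implementation.
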