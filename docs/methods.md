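# Methods

This note documents the models implemented in `biodyn`, their
assumptions, the parameters that matter, and the numerical and design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Engine semantics

The engine is strictly sequential and deterministic: a run is a pure
function of (configuration, seed). One iteration executes, in order:

1. rebuild of the spatial index from the committed population;
2. every *due* per-agent operation, op-major — an operation is applied to
   all live agents in ascending id order before the next operation
   starts (operations are due at iterations 0, f, 2f, … for frequency f);
3. every due standalone operation (diffusion updates, collectors, the
   mechanics sweep);
4. commit of the execution context: queued agent additions and removals
   become effective, and positions are wrapped (toroidal) or clamped
   (open) to the domain.

Agents queued at iteration `i` are therefore invisible to every
neighborhood query and operation at `i` and visible from `i + 1`; ids
are never reused. Removing an unknown id warns instead of raising,
because two behaviors may legitimately remove the same agent within one
iteration. A single `numpy.random.Generator` is shared per simulation;
the deterministic execution order fixes the draw order. The engine is
single-threaded by design — determinism and testability at desk scale
were preferred over thread-level parallelism; repetition across seeds is
the only axis of parallelism the package exposes (consecutive seeds via
the scenario runner).

Op-major ordering (all agents per operation) rather than agent-major
(all operations per agent) was chosen for the per-agent sweep; the two
orderings produce different stochastic trajectories, and op-major
matches the engine's operation-centric scheduling.

## Neighbor search

Space is divided into equal cubic boxes; each agent is indexed by the
box containing its center (half-open boxes `[lo, hi)`, so boundary
positions are unambiguous). If no box size is given it defaults to the
largest agent diameter, which makes a contact query (radius = box edge)
provably complete over the 27-box stencil; queries with radius larger
than the box edge raise rather than silently missing neighbors.
Neighbors at distance exactly equal to the radius are included (the
choice only matters on measure-zero configurations). In toroidal mode
the per-axis box count is `floor(L / box_length)` so boxes tile the
period exactly (the effective edge can therefore be slightly larger than
requested), indices wrap, and distances use the minimum image
`min(|d|, L − |d|)` per axis. A brute-force O(n²) oracle and a
`scipy.spatial.cKDTree` backend (periodic in toroidal mode) provide
independent routes against which the grid is fuzz-tested.

## Extracellular fields

Guidance cues for neurite growth are *static* Gaussian profiles along
one axis, `c(p) = A exp(−(p_ax − μ)² / 2σ²)`, with analytic gradients;
they never change during a run, so they carry no stability constraint.
Dynamic substances use an explicit FTCS lattice:
`c' = c + dt (D ∇²c − λ c)` with the 7-point Laplacian, zero-flux
boundaries (ghost cells mirror the edge) and voxel values at voxel
centers. Stability requires `D dt/Δx² ≤ 1/6`; the step raises with the
admissible `dt` otherwise. Note that *at* the stability limit the update
assigns zero weight to the center cell, so a single-voxel source excites
a checkerboard parity mode; smooth fields are unaffected, but
point-source studies should use half the limit (the test suite does).
With zero decay the scheme conserves total mass `Σc·Δx³` to round-off.
Point deposits add `amount/Δx³` to the single containing voxel; point
queries interpolate trilinearly and gradients are central differences of
the interpolated field with step `Δx`; out-of-domain queries clamp to
the boundary value and log once.

## Mechanics

Cells are soft spheres with overlap `δ = (r_a + r_b) − |p_a − p_b|` and
a linear-spring contact force `k δ` along the line of centers (optional
linear adhesion for small gaps, off by default). The concrete force law
is deliberately isolated behind `pairwise_force` so a different contact
model can be substituted without touching the sweep. Motion is
overdamped — displacement `F/ζ·dt`, computed for all agents from the
pre-step configuration and applied synchronously — and clamped to a
maximum per-step displacement so arbitrarily stiff contacts remain
stable. Coincident centers receive a deterministic, id-seeded random
separation direction. Defaults (`k = 2`, `ζ = 1–2`, clamp 3 μm) are
qualitative-regime choices: two fully overlapping 10 μm cells separate
within a few dozen iterations at `dt = 1`. Cylinder–cylinder and
sphere–cylinder contact are out of scope; the neurite scenario runs
guidance-only, with mechanics disabled.

## Spatial SIR epidemic

Person agents are points in a toroidal box of side `L = 100` (length
units are arbitrary; only the ratio of infection radius and step length
to `L` matters). Per step (1 step = 1 day): every person takes a random
step (uniform direction, length uniform on `[0, max_step]`); every
susceptible with at least one *start-of-step* infected person within the
infection radius is infected with probability `p_infection` — one
Bernoulli draw per susceptible per step regardless of the number of
infected neighbors (this choice changes the mapping to β and is
therefore explicit); every person infected before this step recovers
with probability `p_recovery = γ·dt`. Updates are synchronous within a
step.

The comparator integrates the SIR ODE with fixed-step classic RK4
(`dt = 0.05 d`; halving changes nothing at the reported precision), with
`β = R0 γ`, `γ = 1/T_R`. Presets: measles R0 = 12.9, T_R = 8 d,
N = 2010, I0 = 10; influenza R0 = 1.3, T_R = 4.1 d, N = 2020, I0 = 20.
The N values are scaled-down scenario sizes, and the S/I split is a
scenario default, not a literature value. The total attack fraction is
validated against the final-size relation `z = 1 − exp(−R0 z)`, solved
by bisection to 1e−12.

Two execution paths implement the same per-step semantics: the
engine-integrated path (per-agent operations; used for the lifecycle and
conservation contracts) and a vectorized path (numpy state arrays, one
periodic kd-tree nearest-infected query per step; used for calibration
and multi-seed validation). They cannot be bit-identical — their RNG
draw orders differ — and are instead cross-checked statistically.

**Calibration.** The free spatial parameters (infection radius,
infection probability, maximum step) are fitted with global-best PSO
(30 particles, 100 iterations, constriction coefficients w = 0.7298,
c1 = c2 = 1.49618). The objective is the time-summed squared difference
between ABM and ODE S, I, R curves over 100 days, normalized by N,
averaged over 2 ABM seeds per evaluation — two seeds keep the ~3000
objective evaluations affordable while damping seed noise; the post-fit
validation always uses a fresh 10-seed mean. For influenza no separate
swarm run is needed: at R0 = 1.3 the peak prevalence is ~3% of N, so
the dilute-limit mapping `p_infection · N · v_r / L³ = β·dt` (with `v_r`
the infection-sphere volume) is accurate, and short-horizon refitting
was observed to bias the effective R0 upward; the influenza scenario
therefore uses the analytic mapping with `max_step = 0.8 L`
(near-complete daily re-mixing, so the well-mixed assumption behind the
mapping actually holds — smaller steps leave spatial correlations that
depress the effective R0 and hence the attack fraction).

Known limitation: with one Bernoulli per day the per-susceptible daily
infection hazard saturates at 1, and a day is not infinitesimal for
measles-fast dynamics, so the calibrated ABM tracks the ODE to a few
percent of N rather than exactly; the residual is reported, not hidden.

## Tumor spheroid

Cells grow linearly in volume (`dV = r·dt`) and divide on reaching a
threshold diameter; the division volume split is `u ~ Uniform(0.45,
0.55)` (asymmetric division, exactly volume-conserving), the daughter is
placed one mother radius away in a uniform random direction, and the
mechanical sweep resolves the resulting overlap. Migration is Brownian
(independent Gaussian increments of variance `σ²dt` per coordinate);
apoptosis removes a cell with a fixed per-step probability via the
deferred queue. Initial populations are seeded uniformly in a ball sized
for a 30% packing fraction. The readout is the equivalent-sphere
diameter of the convex hull of all cell centers, `d = (6V_hull/π)^{1/3}`
(the only dimensionally natural scalar from a hull volume), sampled
daily with time in hours. All rate defaults (growth 30 μm³/h, division
at 14 μm, σ = 0.5 μm/√h) are qualitative-regime choices for an
MCF-7-like spheroid; no quantitative reproduction of published growth
curves is claimed. Nutrient limitation and a necrotic core are not
modeled.

## Pyramidal-cell dendritic growth

A cell starts as a 10 μm soma with one apical stub along +z and three
basal stubs in the −z hemisphere, each 0.5 μm long, attached at the soma
center (the attachment point is a convention; placing it at the center
makes SWC round-trips exact). Two static Gaussian cues along z (one
above for the apical tree, one below for the basal trees) provide
gradients. Each active terminal elongates by `speed·dt` per step along
`normalize(w_g ĝ + w_p p̂ + w_r û)` where ĝ is the normalized local cue
gradient, p̂ the element's current direction and û a uniform random unit
vector — each component is normalized before weighting, so the weights
compare like with like. Growing paths are chopped into stored segments
of at most 1 μm: when a tip fills its segment, a continuation element is
queued (deferred, like any agent creation) and the growth behavior
transfers to it via the copy/remove flags, so total tree length grows by
exactly `speed·dt` per active tip per step regardless of discretization.
Diameter shrinks by `taper` per μm grown; at the minimum diameter the
element stops growing permanently. Terminals bifurcate with probability
`p_branch` per step into two daughters with diameter scaled by
`branch_diameter_ratio`, directions at ±half the branch angle (default
30°) around the parent direction in a random plane.

Default regime: apical `speed 1.0, w_g 0.9, w_p 0.6, w_r 0.15,
taper 0.006/μm, p_branch 0.04`; basal `speed 0.6, w_g 0.3, w_p 0.5,
w_r 0.6, taper 0.010/μm, p_branch 0.05`; both with
`branch_diameter_ratio 0.8`. Branching is thus *diameter-limited*: the
ratio and taper bound the number of branch generations, and with a
branch probability high enough to saturate that bound, each tree
reliably produces a realistic double-digit branch-point count with low
cell-to-cell variance — inter-branch segments average tens of μm, as in
real pyramidal dendrites. This stabilizes population morphometrics
(batch means reproducible within a few percent at 20 cells per batch)
without constraining any individual morphology.

Morphometrics per dendritic tree: branch points (elements with exactly
two daughters) and total length (sum of segment lengths), with cell- and
population-level averages; tree integrity (acyclic, connected, daughter
proximal = parent distal) is validated before measuring. SWC export
writes `(index, type, x, y, z, radius, parent)` rows with type 1 = soma,
3 = basal, 4 = apical, coordinates to 1e−6; export→import→export is
byte-identical and preserves morphometrics. The statistical comparison
of simulated populations uses the same two metrics a comparison against
reconstructed morphology databases would use, but is validated only
against self-generated populations; external databases are optional
input, not a test dependency.

## Synthetic data and what passing tests show

All inputs are generated programmatically: agent populations from the
seeded generator, epidemics from the preset disease parameters,
morphologies from the growth model itself. Passing tests therefore
demonstrate internal consistency (conservation laws, oracle equivalence,
analytic limits, reproducibility) and agreement with the mean-field and
geometric theory (SIR ODE, final-size relation, heat kernel, Brownian
MSD) — not agreement with any particular laboratory dataset. Features of
real data the generators do not emulate include contact-network
structure and demographics (epidemic), nutrient gradients and necrosis
(spheroid), and axonal growth or neurite-neurite interactions
(dendrites).

## Problem sizes and tolerances

The shipped validation runs use N = 2010/2020 epidemics over 100–1000
days, 10-seed validation means, 30×100 PSO swarms, ~10³ randomized
neighbor-search configurations with n up to 2000, 10⁴-walker MSD
checks, 64³ diffusion lattices and 20-cell morphometric batches — sizes
chosen so the full validation completes in minutes on one core while
keeping Monte-Carlo error well inside each tolerance. Exact contracts
(conservation, antisymmetry, round-trips) are asserted at 1e−12
relative; mean-field agreements at 2–5%; Monte-Carlo means at 3–4
standard errors of the estimator.
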