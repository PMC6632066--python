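# Methods

`blendsim` models the scale-up of a pharmaceutical powder-blending step
with two coupled layers: a quality-by-design (QbD) statistical layer
(risk scoring, response-surface modelling, Monte-Carlo robustness) and a
mechanistic layer (a soft-sphere discrete-element simulator with virtual
bulk tests and blending-homogeneity metrics). This note records the
models, the estimators, the numerical choices and what the desk-scale
fixtures do and do not demonstrate.

## Risk scoring

Failure mode and effects analysis assigns each (process parameter,
quality attribute) pair severity S, occurrence P and detectability D
scores from {1, 3, 5, 7, 9} and ranks the risk priority number
RPN = S·P·D (1–729). Levels are low (RPN < 82), medium (82–245) and
high (≥ 246); the boundary values 82 and 245 are classified medium and
246 high, reading the verbatim range statements inclusively. The Pareto
threshold is `max_rpn·(1 − confidence)`, 72.9 at the default 90%
confidence. Ties in the Pareto ranking keep input order (stable sort).

## Response-surface layer

Three blending factors — filling level (30–70 %), rotational speed
(15–25 rpm) and blending time (9–24 min) — are coded as
`(natural − center)/half-width` with centers (50, 20, 16.5) and
half-widths (20, 5, 7.5) inferred from the design levels. The design is
the canonical three-factor Box–Behnken set: twelve edge midpoints plus
replicated centre runs (three by default). Responses are fitted by
ordinary least squares on caller-specified terms drawn from main
effects, two-factor interactions and pure quadratics.

ANOVA reports per-term type-III sums of squares (equal to sequential on
this orthogonal design), the model F against the residual mean square,
and three goodness-of-fit statistics: R², adjusted R², and predicted R²
computed as `1 − PRESS/SS_total` with PRESS from leave-one-out leverages
— the standard formula used by commercial DoE software, stated here
because only the name of the quantity is conventional. Backward
elimination at p > 0.05 is available; for the content-uniformity
response it drops the rotational-speed main effect, and the reduced
four-term model is the one whose goodness-of-fit triple matches the
published ANOVA, while the five-term model carries the published
coefficients and optimal-point predictions. Both are exposed; the
package reproduces both sets of numbers.

The design space evaluates every fitted response on a factor grid and
keeps cells where all point predictions meet specification (drug
content 95–105 %, CU ≤ 5 %); a strict mode uses the 95 % confidence
bound on the unfavourable side instead. Grid optimisation ranks
feasible cells by mean linear desirability with ties broken toward
lower filling level and higher speed.

## Monte-Carlo operating space

Each candidate setpoint is perturbed `draws` times (default 10,000)
with factor settings drawn Normal(setpoint, SD) truncated to the factor
ranges; by default the SD is 5 % of each factor's half-range and
response residual noise (SD equal to each fit's residual SD) is added,
since pure setpoint noise cannot fail a strictly interior point. A cell
belongs to the operating space when its simulated failure probability
is below 1 %. The binomial standard error is reported so reduced-draw
runs are honest about their resolution. With zero SDs and residual
noise off, the map reduces exactly to the deterministic design space —
a property the tests exploit. Neither the perturbation magnitudes nor
whether model-parameter uncertainty should be propagated is fixed by
convention; both are configuration, not fact.

## Discrete-element core

Particles are single spheres (sizes drawn from the material's
D10/D50/D90 with probabilities 0.25/0.5/0.25 — a three-point quadrature
of the size distribution) with Hertz–Mindlin (no-slip) contacts:

- normal force `F_n = (4/3)·E*·√R*·δ^{3/2}` with
  `1/E* = (1−ν_a²)/E_a + (1−ν_b²)/E_b`, `1/R* = 1/R_a + 1/R_b`,
  and `E = 2G(1+ν)` from the tabulated shear modulus;
- tangential spring `F_t = −S_t·δ_t` with `S_t = 8G*√(R*δ)`, capped by
  the Coulomb limit `μ_s|F_n|`, the spring rescaled onto the friction
  cone when sliding;
- normal and tangential damping `−2√(5/6)·β·√(S·m*)·v_rel` with
  `β = −ln e/√(ln²e + π²)` tied to the restitution coefficient —
  two-body impacts recover the configured `e` to better than 2 % at a
  time step of 10 % of the Rayleigh time;
- rolling resistance as the constant directional torque
  `−μ_r·|F_n|·R_p·ω̂`, applied per particle;
- optional JKR cohesion for the lubricant:
  `F = −4√(πγE*)·a^{3/2} + (4E*/3R*)·a³` in the contact radius `a`,
  inverted from the overlap `δ = a²/R* − √(4πγa/E*)` by Newton
  iteration on the stable branch. Tensile contact persists to the
  displacement-control fold; the pull-off force is `3πγR*`. With γ = 0
  the JKR and Hertz paths produce identical trajectories.

Integration is semi-implicit (symplectic) Euler — velocities first,
positions second — with a kick-drift-kick velocity-Verlet variant
behind a flag. The stable step is a configurable fraction of the
Rayleigh time `πR√(ρ/G)/(0.1631ν + 0.8766)`: 30 % for bulk-test
calibration runs, 25 % for blending runs. Gravity is 9.81 m/s².

Broad-phase collision detection uses a uniform cell grid (cell = cutoff)
producing exactly the pairs within the cutoff; the candidate list is
kept as a Verlet list with a skin that widens adaptively with the peak
particle speed so free-falling scenes do not force rebuilds every step.
Wall contact transforms particles into each mesh's body frame (meshes
carry prescribed rotation + translation), culls candidate triangles by
a centroid KD-tree plus a bounding-radius test, computes exact
closest-point distances (face/edge/vertex cases), and deduplicates
contacts per smooth surface patch (faces grouped by rounded normal) so
a particle resting across coplanar triangles feels one contact while a
wedge yields two. Wall meshes are built by ring-based lathing and swept
tubes with bounded triangle edge lengths; fan-triangulated caps are
avoided deliberately because sliver triangles explode the candidate
lists. All force loops have a pure-numpy implementation and an
equivalent numba-compiled scalar kernel (the default when numba is
importable); a test asserts the two paths agree to machine precision.

Two numerical guards go beyond the printed force laws, both standard
DEM practice for under-resolved events: the damping impulse in one step
is clamped to the momentum of the relative motion it opposes
(explicitly integrated stiff damping otherwise injects energy at fast
impacts), and the rolling torque per step is clamped so it cannot
reverse a particle's spin.

The implementation follows the canonical Hertz–Mindlin formulation as
written above: normal-force exponent 3/2 with the root on R*, and
damping prefactor 2√(5/6); transcriptions of these expressions
elsewhere sometimes garble the exponent and prefactor, so the forms
used here are stated explicitly.

## Virtual bulk tests

**Static angle of repose.** Particles seeded inside a conical funnel
(orifice 10 particle radii, sitting 11 radii above a rimmed dish) drain
under gravity; the rim recaptures rare ballistic splash ejecta, which
are set down at rest beside the rim, outside the measured region. After
the assembly is at rest (mean kinetic energy per particle below 1e-8 J
held for 0.2 s), the heap angle is estimated by fitting a cone through
the pile's first moments: for an ideal cone tan θ = 2·z̄/r̄. A
surface-profile regression was evaluated first and found noise-dominated
at desk particle counts (a few hundred), with seed-to-seed spread of
several degrees; the moment fit is stable to about one degree and
responds monotonically to rolling friction over its sensitive range,
saturating above μ_r ≈ 0.25. Angles below 2° are flagged as frictionless
collapse.

**Dynamic angle of repose.** A drum sized to put the particle charge at
30 % v/v rotates at 25 rpm; after settling and a spin-up phase, the
free-surface angle is a line fit to the per-bin top surface of the
axial-mean cross-section, averaged over five snapshots and reported
with its SD; a surface-fit R² below 0.8 flags a cataracting regime.

**Basic flow energy.** An FT4-style rig (vessel and two-bladed impeller
scaled so the vessel spans ~28 particle radii; helix −5°) runs a
conditioning traverse followed by a counterclockwise downward test
traverse. Blade torque and axial force are accumulated from
particle–blade contacts each step and integrated as
`E = ∫ (T/(R·tan α) + F) dh` by the trapezoid rule over penetration
depth. Blade speeds are 10× the laboratory schedule (desk default,
configurable): the traverse is quasi-static relative to particle
inertia well beyond this factor, and real-speed traverses would
dominate the runtime for no change in the measured resistance ordering.

**Calibration.** Coordinate descent over (μ_s, μ_r) — shear modulus,
Poisson ratio and restitution held fixed — re-simulates the requested
bulk tests with a common seed, accepting moves that reduce the worst
relative bias, halving the step when no direction improves, and
converging when every response is within the tolerance (10 % relative
by default). The full iteration log is returned; the audit trail of
accepted iterations is non-increasing in worst bias by construction.
Experimental flow-energy magnitudes from the source tables are treated
as qualitative orderings, not bit targets, because the fill masses
behind them are unpublished.

## Blending pipeline

Blender geometry is parametric: the V-blender is a mitred swept tube
(two cylindrical arms at 80°, arm length 3.4 radii) and the double-cone
a lathed profile; both are scaled to hit the nominal internal volume
within 5 % (checked against the watertight mesh volume) and rotate
about the horizontal axis through the centroid. Any geometry can be
replaced by an STL mesh.

Filling draws per-component particles until each component's mass
target is met (components sized so realized mass fractions track the
recipe to well under 1 %), places them on a jittered lattice inside the
mesh from the bottom up — layered in recipe order by default, randomly
interleaved for the pre-mixed control — and settles them under gravity.
The bed volume targets `fill_fraction × nominal volume` through an
assumed packing fraction of 0.58 and is audited afterwards by an
occupied-voxel estimate.

Homogeneity is sampled in eight vertical cylinders in a 4×2 grid over
the quantile bounding box of the bed, at instants when the blender is
in its rest orientation (full revolutions) so the bed is one contiguous
body. Per-bin drug content is the bin's API mass fraction over the
nominal 6.935 %, ×100; content uniformity is the percentage relative
standard deviation across bins (empty bins are excluded, minimum
four). The T-index is the ordinal sampling time; the first index with
mean content in 95–105 % and CU ≤ 5 % is reported as the required
blending time. Simulated and experimental series are compared by
ordinary least squares (slope, intercept, residual SD, R², adjusted R²,
slope p-value), optionally dropping initial high-variability points.

## Desk-scale fixtures: what they show

Full-scale runs (hundreds of thousands of particles for multiple
simulated minutes) are out of desk reach, so every simulation fixture
is deliberately miniaturised, with three coarse-graining choices:

- particle sizes are mapped to comparable millimetre radii per
  component (the lubricant kept finest) instead of the 100× upscale of
  the measured micrometre sizes;
- the shear modulus is reduced (1e5 Pa for bulk-test fixtures, 4e4 Pa
  for blending scenes) to enlarge the stable time step, keeping
  contact deformation near or below ~15 % of a radius at bed bottoms;
- the blending demonstration uses ~2,000–2,500 particles for a few
  revolutions.

Friction- and gravity-dominated bulk behaviour (repose angles, mixing
kinetics in revolutions) is insensitive to stiffness over a wide range,
which is why these reductions are standard in the field. Two limits
matter for interpretation. First, with ~2,000 particles and a 6.9 %
API the binomial sampling floor of content uniformity is ~20 %, far
above the 5 % production specification: the demonstration shows CU
falling from the segregated start to that floor, not specification
compliance, and the specs-met T-index may honestly be "not reached".
Second, desk repose angles are properties of the miniature rig and
coarse-grained material, useful as a monotone, deterministic response
for calibration (parameter recovery is verified by matching responses
within the 10 % tolerance), not as predictions of laboratory angles.

## Degenerate inputs and tie-breaks

Coincident particles are reported as one candidate pair and repelled
along an arbitrary fixed direction with a clamped distance;
zero-area wall triangles are dropped with a warning; empty sampling
bins are excluded (error below four); rank-deficient model matrices
raise an error naming the aliased terms; undefined statistics (zero
residual DF, zero-mean contents) are reported as not-available rather
than raising.
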