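# Methods

This note documents the models inside `imasim`, the parameters that matter,
the choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## Units and frames

All quantities are SI (metres, kilograms, seconds, newtons, radians) in one
right-handed world frame with Z up. Vertex indices are 0-based in memory;
OBJ's 1-based indices are converted only at the I/O boundary.

## Position-based dynamics

Each tissue is a particle system (positions, velocities, inverse masses,
rest positions). A step is: explicit prediction
`x* = x + vΔt + ½a_ext Δt²`; `iterations` Gauss–Seidel sweeps projecting all
distance constraints, then all dihedral constraints, in insertion order;
velocity recovery `v = (x_new − x_old)/Δt`; damping. Fixed particles
(inverse mass 0) are bit-for-bit stationary and end every step with zero
velocity. A NaN appearing after any stage raises an error naming the stage.

**Defaults.** Δt = 5 ms with 5 iterations; gravity (0, 0, −9.81) m/s² for the
fascia, zero for the vessel (in-situ thoracic conditions are modelled
gravity-free — implemented as the same predictor with `a_ext = 0`, not a
separate code path). Stiffnesses: fascia stretch 1.0 / bend 0.5; vessel
stretch 1.0 / bend 0.2.

**Stiffness semantics.** A constraint stiffness k ∈ [0, 1] is applied per
iteration as k′ = 1 − (1 − k)^(1/n_iter), the classic PBD correction that
makes the total per-step correction approximately independent of the
iteration count. Consequence: raising the iteration count does not tighten a
*single* soft constraint (that is by design); it does tighten coupled
constraint networks, where Gauss–Seidel needs sweeps to propagate.

**Dihedral convention.** For wings p0, p1 over the shared edge p2→p3, with
N1 = (p2−p0)×(p3−p0) and N2 = (p3−p1)×(p2−p1),
θ = atan2((n̂1×n̂2)·ê, n̂1·n̂2) ∈ [−π, π]. A coplanar quad with same-facing
normals has θ = 0; folding the p0 wing by +φ about ê *decreases* θ by φ.
The analytic gradients are the discrete-shells hinge gradients; they sum to
zero, so dihedral projections conserve linear momentum for equal masses. The
constraint value is wrapped into (−π, π] before projection so the correction
always takes the short way around.

**Damping.** The drag force F = −k_l v (k_l = 0.03 kg/s) is integrated
explicitly per particle with its own mass: v ← v(1 − Δt·k_l/m). The angular
term T = −k_a ω (k_a = 0.01 kg·m²/s) acts on the object's rigid-rotation
mode: ω is extracted from the free particles' angular momentum about their
centre of mass, and the rotational velocity component is decayed by
exp(−Δt·k_a/I_ω), with I_ω the effective inertia about the current rotation
axis. The exponential form is exact for that mode and unconditionally stable
— soft-tissue meshes have inertias of order 10⁻⁵ kg·m², for which an
explicit Euler torque update (Δt·k_a/I ≈ 1.6 per step) would inject energy.
Per-particle spin is not modelled; the damping coefficients are given as
force/torque coefficients, and the conversion to a velocity update uses the
particle (or modal) mass since no other convention is stated.

## Anatomy construction

**Fascia.** A regular nx×ny grid over [0, w]×[0, h], each cell split along
the (i, j)→(i+1, j+1) diagonal. Distance constraints sit on every unique
edge, dihedral constraints on every interior edge; rest values are measured
on the rest pose, so the initial state is exactly on the constraint
manifold. Perimeter vertices are pinned; the total mass (default 0.05 kg) is
spread uniformly, m_v = M/N_v.

**Vessel.** Two tube meshes share one centerline: a coarse simulation tube
(default 6 circumferential segments) and a fine display tube (default 12–16).
Ring frames are parallel-transported along the centerline. Each display
vertex stores its nearest simulation face and the barycentric weights of its
projection; display deformation is the barycentric interpolation of
simulation-vertex *displacements* added to the display rest pose, so rigid
motions pass through exactly and high-resolution detail is preserved. A
centerline whose non-adjacent segments intersect is rejected.

**Strands.** A face of surface A is eligible when its centroid lies within
d_max of surface B (explicit, or automatically the distance between the two
surface centroids). The face-to-surface metric (centroid to nearest point)
is our choice; the proximity rule only speaks of "distance between surface
elements". From each eligible face, σ origin points are drawn uniformly in
barycentric coordinates (seeded generator; fully deterministic), each strand
leaves along the face normal tilted uniformly within the deviation cone
(default 15°), anchors where its ray first hits B — nearest-point projection
if the ray misses — and is subdivided into n equal segments (defaults σ = 2,
n = 3, matching the reference parameterization). Endpoint particles are
kinematic anchor proxies slaved to their host faces via barycentric
coordinates; interior particles are dynamic. Viscoelastic behaviour is
carried by the per-segment distance constraints plus solver damping; full
SPH neighbourhood forces are a rendering-fidelity feature for which no
kernel or coefficients are specified, and are out of scope.

## Bidirectional coupling

Offsets are displacements from the rest configuration (chosen for
idempotence — re-applying a transfer is harmless). Pairings between
vessel-side strand endpoints and their nearest rest-pose vessel vertices are
precomputed once; no spatial queries run during simulation. Transfer copies
the paired offset with its direction preserved and magnitude clamped at
λ_max (default 5 mm — no value is given in the source material; exposed in
configuration). The coupling state β is tied to instrument engagement
(grasping or contact): β = 1 transfers, β = 0 decays the held vessel offsets
by 0.8 per frame — read as a per-frame decay of the last coupled offset
(geometric, monotone, no oscillation), the reading consistent with "smooth
motion decay". The runner performs one pass per frame — solve vessel →
transfer → solve strands → transfer back — with the applied offset tracked
so only its increment is added each frame; no fixed-point iteration.

## Cutting

**Sheet cutting.** The cut geometry per call is the segment swept by the
tool tip. A local cut frame is built from the sweep direction u and the mean
normal n̄ of nearby faces; vertices are classified by the side plane
m = u×n̄. An edge is split when its endpoints straddle the side plane and
the crossing point lies within the sweep's axial extent and within ε of the
sheet (ε defaults to half the mean edge length). A crossing vertex is
duplicated into left/right copies only when every face around its edge is
fully traversed (two crossed edges); the crack-tip crossing stays single, so
a partial cut remains one connected component with an open seam — vertex
count grows by 2 per interior crossing plus 1 at the tip. Faces are
re-triangulated locally (1 crossed edge → 2 triangles; 2 crossed edges → 3);
current positions, velocities and rest positions of new vertices are
interpolated linearly along the split edge, and inverse masses averaged.
Constraints follow the topology: distance constraints track the edge set,
dihedral constraints track the interior-edge wing map, and all new rest
values are measured on the rest configuration — the solver residual on the
rest pose after any cut is < 1e-9, i.e. cutting injects no elastic energy.
The proximity test for cut-zone vertices uses unsigned distance; the sign of
a signed distance would add nothing to a `d < ε` test.

*Limitations.* Cuts in "general position" are assumed: a sweep passing
exactly through mesh vertices produces no strict edge crossings and is a
no-op (the frame-by-frame runner offsets its demo path off the grid lines).
Incremental frame-by-frame cutting leaves crack-tip bridges where a sweep
tip paused; full separation is demonstrated with a single sweep spanning the
sheet. Non-manifold input is rejected.

**Strand cutting.** The tool plane is n·(x − p) = 0 with the triad
n = R·ŷ, l = R·x̂, f = R·ẑ. A segment is marked when it crosses the plane at
a point with |l·(x−p)| < ω/2 **and** |f·(x−p)| < ω/2 — both width tests are
symmetric absolute-value bounds; the one-sided inequalities as printed would
mark half-space-crossing segments arbitrarily far from the tool, which
contradicts ω being a cutting width. Removal deletes the segment's distance
constraint and splits the strand's particle run. Particles left in no
surviving segment decay, d ← 0.96·d per step, and turn invisible below
6×10⁻⁴ m (a 1 mm particle disappears on step 13). Particles still shared
with surviving segments do not decay.

## Instrument

The pose chain is T_world = T_controller·T_local·T_initial. The jaw model is
a single half-angle θ ∈ [0, θ_max] (θ_max = 30°) with T_upper/lower =
R(±θ, α) about the hinge axis; a configuration-space factor written as two
signed jaw angles elsewhere in the source material is inconsistent with this
one-parameter closure and the single-angle model is used. θ integrates a
scripted rate (hardware buttons are replaced by trajectory-file columns) and
clamps; "closed" is the pure predicate θ < 2.86°, no hysteresis. Grasping
(closed jaws only) captures free particles within 2 mm of the tool origin,
zeroes their inverse masses, slaves them to the tool frame, and restores the
stored inverse masses bitwise on release.

## Electrocautery forces

F_n = clamp(k_d·d + c_d·v_n, 0, 5 N), F_t = clamp(μ·F_n + k_c·v_t, 0, 2 N),
F_th = k_t·P·e^{−α_t·d} while the cautery is active; the total is their sum
and the logged breakdown reproduces it exactly. v_n and v_t are scalar
projections (magnitudes) of the tool-tip velocity — the channels are scalar,
so vector velocities are reduced to their normal/tangential magnitudes. The
thermal depth is taken to be the same contact depth d as the mechanical
channel; the source distinguishes the names but gives one contact. No
numeric values exist for k_d, c_d, μ, k_c, k_t, α_t: the shipped per-layer
defaults (fascia softer and more frictional than vessel wall; fat softest)
are engine defaults, not literature values, and are all configurable.
Cutting vs. coagulation modes differ only through P and k_t. The 1 kHz
haptic / 60 Hz visual split is reproduced as bookkeeping: the force log is
evaluated on a 1 ms clock linearly interpolating the 60 Hz contact states;
no real-time guarantee is claimed.

## Cardiac motion

The heart is kinematic: an ellipsoid surface whose vertices move radially
about the motion centre as u(v, t) = A·w(t mod T)·r̂(v). The waveform w is
an asymmetric raised-cosine bump (sin² over the first third of the cycle —
systole — then quiescent), normalized to peak 1 with w(0) = 0; any periodic
normalized profile is acceptable and this one is configurable. Defaults:
T = 0.8 s (75 bpm), A = 1 cm. Transmission to the field is an explicit
modelling choice — the mechanical path from heart to fascia is not specified
anywhere — implemented as u_pt = A·w(t)·e^{−dist/L}·r̂ with decay length L
(default 3 cm), applied as a moving boundary to the kinematic (pinned)
vertices of nearby tissue. With A = 0 the module is inert and static and
dynamic scenarios are byte-identical except for this module's output.

## Trajectory metrics

SAI = (1/n)·Σ(dᵢ/R)·sᵢ with dᵢ ≥ 0 the perpendicular distance to the vessel
centerline measured after orthogonal projection onto the 2D analysis plane,
R = 2 mm, and sᵢ = +1 on the non-cardiac side, −1 on the cardiac side. A
sample exactly on the centerline counts +1 (documented tie rule: degenerate
samples never count against safety). dᵢ/R is not clamped — SAI can exceed 1;
all shipped reference values are below 1, so the choice is unexercised by
that data. The dispersion D applies the square root that its "standard
deviation" description implies; the formula as printed omits it.

**Bimodal sampler.** Tool positions sit at arc-length-uniform stations along
the centerline with lateral offsets from a two-component normal mixture at
±μ_off (defaults μ_off = R, σ_off = R/2) and weights (1 ± w̄)/2,
w̄ = SAI_target·R/μ_off, which makes the expected signed offset — and hence
the expected SAI, since d·s equals the signed offset — match the target.
Targets with |w̄| > 1 are rejected. The generating procedure beyond the words
"bimodal, weighted by the SAI value" is unspecified, so all parameters are
exposed and the sampler is documented as a reconstruction, not canon. For
fixture files that must reproduce a printed per-trial SAI to 0.001, a
constant lateral shift of (target − sample SAI)·R is applied after sampling;
the shift changes the SAI exactly by the prescribed amount (same-quantity
identity), so the match is to machine precision and involves no tuning.

**Group statistics.** Means, sample SDs (n − 1 denominator) and a Welch
(unequal-variance) two-sample t-test; the test is unnamed in the source, and
Welch is the safe default for two independent small groups. Note the dynamic
reference column has sample SD 0.0296, printed as 0.029 — a truncation; the
acceptance test checks the computed value against both readings.

## Determinism

Every random choice flows from an explicit integer seed through
`numpy.random.default_rng`; constraint sweeps run in fixed order; scenario
artifacts (JSON reports with sorted keys) are byte-identical across runs
with the same scenario and seed.

## What the synthetic world establishes — and what it does not

The generators emulate the *stated* experimental world: the scene layout, a
60 Hz scripted operator, the printed per-trial SAI values, and the printed
model constants. They do not contain patient-specific CT anatomy, real
operator motor noise, learning effects, or the published dispersion means
(whose generative parameters are unpublished — the dispersion metric is
implemented and tested against closed forms instead). A green suite
establishes that the algorithms have the specified analytic behaviour and
that the pipeline reproduces the printed summary statistics from the printed
per-trial data; it cannot establish fresh-human-subject effects (e.g. a new
p < 0.001), frame rates, or 1 kHz haptic-loop timing, and does not try to.
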