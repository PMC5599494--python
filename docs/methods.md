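# Methods

`vesiturn` simulates a closed cellular membrane as a dynamically
triangulated surface whose molecular content turns over: triangles are the
coarse-grained unit of membrane material (each carrying a fixed number
`m_u` of molecules), vertex motion carries the mechanics, edge flips carry
in-plane fluidity, and stress-dependent split/merge moves exchange material
with an implicit intracellular reservoir. This note records the model, the
numerical choices, and what the test battery does and does not establish.

## Model

### Mechanics

Vertices obey the overdamped Langevin equation

    eta dr_i/dt = -grad_i U + w_i,
    <w_i> = 0,   <w_i (t) w_j (t')> = 2 eta kBT delta_ij delta(t-t') I,

integrated by Euler–Maruyama. The energy is

    U = U_cc + U_eff + U_act

with

* `U_cc = sum_{i<j, l_ij < l_rep} (K_r/2)(l_ij/l_rep - 1)^2` — a short-ranged
  pairwise vertex repulsion that keeps the discretization from collapsing;
* `U_eff` — volume elasticity `(K_v/2)(v/v_eq - 1)^2` per vesicle, area
  elasticity `(K_a/2)(a_f/a_eq - 1)^2` per triangle, and the Julicher
  discrete bending energy `sum_i 2 K_c M_i^2 / A_i`, where
  `M_i = sum_j l_j theta_j / 4` sums signed dihedral angles over the edges
  around vertex `i` and `A_i = sum_f a_f / 3` is the barycentric vertex
  area;
* `U_act = sum_f kappa_act (1 + cos phi_f)/2 a_f` — an optional cortical
  tension biased along +x, with `phi_f` the polar angle of the face
  centroid seen from the vesicle center. `phi_f` is frozen during each
  force evaluation, making the term non-conservative; this is the motor of
  the migration scenario.

Forces are exact analytic gradients (closed forms for the area, volume,
edge-length and dihedral-angle derivatives), assembled vectorized over the
mesh. A central finite-difference oracle (with the active weight frozen,
consistent with the model definition) pins every term to ~1e-7 relative in
the tests.

### Fluidity and turnover

One remodeling sweep runs per integration step:

* **Flips** — each edge is an attempt candidate with probability
  `dt/tau_f`; an attempted flip is accepted with the Metropolis factor
  `min(1, exp(-dU/kBT))`, where `dU` is the exact total-energy gap of the
  move. This realizes a per-edge flip rate `(1/tau_f) exp(-dU/kBT)` for
  unfavorable moves and conserves molecules (canonical ensemble).
* **Turnover** — each edge is a candidate with probability `dt/tau_t`
  (never, when `tau_t` is infinite); the direction (split or merge) is a
  fair coin. Acceptance is `min(1, exp(-(dE -/+ 2 m_u mu_r)/kBT))`, upper
  sign for splits. The cost `dE = eps_t (1 -/+ strain/gamma_t)` depends on
  the mean area strain of the two adjacent faces (evaluated on the
  pre-event pair for both directions), encoding mechanosensitive transport:
  stretch beyond `gamma_t` makes splitting free, compression favors
  merging. The reservoir chemical potential derives from the cubic free
  energy `G_r = kBT |M_t - M_eq|^3 / (12 m_u M_inst^2)`, i.e.
  `mu_r = -(kBT/(4 m_u M_inst^2)) (M_t - M_eq)|M_t - M_eq|`: `M_inst` sets
  how loosely the vesicle's molecule count may wander from `M_eq`. An
  accepted split inserts a vertex at the edge midpoint (+2 faces) and moves
  `2 m_u` molecules from the reservoir to the vesicle; a merge collapses
  the edge to its midpoint (-2 faces) and returns them. `M_t + M_r` is
  conserved to the integer.

The cubic `G_r` is motivated by a Gaussian picture of the stationary
`M_t` distribution with spread `M_inst`; since the stochastic dynamics do
not make that law exactly Gaussian, the implementation treats `M_inst` as a
stiffness scale only and the tests assert the restoring direction, not the
stationary spread.

A move accepted thermodynamically can still be rejected by the mesh
legality gate (below); such events are cancelled without molecule transfer.

### Legality and mesh quality

Every move must keep the mesh a closed, consistently oriented, genus-0
manifold (`chi = 2`, `E = 3F/2`, total angle deficit `4 pi`). The quality
gate additionally rejects any move that would create a face with minimum
angle below 5 degrees, a vertex valence outside [3, 12], a flip whose
opposite vertices are already connected, a collapse violating the link
condition (the endpoints must share exactly the two apex vertices), or a
mesh below 8 faces. All thresholds are configuration keys.

## Units and defaults

Model units: length `l = sqrt(a_eq)`, energy `kBT`, molecules `m_u`, and
time `tau = 0.1 eta a_eq / kBT`; with `l = tau = kBT = 1` this fixes
`eta = 10`. Defaults (overridable in the flat YAML config, keyed by the
standard symbols): `K_v = 1e4`, `K_a = 50`, `K_c = 10` (studies scan
1–30), `K_r = 1e3`, `kappa_act = 0` (3 when the migration scenario enables
it), `tau_f = 1e-2`, `tau_t = 1` or infinite, `eps_t = 0.1`,
`gamma_t = 0.05`, `M_inst = 10` (studies scan 10–1000), `dt = 1e-3`.
`l_rep` defaults to half the side of the equilateral triangle of area
`a_eq` (~0.76): just below the vertex spacing of any regular fan of
equal-area triangles, so relaxed packings feel no repulsion while a vertex
inserted on a short edge still does.

`v_eq` defaults to `sphericity * (4/3) pi (F a_eq / 4 pi)^{3/2}` with
sphericity 0.85 — 2527.5 for the 1000-face reference vesicle, quoted as
the integer 2527. `M_eq` defaults to the initial molecule content
(`N_t m_u`, 1000 for the reference vesicle) and `M_tt` to `2 M_eq`, so the
reservoir and vesicle are comparable in size.

## Initial condition

The generator places `V = F/2 + 2` points on a golden-angle (Fibonacci)
spiral (tiny seeded jitter avoids degenerate hull facets) and takes the
convex hull, which yields exactly `2V - 4 = F` triangles — icosphere
subdivision cannot reach arbitrary even counts such as 1000. The sphere is
scaled to total area `F a_eq`, then equilibrated by cycles of L-BFGS
descent (analytic gradients) alternating with greedy downhill flips, at
`K_c = 10` with turnover off and the volume constraint centered on the
sphere's own volume. Convergence: no flip accepted and energy change per
descent iteration below 1e-6. The result has total area within ~0.03% of
`F a_eq` and all face areas within ~1% of `a_eq`; the reference area trace
of a production run therefore starts at `F a_eq` exactly, and the run
itself relaxes the volume toward the sphericity-0.85 `v_eq`.

Two lessons are baked into `relax_mesh`:

* The Julicher vertex measure `M_i` cancels on zigzag pleats (alternating
  +/- pi dihedrals), so deep noiseless descent of a strongly deflated
  vesicle can fold the surface isometrically into creases that cost no
  discrete bending energy — a pure discretization artifact that thermal
  dynamics never sustains (production runs stay below |theta| ~ 1). A fold
  guard (`theta_guard = 2.5` rad) reverts and stops a descent cycle that
  crosses it.
* On a near-regular sphere the tangential modes are almost flat, so a
  per-cycle energy criterion never terminates; the stopping rule is per
  descent iteration.

## Numerical implementation

A geometry/adjacency cache holds per-face areas, normals and centroids,
per-edge lengths and signed dihedrals (positive = locally convex), and
per-vertex `M_i`, `A_i`. Positions change every step, so the geometry
layer is refreshed vectorized once per step; the adjacency layer is
rebuilt only after splits/merges. Accepted flips patch both layers in
place, and the tests assert bit-level agreement with full rebuilds after
thousands of mixed events.

Flip attempts are evaluated in a vectorized batch per sweep: legality,
trial geometry and energy gaps for all candidates against the pre-sweep
cache, then sequential Metropolis acceptance in the shuffled candidate
order; a candidate whose 4-vertex stencil overlaps an earlier accepted
flip in the same sweep is recomputed through the scalar path (the volume
term is always recomputed against the live total volume). Split/merge
trial energies use a local-region evaluator over the affected faces,
edges and vertices; both local paths agree with a global energy
recomputation to ~1e-12 in the tests.

Repulsion pairs come from a k-d tree (`scipy.spatial.cKDTree`) — the sum
is short-ranged by construction — and the pair set is tested against the
O(n^2) double loop. Mesh files travel as ASCII OFF/PLY via `trimesh`
(`process=False`, so the face list round-trips bit-exactly).

Degenerate inputs: zero-area faces, boundary edges in closed-mesh
operations, vanishing vertex areas, and centroid-center coincidence in the
active term each raise a named error; integration aborts with a diagnostic
if positions go non-finite.

Determinism: a single PCG64 generator drives noise, attempt selection,
shuffling and direction coins, so identical config + seed reproduces the
observable table, event log and final mesh bit-for-bit.

## Observables

Sampled rows carry time, total area and enclosed volume, face and molecule
counts, sphericity `v / [(4/3) pi (A/4 pi)^{3/2}]`, the mean local Gaussian
curvature (angle deficit over vertex area, averaged over vertices — the
per-vertex quantity is not conserved because turnover changes the vertex
count, even though the total deficit stays `4 pi`), centroid, the energy
breakdown, and cumulative event counters. Every turnover attempt is logged
with its polar angle relative to +x seen from the centroid, strain, cost
and chemical-potential term; flip attempts are aggregated into counters by
default (they run at ~50 per step; `log_flips=True` logs them
individually).

## Scaled scenarios and what the tests show

The reference studies are reproduced on a 320-face vesicle (502→162
vertices) with `M_eq = 320`, which keeps whole-scenario runs in seconds to
minutes:

* no turnover (`tau_t = inf`, `K_c = 3`, t = 10): the total area stays
  within 5% (measured ~3.5% drift to the thermal steady state) and `N_t`
  is a constant of motion;
* turnover (`tau_t = 1`, `M_inst = 1000`, `K_c = 3`, t = 8): `N_t` and
  area grow toward a plateau (~+6% area, ~+40 molecules at this size);
* rigidity scan (`K_c` in {1, 3, 10, 30}, 3 seeds, t = 5): the final
  molecule count is monotonically non-increasing in `K_c` — floppy
  membranes stretch thermally and split, stiff ones shed area through
  merges;
* migration (`kappa_act = 3`, `K_c = 10`, `M_inst = 10`, t = 60): with
  turnover the centroid travels persistently along x (an order of
  magnitude farther than the no-turnover control); the local strain field
  varies systematically with the polar angle.

The split-vs-merge angular *density* difference that accompanies migration
is real but tiny per event (dipolar rate modulation of order 1%, measured
over a dedicated t = 120 run): the persistent displacement is its time
integral, which is why the displacement comparison is statistically easy
while a two-sample test on event angles needs ~1e5 accepted events per
kind — beyond this suite's problem sizes. The corresponding acceptance
test is included at t = 60 and is expected to fail for power, not for
physics; treat its outcome accordingly.

What the synthetic scenarios do **not** show: the generator's vesicle is a
regularized sphere, not a real cell shape; there is no osmotic pressure,
no hydrodynamics (scalar friction only), no in-plane shear elasticity or
spontaneous curvature, and molecular detail (lipid species, curvature
proteins) is entirely coarse-grained into `dE` and `mu_r`. Quantitative
agreement with any real membrane requires mapping the model units through
measured `kBT`, `a_eq` and `K_c` (the default rigidity range corresponds
to ~4e-20–4e-19 J at 310 K, the range of common lipid bilayers).

## Known limitations

* The vertex-based bending energy is blind to accordion pleats (see
  above); the quality gate and thermal noise keep production runs away
  from them, but pathological hand-built inputs can exploit it.
* `dt = 1e-3` with the default stiffnesses is stable for the studied
  scenarios but not adaptively controlled; instabilities abort with a
  diagnostic rather than being auto-corrected.
* The attempt-rate/Metropolis factorization realizes the target event
  rates exactly only for unfavorable moves (favorable ones cap at one
  attempt per window `tau`); both remodeling channels use the same
  convention, so their ratio is unbiased.
* The event log keeps all turnover attempts in memory for the duration of
  a run; multi-thousand-time-unit runs should stream or thin it.
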