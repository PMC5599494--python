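# vesiturn

Coarse-grained simulation of closed cellular membranes whose molecular
content turns over. A vesicle is a dynamically triangulated surface:
vertices move by overdamped Langevin dynamics under volume, area, bending,
excluded-volume and (optionally) active cortical-tension energies; edge
flips keep the triangulation fluid; and stress-dependent split/merge moves
create and delete triangles, exchanging membrane molecules with an
implicit intracellular reservoir through a grand-canonical chemical
potential. The package is for biophysicists studying how molecular
turnover shapes membrane morphology and enables cell-scale behaviors such
as adaptive area regulation and migration without external traction.

## Model in brief

Vertex positions `r_i` obey

    eta dr_i/dt = -grad U + w_i,      <w_i w_j> = 2 eta kBT delta_ij delta(t-t') I

with

    U = sum_{i<j} (K_r/2)(l_ij/l_rep - 1)^2 [l_ij < l_rep]          (repulsion)
      + (K_v/2)(v/v_eq - 1)^2 + sum_f (K_a/2)(a_f/a_eq - 1)^2       (volume, area)
      + sum_i 2 K_c M_i^2 / A_i                                     (bending)
      + sum_f kappa_act (1 + cos phi_f)/2 a_f                       (active tension)

where `M_i = sum_j l_j theta_j / 4` is the total mean curvature around a
vertex (signed dihedral angles `theta_j`) and `A_i` its barycentric area.
Each triangle carries `m_u` membrane molecules. Per integration step every
edge is a flip candidate with probability `dt/tau_f` (Metropolis
acceptance `min(1, e^{-dU/kBT})`) and a turnover candidate with
probability `dt/tau_t`: a split or merge (fair coin) accepted with
`min(1, e^{-(dE -/+ 2 m_u mu_r)/kBT})`, where
`dE = eps_t (1 -/+ strain/gamma_t)` senses the local area strain and
`mu_r = -(kBT/(4 m_u M_inst^2))(M_t - M_eq)|M_t - M_eq|` is the reservoir
chemical potential. Units: `l = sqrt(a_eq) = 1`, `kBT = 1`,
`tau = 0.1 eta a_eq / kBT = 1` (so `eta = 10`).

See `docs/methods.md` for the full model description, defaults, numerical
choices and limitations.

## Worked example

Generate an equilibrated 320-triangle vesicle, check its structure, and
run two time units with turnover in the floppy-membrane growth regime
(`K_c = 3`, `M_inst = 1000`, `tau_t = 1`):

```console
$ vesiturn generate --faces 320 --seed 0 --out vesicle.off
wrote vesicle.off: 320 faces, 162 vertices, area 320.07, volume 534.34

$ vesiturn validate vesicle.off
OK: 320 faces, 162 vertices, 480 edges, chi=2, total angle deficit = 4*pi

$ vesiturn run --mesh vesicle.off --kc 3 --tau-t 1 --minst 1000 --t-end 2 --seed 1 --out growth_run
t=2: N_t=368, area=359.83, volume=436.98, flips=10838, splits=417, merges=393 -> growth_run
```

Reading the output: the generator delivers a closed genus-0 triangulation
whose total area equals one equilibrium area `a_eq` per face (320.07) and
whose element counts satisfy the Euler relation (162 - 480 + 320 = 2).
Over two time units the volume relaxes toward its equilibrium value
(`v_eq ~ 457` at this size, sphericity 0.85) while thermal stretching at
low bending rigidity biases splits over merges (417 vs 393): the vesicle
gains 2 molecules per net split, growing from 320 to 368 triangles and
from 320 to ~360 area units — membrane growth by molecular turnover, not
by elastic stretch. `growth_run/` contains the sampled observable table
(`observables.csv`: area, volume, molecule counts, energy breakdown,
curvature statistics, centroid), the per-attempt turnover event log
(`events.csv`: time, kind, site polar angle, strain, acceptance), the
final mesh and a checkpoint.

The same machinery is available as a library:

```python
import vesiturn as vt

mesh = vt.generate_vesicle(320, seed=0)
cfg = vt.SimulationConfig(
    mech=vt.MechanicalParams(K_c=3.0),
    turnover=vt.TurnoverParams(tau_f=1e-2, tau_t=1.0),
    M_inst=1000.0, t_end=2.0, seed=1,
)
result = vt.run_simulation(cfg, mesh=mesh)
print(result.final()[["N_t", "area", "volume"]])
```

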