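"""Time integration: overdamped Langevin vertex motion with interleaved
stochastic remodeling sweeps, plus the observables sampled along a run.

Each mechanical step advances every vertex by Euler--Maruyama,

    r_i <- r_i + (dt/eta) * (F_i + w_i),

with ``F_i`` the exact energy gradient and ``w_i`` Gaussian noise of
per-component variance ``2 eta kBT / dt`` (delta-correlated thermal force),
so the free-vertex displacement variance is ``2 (kBT/eta) dt`` per
component.  One remodeling sweep runs per mechanical step: every edge is a
Bernoulli flip candidate with probability ``dt/tau_f`` and a turnover
candidate with probability ``dt/tau_t``; accepted moves are applied
immediately.  The friction default ``eta = 10`` follows from the model's
time unit ``tau = 0.1 eta a_eq / kBT`` with ``l = tau = kBT = 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import topology as topo
from .energetics import (
    MechanicalParams,
    active_center,
    energy_breakdown,
)
from .energetics import forces as compute_forces
from .mesh import MeshCache, TriangleMesh
from .turnover import (
    ReservoirState,
    TurnoverParams,
    attempt_probability,
    chemical_potential,
    flip_acceptance,
    turnover_acceptance,
    turnover_cost,
)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationInstability",
    "langevin_step",
    "topology_sweep",
    "run_simulation",
    "sphericity",
]


class SimulationInstability(RuntimeError):
    """Integration produced non-finite vertex positions."""


def sphericity(volume: float, area: float) -> float:
    """Volume over the volume of the sphere with the same surface area."""
    return volume / ((4.0 / 3.0) * math.pi * (area / (4.0 * math.pi)) ** 1.5)


def equilibrium_volume(
    face_count: int, target_sphericity: float, a_eq: float = 1.0
) -> float:
    """v_eq of a vesicle with area ``face_count * a_eq`` at a given sphericity."""
    area = face_count * a_eq
    return target_sphericity * (4.0 / 3.0) * math.pi * (area / (4.0 * math.pi)) ** 1.5


@dataclass
class SimulationConfig:
    """Complete run description; defaults are the reference parameter set.

    ``v_eq`` and ``M_eq`` default to values consistent with the initial
    vesicle (``v_eq`` from ``sphericity`` and ``face_count``; ``M_eq`` equal
    to the initial molecule content), which reproduces the standard
    1000-face setup (v_eq = 2527, M_eq = 1000) and scales coherently for
    smaller test vesicles.
    """

    mech: MechanicalParams = field(default_factory=MechanicalParams)
    turnover: TurnoverParams = field(default_factory=TurnoverParams)
    face_count: int = 1000
    sphericity: float = 0.85
    v_eq: float | None = None
    M_eq: float | None = None
    M_inst: float = 10.0
    m_u: int = 1
    M_tt: int | None = None
    dt: float = 1.0e-3
    t_end: float = 1.0
    sample_interval: float = 0.05
    seed: int = 0
    gate: topo.QualityGate = field(default_factory=topo.QualityGate)
    log_flips: bool = False
    frames_dir: str | None = None
    frame_interval: float | None = None
    init_mesh_path: str | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dt > self.turnover.tau_f:
            raise ValueError("dt must not exceed tau_f")


@dataclass
class SimulationResult:
    """Trajectory summary: sampled observables, event log and final state."""

    observables: pd.DataFrame
    events: pd.DataFrame
    mesh: TriangleMesh
    reservoir: ReservoirState
    counters: dict
    config: SimulationConfig

    def final(self) -> pd.Series:
        return self.observables.iloc[-1]


def langevin_step(
    positions: np.ndarray,
    forces: np.ndarray,
    eta: float,
    kBT: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler--Maruyama update of the overdamped Langevin equation."""
    new = positions + (dt / eta) * forces
    if kBT > 0:
        sigma = math.sqrt(2.0 * eta * kBT / dt)
        new = new + (dt / eta) * sigma * rng.standard_normal(positions.shape)
    return new


EVENT_COLUMNS = [
    "time",
    "kind",
    "u",
    "v",
    "accepted",
    "reason",
    "delta_E",
    "mu_term",
    "angle",
    "strain",
]


def _polar_angle(site, center) -> float:
    rel = (site[0] - center[0], site[1] - center[1], site[2] - center[2])
    rn = math.sqrt(rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2)
    if rn == 0.0:
        return float("nan")
    return math.acos(max(-1.0, min(1.0, rel[0] / rn)))


def topology_sweep(
    mesh: TriangleMesh,
    cache: MeshCache,
    params: MechanicalParams,
    turnover: TurnoverParams,
    reservoir: ReservoirState,
    rng: np.random.Generator,
    dt: float,
    center,
    t: float,
    counters: dict,
    events: list,
    gate: topo.QualityGate = topo.DEFAULT_GATE,
    log_flips: bool = False,
) -> None:
    """One stochastic remodeling sweep over the edges, in random order.

    Flip attempts run first (canonical, molecule-conserving), then turnover
    attempts (grand-canonical, transferring ``2 m_u`` molecules per event).
    Accepted moves are applied immediately; a move accepted thermodynamically
    but rejected by the mesh legality gate is cancelled without transfer.
    """
    kBT = params.kBT
    n_edges = len(cache.edges)
    p_flip = attempt_probability(dt, turnover.tau_f)
    if p_flip > 0.0:
        sel = np.flatnonzero(rng.random(n_edges) < p_flip)
        rng.shuffle(sel)
        if log_flips:
            # per-event logging goes through the scalar path
            for k in sel:
                counters["flip_attempts"] += 1
                k = int(k)
                u, v = (int(x) for x in cache.edges[k])
                try:
                    d_u, payload = topo.flip_trial(cache, k, params, center, gate)
                except topo.IllegalMove as err:
                    events.append(
                        (t, "flip", u, v, False, err.reason,
                         float("nan"), float("nan"), float("nan"), float("nan"))
                    )
                    continue
                if d_u <= 0 or rng.random() < flip_acceptance(d_u, kBT):
                    topo.apply_flip(cache, payload)
                    counters["flips"] += 1
                    events.append(
                        (t, "flip", u, v, True, "",
                         d_u, float("nan"), float("nan"), float("nan"))
                    )
                else:
                    events.append(
                        (t, "flip", u, v, False, "metropolis",
                         d_u, float("nan"), float("nan"), float("nan"))
                    )
        else:
            attempted, accepted = topo.flip_sweep(
                cache, params, sel, center, rng, gate, kBT
            )
            counters["flip_attempts"] += attempted
            counters["flips"] += accepted

    p_turn = attempt_probability(dt, turnover.tau_t)
    if p_turn > 0.0:
        sel = np.flatnonzero(rng.random(n_edges) < p_turn)
        rng.shuffle(sel)
        for k in sel:
            k = int(k)
            if k >= len(cache.edges):
                continue  # edge vanished in an earlier event this sweep
            counters["turnover_attempts"] += 1
            direction = "split" if rng.random() < 0.5 else "merge"
            f0, f1 = (int(x) for x in cache.edge_faces[k])
            mean_area = 0.5 * (cache.face_area[f0] + cache.face_area[f1])
            strain = mean_area / params.a_eq - 1.0
            d_e = turnover_cost(
                mean_area, params.a_eq, turnover.eps_t, turnover.gamma_t, direction
            )
            mu = chemical_potential(reservoir, kBT)
            mu_term = 2.0 * reservoir.m_u * mu * (1.0 if direction == "split" else -1.0)
            u, v = (int(x) for x in cache.edges[k])
            site = 0.5 * (mesh.positions[u] + mesh.positions[v])
            angle = _polar_angle(site, center)
            if rng.random() >= turnover_acceptance(
                d_e, mu, reservoir.m_u, direction, kBT
            ):
                events.append(
                    (t, direction, u, v, False, "thermodynamic",
                     d_e, mu_term, angle, strain)
                )
                continue
            try:
                if direction == "split":
                    topo.check_split(cache, k, gate)
                    topo.apply_split(mesh, cache, k)
                    reservoir.transfer_to_vesicle(2 * reservoir.m_u)
                    counters["splits"] += 1
                else:
                    topo.check_merge(cache, k, gate)
                    topo.apply_merge(mesh, cache, k)
                    reservoir.transfer_to_vesicle(-2 * reservoir.m_u)
                    counters["merges"] += 1
            except topo.IllegalMove as err:
                events.append(
                    (t, direction, u, v, False, err.reason,
                     d_e, mu_term, angle, strain)
                )
                continue
            cache.rebuild_topology()
            cache.refresh_geometry()
            events.append(
                (t, direction, u, v, True, "", d_e, mu_term, angle, strain)
            )


OBS_COLUMNS = [
    "time", "area", "volume", "N_t", "M_t", "M_r", "sphericity",
    "mean_gauss_curvature", "centroid_x", "centroid_y", "centroid_z",
    "U_cc", "U_volume", "U_area", "U_bending", "U_act", "U_total",
    "flips", "splits", "merges", "flip_attempts", "turnover_attempts",
]


def _sample(mesh, cache, params, center, reservoir, counters, t):
    br = energy_breakdown(mesh, params, center=center, cache=cache)
    deficits = cache.angle_deficits()
    mean_k = float(np.mean(deficits / cache.vertex_A))
    return (
        t, cache.total_area, cache.total_volume, mesh.n_faces,
        reservoir.M_t, reservoir.M_r,
        sphericity(cache.total_volume, cache.total_area),
        mean_k, float(center[0]), float(center[1]), float(center[2]),
        br.U_cc, br.U_volume, br.U_area, br.U_bending, br.U_act, br.U_total,
        counters["flips"], counters["splits"], counters["merges"],
        counters["flip_attempts"], counters["turnover_attempts"],
    )


def run_simulation(
    config: SimulationConfig, mesh: TriangleMesh | None = None
) -> SimulationResult:
    """Run a full trajectory; deterministic for a given config and seed."""
    rng = np.random.default_rng(config.seed)
    if mesh is None:
        if config.init_mesh_path is not None:
            from .io import read_mesh

            mesh = read_mesh(config.init_mesh_path)
        else:
            from .meshgen import generate_vesicle

            mesh = generate_vesicle(
                config.face_count,
                sphericity=config.sphericity,
                seed=int(rng.integers(2**31 - 1)),
            )
    else:
        mesh = mesh.copy()

    v_eq = config.v_eq
    if v_eq is None:
        v_eq = equilibrium_volume(
            mesh.n_faces, config.sphericity, config.mech.a_eq
        )
    params = config.mech.replace(v_eq=v_eq)
    m_eq = config.M_eq
    if m_eq is None:
        m_eq = mesh.n_faces * config.m_u
    reservoir = ReservoirState(
        M_t=mesh.n_faces * config.m_u,
        M_eq=m_eq,
        M_inst=config.M_inst,
        m_u=config.m_u,
        M_tt=config.M_tt,
    )

    frame_writer = None
    if config.frames_dir is not None:
        from .io import FrameWriter

        frame_writer = FrameWriter(config.frames_dir)

    cache = MeshCache(mesh)
    n_steps = int(round(config.t_end / config.dt))
    sample_every = max(1, int(round(config.sample_interval / config.dt)))
    frame_every = None
    if frame_writer is not None:
        frame_every = max(
            1, int(round((config.frame_interval or config.sample_interval) / config.dt))
        )
    counters = {
        "flips": 0, "splits": 0, "merges": 0,
        "flip_attempts": 0, "turnover_attempts": 0,
    }
    records = []
    events: list = []
    dt = config.dt
    eta = params.eta
    kBT = params.kBT

    for step in range(n_steps):
        t = step * dt
        center = active_center(mesh, cache)
        if step % sample_every == 0:
            records.append(
                _sample(mesh, cache, params, center, reservoir, counters, t)
            )
        if frame_every is not None and step % frame_every == 0:
            frame_writer.write(mesh, step)
        topology_sweep(
            mesh, cache, params, config.turnover, reservoir, rng, dt,
            center, t, counters, events, config.gate, config.log_flips,
        )
        center = active_center(mesh, cache)
        f = compute_forces(mesh, params, center, cache)
        mesh.positions = langevin_step(mesh.positions, f, eta, kBT, dt, rng)
        if not np.all(np.isfinite(mesh.positions)):
            raise SimulationInstability(
                f"non-finite positions at t={t + dt:.6g} (step {step + 1}); "
                f"N_t={mesh.n_faces}, last |F|max={np.abs(f).max():.3g}"
            )
        cache.refresh_geometry()

    center = active_center(mesh, cache)
    records.append(
        _sample(mesh, cache, params, center, reservoir, counters, n_steps * dt)
    )
    if frame_writer is not None:
        frame_writer.write(mesh, n_steps)

    observables = pd.DataFrame.from_records(records, columns=OBS_COLUMNS)
    events_df = pd.DataFrame.from_records(events, columns=EVENT_COLUMNS)
    return SimulationResult(observables, events_df, mesh, reservoir, counters, config)
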