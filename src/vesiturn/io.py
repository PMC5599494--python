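"""Mesh, configuration and trajectory file I/O.

Meshes travel as ASCII OFF or PLY (positions in model units, face winding
preserved exactly on round-trip); run configurations are flat YAML mappings
keyed by the standard parameter symbols; observables and event logs are
written as CSV by the CLI.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import trimesh
import yaml

from . import topology as topo
from .dynamics import SimulationConfig
from .energetics import MechanicalParams
from .mesh import MeshError, TriangleMesh, build_mesh
from .turnover import TurnoverParams

__all__ = [
    "MeshParseError",
    "read_mesh",
    "write_mesh",
    "load_config",
    "save_config",
    "config_to_dict",
    "FrameWriter",
]


class MeshParseError(MeshError):
    """Malformed mesh file."""


_FORMATS = {"off", "ply"}


def _format_of(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; use OFF or PLY")
    return fmt


def read_mesh(path, fmt: str | None = None, validate: bool = True) -> TriangleMesh:
    """Read an ASCII OFF or PLY mesh and validate it."""
    fmt = _format_of(path, fmt)
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False)
    except Exception as err:  # surface parser failures uniformly
        raise MeshParseError(f"{path}: {err}") from err
    if not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise MeshParseError(f"{path}: no triangular faces found")
    if tm.faces.shape[1] != 3:
        raise MeshParseError(f"{path}: non-triangular faces")
    return build_mesh(
        np.asarray(tm.vertices, dtype=float),
        np.asarray(tm.faces, dtype=np.int64),
        validate=validate,
    )


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write an ASCII OFF or PLY file preserving the face list bit-exactly."""
    fmt = _format_of(path, fmt)
    tm = trimesh.Trimesh(
        vertices=mesh.positions, faces=mesh.faces, process=False
    )
    if fmt == "ply":
        data = tm.export(file_type="ply", encoding="ascii")
        with open(path, "wb") as fh:
            fh.write(data)
    else:
        with open(path, "w") as fh:
            fh.write(tm.export(file_type="off"))


class FrameWriter:
    """Writes numbered OFF frames of a running simulation."""

    def __init__(self, directory, fmt: str = "off"):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)
        self.fmt = fmt

    def write(self, mesh: TriangleMesh, step: int) -> Path:
        path = self.directory / f"frame_{step:08d}.{self.fmt}"
        write_mesh(mesh, path, self.fmt)
        return path


# ---------------------------------------------------------------------------
# flat YAML configuration keyed by the standard parameter symbols

_MECH_KEYS = {
    "K_v": "K_v", "K_a": "K_a", "K_c": "K_c", "K_r": "K_r",
    "kappa_act": "kappa_act", "a_eq": "a_eq", "l_rep": "l_rep",
    "eta": "eta", "kBT": "kBT",
}
_TURN_KEYS = {"tau_f": "tau_f", "tau_t": "tau_t", "eps_t": "eps_t",
              "gamma_t": "gamma_t"}
_GATE_KEYS = {"min_angle_deg", "min_valence", "max_valence", "min_faces"}
_TOP_KEYS = {
    "face_count", "sphericity", "v_eq", "M_eq", "M_inst", "m_u", "M_tt",
    "dt", "t_end", "sample_interval", "seed", "log_flips",
    "frames_dir", "frame_interval", "init_mesh_path",
}


def _plain(value):
    if isinstance(value, np.floating):
        return float(value)
    if isinstance(value, np.integer):
        return int(value)
    return value


def config_to_dict(config: SimulationConfig) -> dict:
    out: dict = {}
    for key, attr in _MECH_KEYS.items():
        out[key] = _plain(getattr(config.mech, attr))
    # v_eq in MechanicalParams is superseded by the config-level value
    for key, attr in _TURN_KEYS.items():
        out[key] = _plain(getattr(config.turnover, attr))
    for key in _GATE_KEYS:
        out[key] = _plain(getattr(config.gate, key))
    for key in _TOP_KEYS:
        out[key] = _plain(getattr(config, key))
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    unknown = (
        set(data)
        - set(_MECH_KEYS)
        - set(_TURN_KEYS)
        - _GATE_KEYS
        - _TOP_KEYS
    )
    if unknown:
        raise KeyError(f"unknown configuration keys: {sorted(unknown)}")
    mech_kw = {attr: data.pop(k) for k, attr in _MECH_KEYS.items() if k in data}
    turn_kw = {attr: data.pop(k) for k, attr in _TURN_KEYS.items() if k in data}
    gate_kw = {k: data.pop(k) for k in list(data) if k in _GATE_KEYS}
    if "tau_t" in turn_kw and turn_kw["tau_t"] is None:
        turn_kw["tau_t"] = math.inf
    return SimulationConfig(
        mech=MechanicalParams(**mech_kw),
        turnover=TurnoverParams(**turn_kw),
        gate=topo.QualityGate(**gate_kw),
        **data,
    )


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a flat mapping")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def save_result(result, directory) -> None:
    """Write observables, event log, final mesh and checkpoint metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    result.observables.to_csv(directory / "observables.csv", index=False)
    result.events.to_csv(directory / "events.csv", index=False)
    write_mesh(result.mesh, directory / "final_mesh.off")
    state = {
        "M_t": int(result.reservoir.M_t),
        "M_tt": int(result.reservoir.M_tt),
        "M_eq": float(result.reservoir.M_eq),
        "M_inst": float(result.reservoir.M_inst),
        "m_u": int(result.reservoir.m_u),
        "counters": {k: int(v) for k, v in result.counters.items()},
    }
    with open(directory / "checkpoint.yaml", "w") as fh:
        yaml.safe_dump(state, fh)
    save_config(result.config, directory / "config.yaml")
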