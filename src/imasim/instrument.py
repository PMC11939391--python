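"""Kinematics of jawed surgical instruments (forceps / electrocautery).

The instrument pose lives in SE(3) through the transform hierarchy
T_world = T_controller · T_local · T_initial. Jaw closure is a single
half-angle θ ∈ [0, θ_max] (θ_max default 30°) integrated from a scripted rate
θ̇; the jaws rotate symmetrically about the hinge axis as R(±θ, α). The
instrument counts as closed below the 2.86° threshold — a pure function of θ,
no hysteresis. Grasping kinematically attaches nearby particles to the tool
frame; release restores their inverse masses bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation, Slerp

from .mesh_core import RigidTransform
from .pbd import ParticleSystem

logger = logging.getLogger(__name__)

THETA_MAX_DEFAULT = np.deg2rad(30.0)       # 0.5236 rad
CLOSE_THRESHOLD_DEFAULT = np.deg2rad(2.86)  # 0.04991 rad

__all__ = [
    "InstrumentState",
    "world_transform",
    "update_jaw",
    "jaw_transforms",
    "grasp",
    "release",
    "update_grasped_particles",
    "ToolScript",
    "load_tool_script",
    "save_tool_script",
    "THETA_MAX_DEFAULT",
    "CLOSE_THRESHOLD_DEFAULT",
]


@dataclass
class InstrumentState:
    """Pose chain, jaw state and the set of currently grasped particles."""

    t_controller: RigidTransform = field(default_factory=RigidTransform.identity)
    t_local: RigidTransform = field(default_factory=RigidTransform.identity)
    t_initial: RigidTransform = field(default_factory=RigidTransform.identity)
    jaw_angle: float = 0.0
    jaw_rate: float = 0.0
    theta_max: float = THETA_MAX_DEFAULT
    close_threshold: float = CLOSE_THRESHOLD_DEFAULT
    jaw_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    grasp_set: dict[int, tuple[float, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.jaw_axis = np.asarray(self.jaw_axis, dtype=float).reshape(3)
        mag = np.linalg.norm(self.jaw_axis)
        if abs(mag - 1.0) > 1e-9:
            raise ValueError("jaw axis must be a unit vector")
        if not (0.0 <= self.jaw_angle <= self.theta_max):
            raise ValueError("jaw angle must lie in [0, theta_max]")

    @property
    def closed(self) -> bool:
        return self.jaw_angle < self.close_threshold

    @property
    def grasping(self) -> bool:
        return bool(self.grasp_set)


def world_transform(state: InstrumentState) -> RigidTransform:
    """T_world = T_controller · T_local · T_initial (printed composition order)."""
    return state.t_controller @ state.t_local @ state.t_initial


def update_jaw(state: InstrumentState, dt: float) -> InstrumentState:
    """Integrate θ ← clamp(θ + θ̇·dt, 0, θ_max), in place; returns the state."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    state.jaw_angle = float(np.clip(state.jaw_angle + state.jaw_rate * dt,
                                    0.0, state.theta_max))
    return state


def jaw_transforms(state: InstrumentState) -> tuple[RigidTransform, RigidTransform]:
    """World transforms of the two jaws: T_world · R(±θ, α)."""
    w = world_transform(state)
    r_up = RigidTransform(Rotation.from_rotvec(state.jaw_angle * state.jaw_axis)
                          .as_matrix())
    r_lo = RigidTransform(Rotation.from_rotvec(-state.jaw_angle * state.jaw_axis)
                          .as_matrix())
    return w @ r_up, w @ r_lo


def grasp(state: InstrumentState, system: ParticleSystem,
          capture_radius: float = 0.002) -> set[int]:
    """Kinematically attach particles within ``capture_radius`` of the jaw midpoint.

    Only a closed instrument can grasp (an open one is a warned no-op).
    Attached particles get inverse mass 0 and are slaved to the tool frame via
    :func:`update_grasped_particles`; their original inverse masses are kept
    for exact restoration on release.
    """
    if not state.closed:
        logger.warning("grasp attempted with open jaws: ignored")
        return set()
    w = world_transform(state)
    tip = w.translation
    inv = w.inverse()
    d = np.linalg.norm(system.positions - tip, axis=1)
    caught = np.flatnonzero((d <= capture_radius) & (system.inverse_masses > 0))
    for idx in caught:
        local = inv.apply(system.positions[idx])
        state.grasp_set[int(idx)] = (float(system.inverse_masses[idx]), local)
        system.inverse_masses[idx] = 0.0
        system.velocities[idx] = 0.0
    return set(state.grasp_set)


def update_grasped_particles(state: InstrumentState,
                             system: ParticleSystem) -> None:
    """Slave grasped particles to the current tool frame, in place."""
    if not state.grasp_set:
        return
    w = world_transform(state)
    for idx, (_, local) in state.grasp_set.items():
        system.positions[idx] = w.apply(local)


def release(state: InstrumentState, system: ParticleSystem) -> set[int]:
    """Restore the original inverse masses of all grasped particles, bitwise."""
    released = set(state.grasp_set)
    for idx, (w0, _) in state.grasp_set.items():
        system.inverse_masses[idx] = w0
    state.grasp_set.clear()
    return released


# ---------------------------------------------------------------------------
# scripted trajectories (the stand-in for haptic hardware)
# ---------------------------------------------------------------------------

SCRIPT_COLUMNS = ["time_s", "tx", "ty", "tz", "qw", "qx", "qy", "qz",
                  "jaw_rate", "pedal_state"]


@dataclass
class ToolScript:
    """Scripted 60 Hz tool poses: times, positions, orientations, jaw rate, pedal."""

    times: np.ndarray
    positions: np.ndarray
    quaternions: np.ndarray  # (n, 4) scalar-first (qw, qx, qy, qz)
    jaw_rates: np.ndarray
    pedal_states: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("script times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def pose_at(self, t: float) -> tuple[RigidTransform, float, bool]:
        """Linearly interpolated (pose, jaw rate, pedal) at time t (clamped)."""
        t = float(np.clip(t, self.times[0], self.times[-1]))
        k = int(np.searchsorted(self.times, t, side="right") - 1)
        k = min(k, len(self.times) - 2) if len(self.times) > 1 else 0
        if len(self.times) == 1:
            pos = self.positions[0]
            quat = self.quaternions[0]
        else:
            t0, t1 = self.times[k], self.times[k + 1]
            a = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
            pos = (1 - a) * self.positions[k] + a * self.positions[k + 1]
            rots = Rotation.from_quat(self.quaternions[[k, k + 1]][:, [1, 2, 3, 0]])
            quat_r = Slerp([0.0, 1.0], rots)(a)
            q = quat_r.as_quat()
            quat = np.array([q[3], q[0], q[1], q[2]])
        pose = RigidTransform.from_quaternion(*quat, translation=pos)
        return pose, float(self.jaw_rates[k]), bool(self.pedal_states[k])


def load_tool_script(path) -> ToolScript:
    df = pd.read_csv(path)
    missing = [c for c in SCRIPT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: trajectory script missing columns {missing}")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return ToolScript(df["time_s"].to_numpy(dtype=float),
                      df[["tx", "ty", "tz"]].to_numpy(dtype=float),
                      q,
                      df["jaw_rate"].to_numpy(dtype=float),
                      df["pedal_state"].to_numpy().astype(bool))


def save_tool_script(script: ToolScript, path) -> None:
    df = pd.DataFrame({
        "time_s": script.times,
        "tx": script.positions[:, 0], "ty": script.positions[:, 1],
        "tz": script.positions[:, 2],
        "qw": script.quaternions[:, 0], "qx": script.quaternions[:, 1],
        "qy": script.quaternions[:, 2], "qz": script.quaternions[:, 3],
        "jaw_rate": script.jaw_rates,
        "pedal_state": script.pedal_states.astype(int),
    })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
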