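"""Position-based-dynamics core: prediction, constraint projection, damping, stepping.

The solver follows the classic two-stage scheme: positions are predicted by
explicit integration, then iteratively projected onto the constraint manifold
(distance constraints first, then dihedral bending constraints, fixed
Gauss–Seidel order), velocities are recovered from the position change, and
viscous damping is applied. Defaults mirror the soft-tissue configuration the
engine ships with: Δt = 5 ms, 5 solver iterations, linear damping 0.03 kg/s and
angular (rigid-mode) damping 0.01 kg·m²/s.

Stiffness k ∈ [0, 1] is interpreted per constraint with the classic PBD
per-iteration scaling k' = 1 − (1 − k)^(1/n_iterations), so the total
correction after n iterations is approximately k-independent of n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import count

import numpy as np

from ._kernels import (
    dihedral_angle_k,
    dihedral_gradients_k,
    dihedral_sweep,
    distance_sweep,
)

logger = logging.getLogger(__name__)

GRAVITY = np.array([0.0, 0.0, -9.81])

__all__ = [
    "ParticleSystem",
    "DistanceConstraint",
    "DihedralConstraint",
    "ConstraintSet",
    "SolverConfig",
    "predict_positions",
    "project_distance",
    "dihedral_angle",
    "dihedral_constraint_gradients",
    "project_dihedral",
    "apply_damping",
    "step",
    "constraint_residuals",
]


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------


@dataclass
class ParticleSystem:
    """Positions, velocities, inverse masses and rest positions of one object.

    Fixed (kinematic) particles carry inverse mass 0 and keep zero velocity
    through every solver step.
    """

    positions: np.ndarray
    velocities: np.ndarray = None  # type: ignore[assignment]
    inverse_masses: np.ndarray = None  # type: ignore[assignment]
    rest_positions: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        if self.inverse_masses is None:
            self.inverse_masses = np.ones(n)
        if self.rest_positions is None:
            self.rest_positions = self.positions.copy()
        self.velocities = np.array(self.velocities, dtype=float).reshape(-1, 3)
        self.inverse_masses = np.array(self.inverse_masses, dtype=float).reshape(-1)
        self.rest_positions = np.array(self.rest_positions, dtype=float).reshape(-1, 3)
        if not (len(self.velocities) == len(self.inverse_masses)
                == len(self.rest_positions) == n):
            raise ValueError("particle arrays have mismatched lengths")
        if np.any(self.inverse_masses < 0):
            raise ValueError("inverse masses must be >= 0")

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def fixed(self) -> np.ndarray:
        return self.inverse_masses == 0.0

    def masses(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.fixed, np.inf, 1.0 / np.where(self.fixed, 1.0,
                                                               self.inverse_masses))

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(self.positions.copy(), self.velocities.copy(),
                              self.inverse_masses.copy(), self.rest_positions.copy())


@dataclass(frozen=True)
class DistanceConstraint:
    """Stretch constraint C = |p_i − p_j| − d0 between a particle pair."""

    i: int
    j: int
    rest_length: float
    stiffness: float = 1.0

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("distance constraint needs two distinct particles")
        if self.rest_length < 0:
            raise ValueError("rest length must be >= 0")
        if not (0.0 <= self.stiffness <= 1.0):
            raise ValueError("stiffness must lie in [0, 1]")


@dataclass(frozen=True)
class DihedralConstraint:
    """Bending constraint C = θ(p0, p1, p2, p3) − θ_rest about shared edge (p2, p3)."""

    p0: int
    p1: int
    p2: int
    p3: int
    rest_angle: float
    stiffness: float = 1.0

    def __post_init__(self) -> None:
        if len({self.p0, self.p1, self.p2, self.p3}) != 4:
            raise ValueError("dihedral constraint needs four distinct particles")
        if not np.isfinite(self.rest_angle):
            raise ValueError("rest angle must be finite")
        if not (0.0 <= self.stiffness <= 1.0):
            raise ValueError("stiffness must lie in [0, 1]")

    @property
    def quad(self) -> tuple[int, int, int, int]:
        return (self.p0, self.p1, self.p2, self.p3)


class ConstraintSet:
    """Typed constraint store with stable integer ids, supporting the add/remove
    deltas produced by cutting. Iteration order (and hence Gauss–Seidel order)
    is insertion order."""

    def __init__(self) -> None:
        self._next_id = count()
        self.distance: dict[int, DistanceConstraint] = {}
        self.dihedral: dict[int, DihedralConstraint] = {}
        self._edge_index: dict[tuple[int, int], int] = {}
        self._packed = None

    # -- mutation ----------------------------------------------------------

    def add_distance(self, c: DistanceConstraint) -> int:
        cid = next(self._next_id)
        self.distance[cid] = c
        self._edge_index[(min(c.i, c.j), max(c.i, c.j))] = cid
        self._packed = None
        return cid

    def add_dihedral(self, c: DihedralConstraint) -> int:
        cid = next(self._next_id)
        self.dihedral[cid] = c
        self._packed = None
        return cid

    def remove(self, cid: int) -> None:
        if cid in self.distance:
            c = self.distance.pop(cid)
            self._edge_index.pop((min(c.i, c.j), max(c.i, c.j)), None)
        elif cid in self.dihedral:
            del self.dihedral[cid]
        else:
            raise KeyError(f"no constraint with id {cid}")
        self._packed = None

    def distance_id_for_edge(self, i: int, j: int) -> int | None:
        return self._edge_index.get((min(i, j), max(i, j)))

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.distance) + len(self.dihedral)

    def packed(self, iterations: int):
        """Packed numpy views for the solver kernels, with per-iteration
        stiffness k' = 1 − (1 − k)^(1/iterations). Cached until mutation."""
        key = (self._packed or (None,))[0]
        if key == iterations:
            return self._packed[1]
        dist = list(self.distance.values())
        dih = list(self.dihedral.values())
        di = np.array([c.i for c in dist], dtype=np.int64)
        dj = np.array([c.j for c in dist], dtype=np.int64)
        dr = np.array([c.rest_length for c in dist], dtype=float)
        dk = _per_iteration_stiffness(np.array([c.stiffness for c in dist]), iterations)
        quads = np.array([c.quad for c in dih], dtype=np.int64).reshape(-1, 4)
        ar = np.array([c.rest_angle for c in dih], dtype=float)
        ak = _per_iteration_stiffness(np.array([c.stiffness for c in dih]), iterations)
        pack = (di, dj, dr, dk, quads, ar, ak)
        self._packed = (iterations, pack)
        return pack

    def to_dataframe(self):
        """Constraint table as a pandas DataFrame, for CSV export/inspection."""
        import pandas as pd
        rows = []
        for cid, c in self.distance.items():
            rows.append({"id": cid, "type": "distance", "p0": c.i, "p1": c.j,
                         "p2": -1, "p3": -1, "rest": c.rest_length,
                         "stiffness": c.stiffness})
        for cid, c in self.dihedral.items():
            rows.append({"id": cid, "type": "dihedral", "p0": c.p0, "p1": c.p1,
                         "p2": c.p2, "p3": c.p3, "rest": c.rest_angle,
                         "stiffness": c.stiffness})
        return pd.DataFrame(rows, columns=["id", "type", "p0", "p1", "p2", "p3",
                                           "rest", "stiffness"])


def _per_iteration_stiffness(k: np.ndarray, iterations: int) -> np.ndarray:
    k = np.clip(np.asarray(k, dtype=float), 0.0, 1.0)
    return 1.0 - (1.0 - k) ** (1.0 / max(1, iterations))


@dataclass
class SolverConfig:
    """Fixed-timestep solver parameters (SI units)."""

    dt: float = 0.005
    iterations: int = 5
    external_acceleration: np.ndarray = field(
        default_factory=lambda: GRAVITY.copy())
    linear_damping: float = 0.03    # k_l, kg/s
    angular_damping: float = 0.01   # k_a, kg*m^2/s

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.linear_damping < 0 or self.angular_damping < 0:
            raise ValueError("damping coefficients must be >= 0")
        self.external_acceleration = np.asarray(self.external_acceleration,
                                                dtype=float).reshape(3)


# ---------------------------------------------------------------------------
# solver stages
# ---------------------------------------------------------------------------


def predict_positions(system: ParticleSystem, config: SolverConfig) -> np.ndarray:
    """Explicit prediction x* = x + v·dt + ½·a_ext·dt² (fixed particles stay put)."""
    bad = ~np.isfinite(system.positions).all(axis=1) | \
        ~np.isfinite(system.velocities).all(axis=1)
    if np.any(bad):
        raise ValueError(
            f"non-finite state on particle {int(np.flatnonzero(bad)[0])}")
    dt = config.dt
    x_star = (system.positions + system.velocities * dt
              + 0.5 * config.external_acceleration * dt * dt)
    fixed = system.fixed
    x_star[fixed] = system.positions[fixed]
    return x_star


def project_distance(positions: np.ndarray, constraint: DistanceConstraint,
                     inverse_masses: np.ndarray) -> np.ndarray:
    """Position corrections (2, 3) for one distance constraint at stiffness 1.

    Corrections lie along the inter-particle axis and are weighted by inverse
    mass. Coincident particles give a zero correction and a logged warning
    (the constraint gradient is undefined there).
    """
    i, j = constraint.i, constraint.j
    wi, wj = inverse_masses[i], inverse_masses[j]
    delta = positions[i] - positions[j]
    dist = float(np.linalg.norm(delta))
    out = np.zeros((2, 3))
    if wi + wj == 0.0:
        return out
    if dist < 1e-12:
        logger.warning("coincident particles %d, %d: distance gradient undefined",
                       i, j)
        return out
    corr = (dist - constraint.rest_length) / (dist * (wi + wj)) * delta
    out[0] = -wi * corr
    out[1] = wj * corr
    return out


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in [−π, π] about the shared edge p2→p3.

    Convention: the edge is oriented p2→p3 and the wing normals are
    n1 ∝ (p2−p0)×(p3−p0), n2 ∝ (p3−p1)×(p2−p1); a coplanar quad with
    same-facing normals has angle 0, and folding the p0 wing by +φ about the
    edge direction decreases the angle by φ.
    """
    args = [np.asarray(p, dtype=float).reshape(3) for p in (p0, p1, p2, p3)]
    theta = dihedral_angle_k(*args)
    if np.isnan(theta):
        raise ValueError("degenerate wing triangle (normal magnitude < 1e-12)")
    return float(theta)


def dihedral_constraint_gradients(p0, p1, p2, p3) -> np.ndarray:
    """Analytic (4, 3) gradient of the dihedral angle w.r.t. the four particles."""
    args = [np.asarray(p, dtype=float).reshape(3) for p in (p0, p1, p2, p3)]
    if np.isnan(dihedral_angle_k(*args)):
        raise ValueError("degenerate wing triangle (normal magnitude < 1e-12)")
    return dihedral_gradients_k(*args)


def project_dihedral(positions: np.ndarray, constraint: DihedralConstraint,
                     inverse_masses: np.ndarray) -> np.ndarray:
    """Position corrections (4, 3) for one dihedral constraint at stiffness 1.

    Standard PBD projection Δp_k = −w_k C ∇_kθ / Σ w |∇θ|² with C wrapped into
    (−π, π]. Degenerate wings give zero corrections and a logged warning.
    """
    quad = constraint.quad
    pts = [positions[k] for k in quad]
    theta = dihedral_angle_k(*pts)
    out = np.zeros((4, 3))
    if np.isnan(theta):
        logger.warning("degenerate dihedral wings on quad %s", quad)
        return out
    c = (theta - constraint.rest_angle + np.pi) % (2 * np.pi) - np.pi
    grads = dihedral_gradients_k(*pts)
    w = inverse_masses[list(quad)]
    denom = float(np.sum(w * np.einsum("ij,ij->i", grads, grads)))
    if denom < 1e-18:
        return out
    lam = -c / denom
    out = lam * w[:, None] * grads
    return out


def apply_damping(system: ParticleSystem, config: SolverConfig) -> None:
    """Viscous damping, in place.

    Linear: v ← v·(1 − dt·k_l/m) per particle (the drag force F = −k_l v
    integrated explicitly with the particle's own mass). Angular: the
    object's rigid-rotation mode about its centre of mass is extracted and
    damped by the torque T = −k_a ω (Müller-style mode damping) — per-particle
    spin is not tracked, so only the collective rotation is affected. The
    torque is integrated exactly on that mode, v_rot ← v_rot·exp(−dt·k_a/I_ω)
    with I_ω the effective inertia about the current rotation axis, which is
    unconditionally stable even when dt·k_a/I_ω is large (soft-tissue meshes
    have tiny inertias, so an explicit Euler torque update would explode).
    """
    free = ~system.fixed
    if not np.any(free):
        return
    m = 1.0 / system.inverse_masses[free]
    if config.linear_damping > 0:
        factor = 1.0 - config.dt * config.linear_damping / m
        system.velocities[free] *= np.clip(factor, 0.0, None)[:, None]
    if config.angular_damping > 0 and np.count_nonzero(free) >= 2:
        x = system.positions[free]
        v = system.velocities[free]
        mtot = m.sum()
        com = (m[:, None] * x).sum(axis=0) / mtot
        r = x - com
        L = (m[:, None] * np.cross(r, v)).sum(axis=0)
        # inertia tensor about the COM
        r2 = np.einsum("ij,ij->i", r, r)
        inertia = (m[:, None, None] * (np.eye(3)[None] * r2[:, None, None]
                                       - r[:, :, None] * r[:, None, :])).sum(axis=0)
        try:
            omega = np.linalg.solve(inertia, L)
        except np.linalg.LinAlgError:
            omega = np.linalg.pinv(inertia) @ L
        omega_sq = omega @ omega
        if omega_sq > 1e-24:
            inertia_eff = float(omega @ inertia @ omega) / omega_sq
            decay = np.exp(-config.dt * config.angular_damping
                           / max(inertia_eff, 1e-18))
            system.velocities[free] += (decay - 1.0) * np.cross(omega, r)


def _check_finite(arr: np.ndarray, stage: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise FloatingPointError(f"NaN/Inf detected after stage '{stage}'")


def step(system: ParticleSystem, constraints: ConstraintSet,
         config: SolverConfig) -> ParticleSystem:
    """Advance the system by one timestep, in place; returns the system.

    predict → (project all constraints) × iterations → velocity update →
    damping. Fixed particles never move; a NaN appearing after any stage
    raises naming that stage.
    """
    x_old = system.positions.copy()
    x = predict_positions(system, config)
    _check_finite(x, "predict")
    di, dj, dr, dk, quads, ar, ak = constraints.packed(config.iterations)
    w = system.inverse_masses
    for _ in range(config.iterations):
        if len(di):
            distance_sweep(x, w, di, dj, dr, dk)
        if len(quads):
            dihedral_sweep(x, w, quads, ar, ak)
    fixed = system.fixed
    x[fixed] = x_old[fixed]
    _check_finite(x, "project")
    system.velocities = (x - x_old) / config.dt
    system.velocities[fixed] = 0.0
    system.positions = x
    apply_damping(system, config)
    system.velocities[fixed] = 0.0
    _check_finite(system.velocities, "damping")
    return system


def constraint_residuals(system: ParticleSystem,
                         constraints: ConstraintSet) -> np.ndarray:
    """|C| for every constraint (distance then dihedral, insertion order)."""
    x = system.positions
    res = []
    for c in constraints.distance.values():
        res.append(abs(float(np.linalg.norm(x[c.i] - x[c.j])) - c.rest_length))
    for c in constraints.dihedral.values():
        theta = dihedral_angle_k(*(x[k] for k in c.quad))
        if np.isnan(theta):
            res.append(np.nan)
        else:
            res.append(abs(float((theta - c.rest_angle + np.pi)
                                 % (2 * np.pi) - np.pi)))
    return np.asarray(res)
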