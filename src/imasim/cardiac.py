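"""Parametric beating-heart surface and its influence on the surgical field.

The heart is kinematic: a closed surface (ellipsoid by default) whose vertices
move radially about a motion centre following a normalized periodic waveform,
u(v, t) = A · w(t mod T) · r̂(v). The waveform is an asymmetric raised cosine —
a systolic bump occupying the first third of the cycle, quiescent diastole —
normalized to peak 1 and zero at phase 0. Pulsation reaches the rest of the
scene as an exponentially decaying displacement field,
u_pt = A · w(t) · exp(−dist/L) · r̂, applied as a moving boundary to nearby
tissue; with amplitude 0 the module is inert and the scene is byte-identical
to the static scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_core import TriangleMesh, closest_point_on_mesh

__all__ = ["CardiacCycleSpec", "make_ellipsoid_heart", "waveform",
           "heart_displacement", "field_perturbation"]

SYSTOLIC_FRACTION = 1.0 / 3.0


def make_ellipsoid_heart(center=(0.0, 0.0, 0.0), semi_axes=(0.04, 0.03, 0.035),
                         n_theta: int = 12, n_phi: int = 16) -> TriangleMesh:
    """UV-sphere ellipsoid approximating the epicardial surface."""
    center = np.asarray(center, dtype=float)
    a, b, c = semi_axes
    verts = [center + np.array([0.0, 0.0, c])]
    for it in range(1, n_theta):
        th = np.pi * it / n_theta
        for ip in range(n_phi):
            ph = 2 * np.pi * ip / n_phi
            verts.append(center + np.array([a * np.sin(th) * np.cos(ph),
                                            b * np.sin(th) * np.sin(ph),
                                            c * np.cos(th)]))
    verts.append(center + np.array([0.0, 0.0, -c]))
    south = len(verts) - 1
    faces = []
    for ip in range(n_phi):
        faces.append([0, 1 + ip, 1 + (ip + 1) % n_phi])
    for it in range(n_theta - 2):
        r0 = 1 + it * n_phi
        r1 = r0 + n_phi
        for ip in range(n_phi):
            a0, a1 = r0 + ip, r0 + (ip + 1) % n_phi
            b0, b1 = r1 + ip, r1 + (ip + 1) % n_phi
            faces.append([a0, b0, b1])
            faces.append([a0, b1, a1])
    r0 = 1 + (n_theta - 2) * n_phi
    for ip in range(n_phi):
        faces.append([south, r0 + (ip + 1) % n_phi, r0 + ip])
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


@dataclass
class CardiacCycleSpec:
    """Cardiac pulsation parameters: period (default 0.8 s ≈ 75 bpm), peak
    radial amplitude (default 1 cm), transmission decay length, heart surface."""

    period: float = 0.8
    amplitude: float = 0.01
    decay_length: float = 0.03
    mesh: TriangleMesh = field(default_factory=make_ellipsoid_heart)
    motion_center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay_length <= 0:
            raise ValueError("decay length must be positive")
        if self.motion_center is None:
            self.motion_center = self.mesh.centroid()
        self.motion_center = np.asarray(self.motion_center, dtype=float).reshape(3)


def waveform(spec: CardiacCycleSpec, t: float | np.ndarray) -> float | np.ndarray:
    """Normalized periodic activation w(t) ∈ [0, 1]: raised-cosine systolic bump
    over the first third of the cycle, zero during diastole, w(0) = 0, peak 1."""
    phase = np.mod(np.asarray(t, dtype=float), spec.period) / spec.period
    w = np.where(phase < SYSTOLIC_FRACTION,
                 np.sin(np.pi * phase / SYSTOLIC_FRACTION) ** 2, 0.0)
    return float(w) if np.isscalar(t) or np.ndim(t) == 0 else w


def heart_displacement(spec: CardiacCycleSpec, t: float) -> np.ndarray:
    """Per-vertex radial displacement field of the heart surface at time t."""
    if t < 0:
        raise ValueError("time must be >= 0")
    r = spec.mesh.vertices - spec.motion_center
    mags = np.linalg.norm(r, axis=1, keepdims=True)
    rhat = np.where(mags > 1e-12, r / np.where(mags == 0, 1.0, mags), 0.0)
    return spec.amplitude * waveform(spec, t) * rhat


def field_perturbation(spec: CardiacCycleSpec, point, t: float) -> np.ndarray:
    """Pulsation-induced displacement at an arbitrary scene point.

    Magnitude decays exponentially with distance from the heart surface
    (length scale ``decay_length``); direction is radial from the motion
    centre. Identically zero for amplitude 0 (static scenario).
    """
    if spec.amplitude == 0.0:
        return np.zeros(3)
    p = np.asarray(point, dtype=float)
    dist, _, _ = closest_point_on_mesh(p, spec.mesh)
    r = p - spec.motion_center
    mag = np.linalg.norm(r)
    rhat = r / mag if mag > 1e-12 else np.zeros(3)
    return (spec.amplitude * waveform(spec, t)
            * np.exp(-dist / spec.decay_length)) * rhat
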