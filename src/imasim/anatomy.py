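"""Procedural construction of the simulated tissue components.

Four components make up the surgical field: a rectangular fascia sheet
(cloth-like PBD mesh, perimeter pinned, under gravity), a multi-resolution
vessel tube standing in for the internal mammary artery (low-res simulation
mesh + high-res display mesh linked by barycentric interpolation), a network
of connective-tissue strands joining the vessel to the chest-wall support,
and the rigid cylindrical chest-wall support itself.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import (
    TriangleMesh,
    PolylineMesh,
    closest_point_on_mesh,
    closest_point_on_triangle,
    ray_mesh_intersect,
)
from .pbd import ConstraintSet, DihedralConstraint, DistanceConstraint, ParticleSystem
from ._kernels import dihedral_angle_k

logger = logging.getLogger(__name__)

__all__ = [
    "FasciaSpec",
    "MultiResVessel",
    "StrandGenSpec",
    "Strand",
    "StrandNetwork",
    "build_fascia",
    "assign_uniform_mass",
    "constraints_from_mesh",
    "build_vessel",
    "interpolate_display",
    "generate_strands",
    "attach_strand_constraints",
    "update_strand_anchors",
    "build_support_cylinder",
]


# ---------------------------------------------------------------------------
# fascia sheet
# ---------------------------------------------------------------------------


@dataclass
class FasciaSpec:
    """Rectangular fascia sheet: width × height (m), grid resolution, total mass."""

    width: float = 0.08
    height: float = 0.12
    resolution: tuple[int, int] = (9, 13)
    total_mass: float = 0.05
    distance_stiffness: float = 1.0
    dihedral_stiffness: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("fascia dimensions must be positive")
        nx, ny = self.resolution
        if nx < 2 or ny < 2:
            raise ValueError("resolution must be at least 2x2")
        if self.total_mass <= 0:
            raise ValueError("total mass must be positive")


def assign_uniform_mass(mesh: TriangleMesh, total_mass: float) -> np.ndarray:
    """Uniform per-vertex masses m_v = M_total / N_v; they sum to M_total."""
    if total_mass <= 0:
        raise ValueError("total mass must be positive")
    nv = len(mesh.vertices)
    if nv < 1:
        raise ValueError("mesh has no vertices")
    return np.full(nv, total_mass / nv)


def constraints_from_mesh(mesh: TriangleMesh, rest_positions: np.ndarray,
                          distance_stiffness: float = 1.0,
                          dihedral_stiffness: float = 0.5) -> ConstraintSet:
    """Distance constraint on every unique edge, dihedral on every interior edge.

    Rest lengths/angles are measured on ``rest_positions``, so the rest pose is
    exactly on the constraint manifold.
    """
    cs = ConstraintSet()
    inc = mesh.edge_face_incidence()
    for (i, j) in map(tuple, mesh.edges()):
        rest = float(np.linalg.norm(rest_positions[i] - rest_positions[j]))
        cs.add_distance(DistanceConstraint(int(i), int(j), rest, distance_stiffness))
    for (i, j), fs in inc.items():
        if len(fs) != 2:
            continue
        wings = []
        for fi in fs:
            wings.append(int(next(v for v in mesh.faces[fi] if v not in (i, j))))
        p0, p1 = wings
        rest = float(dihedral_angle_k(rest_positions[p0], rest_positions[p1],
                                      rest_positions[i], rest_positions[j]))
        if np.isnan(rest):
            continue
        cs.add_dihedral(DihedralConstraint(p0, p1, int(i), int(j), rest,
                                           dihedral_stiffness))
    return cs


def build_fascia(spec: FasciaSpec,
                 origin=(0.0, 0.0, 0.0),
                 ) -> tuple[TriangleMesh, ConstraintSet, ParticleSystem]:
    """Regular triangulated grid over [0, w] × [0, h] in the x–y plane (z up).

    Each grid cell is split along the (i, j) → (i+1, j+1) diagonal. Perimeter
    vertices are pinned (inverse mass 0); interior vertices share the total
    mass uniformly.
    """
    nx, ny = spec.resolution
    xs = np.linspace(0.0, spec.width, nx)
    ys = np.linspace(0.0, spec.height, ny)
    verts = np.array([[x, y, 0.0] for y in ys for x in xs]) + np.asarray(origin,
                                                                         dtype=float)
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            v00 = j * nx + i
            v10 = v00 + 1
            v01 = v00 + nx
            v11 = v01 + 1
            faces.append([v00, v10, v11])
            faces.append([v00, v11, v01])
    mesh = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
    cs = constraints_from_mesh(mesh, mesh.vertices, spec.distance_stiffness,
                               spec.dihedral_stiffness)
    masses = assign_uniform_mass(mesh, spec.total_mass)
    inv_m = 1.0 / masses
    inv_m[mesh.boundary_vertex_flags] = 0.0
    system = ParticleSystem(mesh.vertices.copy(), inverse_masses=inv_m)
    return mesh, cs, system


# ---------------------------------------------------------------------------
# multi-resolution vessel
# ---------------------------------------------------------------------------


@dataclass
class MultiResVessel:
    """Low-res simulation tube + high-res display tube with a precomputed map.

    ``mapping`` holds, per display vertex, the simulation face index and the
    barycentric weights of its projection onto that face (weights ≥ 0, sum 1).
    """

    sim_mesh: TriangleMesh
    display_mesh: TriangleMesh
    mapping_faces: np.ndarray
    mapping_weights: np.ndarray
    centerline: PolylineMesh = None  # type: ignore[assignment]


def _segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments p1q1 and p2q2 (Ericson §5.1.9)."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= 1e-18 and e <= 1e-18:
        return float(np.linalg.norm(r))
    if a <= 1e-18:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = d1 @ r
        if e <= 1e-18:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = d1 @ d2
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-18 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def _transport_frames(points: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Parallel-transported (u, w) frame vectors perpendicular to each tangent."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    t0 = tangents[0]
    ref = np.array([0.0, 0.0, 1.0])
    if abs(t0 @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(t0, ref)
    u /= np.linalg.norm(u)
    frames = []
    for t in tangents:
        u = u - (u @ t) * t
        u /= np.linalg.norm(u)
        w = np.cross(t, u)
        frames.append((u.copy(), w))
    return frames


def _tube_mesh(points: np.ndarray, radius: float, n_circ: int) -> TriangleMesh:
    frames = _transport_frames(points)
    angles = np.linspace(0.0, 2 * np.pi, n_circ, endpoint=False)
    verts = []
    for p, (u, w) in zip(points, frames):
        for a in angles:
            verts.append(p + radius * (np.cos(a) * u + np.sin(a) * w))
    faces = []
    n_rings = len(points)
    for r in range(n_rings - 1):
        for c in range(n_circ):
            a = r * n_circ + c
            b = r * n_circ + (c + 1) % n_circ
            a2 = a + n_circ
            b2 = b + n_circ
            faces.append([a, b, b2])
            faces.append([a, b2, a2])
    return TriangleMesh(np.asarray(verts), np.asarray(faces, dtype=np.int64))


def _barycentric(point, a, b, c) -> np.ndarray:
    v0, v1, v2 = b - a, c - a, np.asarray(point, dtype=float) - a
    d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
    d20, d21 = v2 @ v0, v2 @ v1
    denom = d00 * d11 - d01 * d01
    if abs(denom) < 1e-18:
        return np.array([1.0, 0.0, 0.0])
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    bary = np.array([1.0 - v - w, v, w])
    bary = np.clip(bary, 0.0, None)
    return bary / bary.sum()


def build_vessel(centerline: np.ndarray, radius: float,
                 sim_segments: int = 8, display_segments: int = 16,
                 ) -> MultiResVessel:
    """Tube meshes around a shared centerline at two circumferential resolutions.

    Each display vertex is mapped to its nearest simulation face with the
    barycentric weights of its projection; display deformation is then the
    barycentric interpolation of simulation-vertex displacements.
    """
    points = np.asarray(centerline, dtype=float).reshape(-1, 3)
    if len(points) < 2:
        raise ValueError("centerline needs at least 2 points")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if display_segments < sim_segments:
        raise ValueError("display resolution must be >= simulation resolution")
    for i in range(len(points) - 1):
        for j in range(i + 2, len(points) - 1):
            if _segment_segment_distance(points[i], points[i + 1],
                                         points[j], points[j + 1]) < 1e-9:
                raise ValueError("self-intersecting centerline")
    sim = _tube_mesh(points, radius, sim_segments)
    disp = _tube_mesh(points, radius, display_segments)
    faces = np.empty(len(disp.vertices), dtype=np.int64)
    weights = np.empty((len(disp.vertices), 3))
    for vi, p in enumerate(disp.vertices):
        _, q, fi = closest_point_on_mesh(p, sim)
        a, b, c = sim.vertices[sim.faces[fi]]
        faces[vi] = fi
        weights[vi] = _barycentric(q, a, b, c)
    segs = np.column_stack([np.arange(len(points) - 1), np.arange(1, len(points))])
    cl = PolylineMesh(points, segs, np.full(len(points), 2 * radius))
    return MultiResVessel(sim, disp, faces, weights, cl)


def interpolate_display(vessel: MultiResVessel,
                        sim_positions: np.ndarray) -> np.ndarray:
    """Display-vertex positions given deformed simulation-vertex positions.

    display = display_rest + Σ_k w_k · (sim_k − sim_rest_k); linear in the
    simulation displacement, so rigid translations pass through exactly.
    """
    sim_disp = np.asarray(sim_positions, dtype=float) - vessel.sim_mesh.vertices
    tri = vessel.sim_mesh.faces[vessel.mapping_faces]
    interp = np.einsum("nk,nkd->nd", vessel.mapping_weights, sim_disp[tri])
    return vessel.display_mesh.vertices + interp


# ---------------------------------------------------------------------------
# connective-tissue strands
# ---------------------------------------------------------------------------


@dataclass
class StrandGenSpec:
    """Strand generation parameters.

    ``max_distance=None`` selects the automatic rule d_max = |C_A − C_B|
    (distance between the two surfaces' centroids). Defaults follow the
    reference parameterization: σ = 2 strands per face, n = 3 segments per
    strand, 15° normal deviation cone.
    """

    strands_per_face: int = 2
    segments_per_strand: int = 3
    max_distance: float | None = None
    max_angle_deviation: float = np.deg2rad(15.0)
    diameter: float = 1e-3

    def __post_init__(self) -> None:
        if self.strands_per_face < 1:
            raise ValueError("strands_per_face must be >= 1")
        if self.segments_per_strand < 1:
            raise ValueError("segments_per_strand must be >= 1")
        if self.max_distance is not None and self.max_distance <= 0:
            raise ValueError("explicit max_distance must be positive")


@dataclass
class Strand:
    """One strand: its particle indices (ordered A→B) and anchor bookkeeping."""

    particle_ids: list[int]
    face_a: int
    face_b: int
    bary_a: np.ndarray
    bary_b: np.ndarray


@dataclass
class StrandNetwork:
    """Polyline strand network linking surface A (chest-wall side) to surface B."""

    polyline: PolylineMesh
    strands: list[Strand] = field(default_factory=list)
    surface_a: TriangleMesh = None  # type: ignore[assignment]
    surface_b: TriangleMesh = None  # type: ignore[assignment]

    @property
    def n_particles(self) -> int:
        return len(self.polyline.vertices)

    def endpoint_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(A-side endpoint ids, B-side endpoint ids), one per strand."""
        a = np.array([s.particle_ids[0] for s in self.strands], dtype=np.int64)
        b = np.array([s.particle_ids[-1] for s in self.strands], dtype=np.int64)
        return a, b


def generate_strands(surface_a: TriangleMesh, surface_b: TriangleMesh,
                     spec: StrandGenSpec, seed: int) -> StrandNetwork:
    """Grow strands from eligible faces of A to anchor points on B.

    A face of A is eligible when its centroid lies within ``d_max`` of B
    (d_max automatic: distance between the surface centroids). From each
    eligible face, σ origin points are sampled uniformly in barycentric
    coordinates, each strand leaves along the face normal perturbed within the
    deviation cone, anchors where its ray meets B (nearest-point projection as
    fallback) and is subdivided into n equal segments. Fully deterministic for
    a fixed seed.
    """
    rng = np.random.default_rng(seed)
    d_max = spec.max_distance
    if d_max is None:
        d_max = float(np.linalg.norm(surface_a.centroid() - surface_b.centroid()))
    centroids = surface_a.face_centroids()
    normals = surface_a.face_normals()
    b_centroid = surface_b.centroid()
    verts: list[np.ndarray] = []
    segs: list[list[int]] = []
    strands: list[Strand] = []
    n_seg = spec.segments_per_strand
    for fi in range(len(surface_a.faces)):
        dist, _, _ = closest_point_on_mesh(centroids[fi], surface_b)
        if dist > d_max:
            continue
        nrm = normals[fi]
        if nrm @ (b_centroid - centroids[fi]) < 0:
            nrm = -nrm
        a, b, c = surface_a.vertices[surface_a.faces[fi]]
        for _ in range(spec.strands_per_face):
            u, v = rng.random(2)
            if u + v > 1.0:
                u, v = 1.0 - u, 1.0 - v
            bary_a = np.array([1.0 - u - v, u, v])
            origin = bary_a @ np.vstack([a, b, c])
            direction = _cone_sample(nrm, spec.max_angle_deviation, rng)
            hit = ray_mesh_intersect(origin, direction, surface_b)
            if hit is not None:
                _, target, face_b = hit
            else:
                _, target, face_b = closest_point_on_mesh(origin, surface_b)
            ta, tb, tc = surface_b.vertices[surface_b.faces[face_b]]
            bary_b = _barycentric(target, ta, tb, tc)
            base = len(verts)
            for k in range(n_seg + 1):
                verts.append(origin + (target - origin) * (k / n_seg))
            for k in range(n_seg):
                segs.append([base + k, base + k + 1])
            strands.append(Strand(list(range(base, base + n_seg + 1)),
                                  fi, int(face_b), bary_a, bary_b))
    if not strands:
        warnings.warn("no eligible faces within d_max: empty strand network",
                      stacklevel=2)
        poly = PolylineMesh(np.zeros((0, 3)), np.zeros((0, 2), dtype=np.int64),
                            np.zeros(0))
    else:
        poly = PolylineMesh(np.asarray(verts),
                            np.asarray(segs, dtype=np.int64),
                            np.full(len(verts), spec.diameter))
    return StrandNetwork(poly, strands, surface_a, surface_b)


def _cone_sample(axis: np.ndarray, max_angle: float, rng) -> np.ndarray:
    """Random unit vector within ``max_angle`` of ``axis`` (uniform in solid angle)."""
    if max_angle <= 0:
        return axis
    cos_t = 1.0 - rng.random() * (1.0 - np.cos(max_angle))
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.random() * 2 * np.pi
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    return cos_t * axis + sin_t * (np.cos(phi) * u + np.sin(phi) * w)


def attach_strand_constraints(network: StrandNetwork,
                              stiffness: float = 1.0,
                              particle_mass: float = 1e-4,
                              ) -> tuple[ParticleSystem, ConstraintSet]:
    """Particle system + one distance constraint per strand segment.

    Rest lengths equal the initial segment lengths. Strand endpoints are
    kinematic anchor proxies (inverse mass 0) slaved to their host surfaces
    via :func:`update_strand_anchors`; interior particles are dynamic.
    """
    if not network.strands:
        raise ValueError("empty strand network")
    poly = network.polyline
    inv_m = np.full(network.n_particles, 1.0 / particle_mass)
    ends_a, ends_b = network.endpoint_indices()
    inv_m[ends_a] = 0.0
    inv_m[ends_b] = 0.0
    system = ParticleSystem(poly.vertices.copy(), inverse_masses=inv_m)
    cs = ConstraintSet()
    for i, j in map(tuple, poly.segments):
        rest = float(np.linalg.norm(poly.vertices[i] - poly.vertices[j]))
        cs.add_distance(DistanceConstraint(int(i), int(j), rest, stiffness))
    return system, cs


def update_strand_anchors(network: StrandNetwork, system: ParticleSystem,
                          surface_a_positions: np.ndarray,
                          surface_b_positions: np.ndarray) -> None:
    """Move endpoint anchor proxies to follow their host surfaces, in place."""
    fa = network.surface_a.faces
    fb = network.surface_b.faces
    for s in network.strands:
        system.positions[s.particle_ids[0]] = \
            s.bary_a @ surface_a_positions[fa[s.face_a]]
        system.positions[s.particle_ids[-1]] = \
            s.bary_b @ surface_b_positions[fb[s.face_b]]


# ---------------------------------------------------------------------------
# chest-wall support
# ---------------------------------------------------------------------------


def build_support_cylinder(center=(0.0, 0.0, 0.0), axis=(0.0, 1.0, 0.0),
                           radius: float = 0.05, length: float = 0.15,
                           n_circ: int = 12, n_axial: int = 8) -> TriangleMesh:
    """Rigid open cylinder standing in for the thoracic wall (all vertices fixed
    by callers; the mesh itself is plain geometry)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    line = np.asarray(center, dtype=float) + \
        np.linspace(-length / 2, length / 2, n_axial)[:, None] * axis
    return _tube_mesh(line, radius, n_circ)
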