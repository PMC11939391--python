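"""Dissection algorithms: topology-preserving sheet cutting and strand removal.

Sheet (fascia) cutting splits mesh edges crossed by the tool-tip sweep,
duplicates the crossing vertices into left/right seam copies, re-triangulates
the affected faces locally and updates the constraint set by an explicit
add/remove delta. Current and rest positions of new vertices are interpolated
linearly along the split edge, so the rest pose stays exactly on the
constraint manifold (a cut injects no elastic energy). Vertices not touched
by the cut are never moved.

Strand (connective-tissue) cutting marks polyline segments that cross the
tool's cutting plane inside a symmetric ω × ω slot around the tool position,
removes their distance constraints, and shrinks orphaned particles by a 0.96
per-step diameter decay until they drop below the 6×10⁻⁴ visibility
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .anatomy import StrandNetwork
from .mesh_core import TriangleMesh, point_to_segment
from .pbd import (
    ConstraintSet,
    DihedralConstraint,
    DistanceConstraint,
    ParticleSystem,
)
from ._kernels import dihedral_angle_k

DIAMETER_DECAY = 0.96
VISIBILITY_THRESHOLD = 6e-4

__all__ = [
    "CutGeometry",
    "CutPlane",
    "TopologyDelta",
    "find_cut_vertices",
    "cut_fascia",
    "tool_frame",
    "mark_segments_for_removal",
    "remove_segments",
    "decay_diameters",
    "mesh_components",
    "DIAMETER_DECAY",
    "VISIBILITY_THRESHOLD",
]


@dataclass
class CutGeometry:
    """Tool-tip sweep between frames: a 3D segment plus proximity threshold ε."""

    start: np.ndarray
    end: np.ndarray
    epsilon: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        self.end = np.asarray(self.end, dtype=float).reshape(3)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class CutPlane:
    """Tool cutting plane: origin p, orthonormal triad (n, l, f), slot width ω_c."""

    origin: np.ndarray
    normal: np.ndarray
    lateral: np.ndarray
    forward: np.ndarray
    width: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        triad = np.column_stack([np.asarray(v, dtype=float).reshape(3)
                                 for v in (self.normal, self.lateral, self.forward)])
        if not np.allclose(triad.T @ triad, np.eye(3), atol=1e-9):
            raise ValueError("(n, l, f) must be orthonormal within 1e-9")
        if self.width <= 0:
            raise ValueError("cut width must be positive")

    @classmethod
    def from_pose(cls, origin, rotation, width: float) -> "CutPlane":
        n, l, f = tool_frame(rotation)
        return cls(origin, n, l, f, width)


@dataclass
class TopologyDelta:
    """Explicit record of one cutting operation on a mesh + constraint set."""

    removed_constraints: list[int] = field(default_factory=list)
    added_constraints: list[int] = field(default_factory=list)
    added_vertices: list[int] = field(default_factory=list)
    face_replacements: dict[int, list[int]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not (self.removed_constraints or self.added_constraints
                    or self.added_vertices or self.face_replacements)

    def summary(self) -> dict:
        return {"removed_constraints": len(self.removed_constraints),
                "added_constraints": len(self.added_constraints),
                "added_vertices": len(self.added_vertices),
                "replaced_faces": len(self.face_replacements)}


def find_cut_vertices(mesh: TriangleMesh, geom: CutGeometry) -> set[int]:
    """Indices of vertices strictly within ε of the swept tool segment."""
    out = set()
    for vi, v in enumerate(mesh.vertices):
        d, _, _ = point_to_segment(v, geom.start, geom.end)
        if d < geom.epsilon:
            out.add(vi)
    return out


def mesh_components(mesh: TriangleMesh) -> int:
    """Number of connected components of the mesh's vertex–edge graph."""
    n = len(mesh.vertices)
    e = mesh.edges()
    if not len(e):
        return n
    m = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
    ncomp, _ = connected_components(m, directed=False)
    return int(ncomp)


# ---------------------------------------------------------------------------
# sheet cutting
# ---------------------------------------------------------------------------


def _interior_edge_wings(mesh: TriangleMesh) -> dict[tuple[int, int], tuple[int, int]]:
    """Map interior edge -> (wing vertex of face 1, wing vertex of face 2)."""
    wings: dict[tuple[int, int], tuple[int, int]] = {}
    for (i, j), fs in mesh.edge_face_incidence().items():
        if len(fs) == 2:
            w = tuple(int(next(v for v in mesh.faces[fi] if v not in (i, j)))
                      for fi in fs)
            wings[(i, j)] = w  # type: ignore[assignment]
    return wings


def cut_fascia(mesh: TriangleMesh, system: ParticleSystem,
               constraints: ConstraintSet, geom: CutGeometry,
               ) -> tuple[TriangleMesh, ParticleSystem, TopologyDelta]:
    """Cut the sheet along the swept tool segment.

    Edges whose endpoints straddle the cut line (within the sweep's axial
    extent and within ε of the sheet plane) are split at the crossing point.
    A crossing vertex is duplicated into left/right copies when every face
    around its edge is fully traversed by the cut; the crack-tip crossing is
    kept single so a partial cut stays one connected component. The returned
    delta lists removed/added constraints, new vertices and face
    replacements; ``constraints`` is updated in place.
    """
    inc = mesh.edge_face_incidence()
    if any(len(fs) > 2 for fs in inc.values()):
        raise ValueError("non-manifold input mesh")

    u = geom.end - geom.start
    length = np.linalg.norm(u)
    if length < 1e-12:
        return mesh, system, TopologyDelta()
    u = u / length

    # local sheet normal from faces near the sweep
    cents = mesh.face_centroids()
    near = np.array([point_to_segment(c, geom.start, geom.end)[0] for c in cents])
    sel = near < max(geom.epsilon * 4, near.min() + 1e-12)
    n_avg = mesh.face_normals()[sel].mean(axis=0)
    n_avg -= (n_avg @ u) * u
    mag = np.linalg.norm(n_avg)
    if mag < 1e-12:
        return mesh, system, TopologyDelta()
    n_avg /= mag
    m_side = np.cross(u, n_avg)

    side = (mesh.vertices - geom.start) @ m_side
    crossings: dict[tuple[int, int], tuple[float, np.ndarray]] = {}
    for (i, j) in map(tuple, mesh.edges()):
        si, sj = side[i], side[j]
        if si * sj >= 0:
            continue
        t = si / (si - sj)
        q = mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i])
        axial = (q - geom.start) @ u
        out_of_plane = abs((q - geom.start) @ n_avg)
        if -1e-12 <= axial <= length + 1e-12 and out_of_plane <= geom.epsilon:
            crossings[(i, j)] = (t, q)
    if not crossings:
        return mesh, system, TopologyDelta()

    # faces by number of crossed edges
    face_cuts: dict[int, list[tuple[int, int]]] = {}
    for e in crossings:
        for fi in inc[e]:
            face_cuts.setdefault(fi, []).append(e)

    # a crossing is duplicated iff every adjacent face has exactly 2 crossed edges
    duplicated = {e: all(len(face_cuts[fi]) == 2 for fi in inc[e])
                  for e in crossings}

    verts = [mesh.vertices.copy()]
    rest = [system.rest_positions.copy()]
    vel = [system.velocities.copy()]
    invm = [system.inverse_masses.copy()]
    next_idx = len(mesh.vertices)
    delta = TopologyDelta()

    def _new_vertex(e: tuple[int, int], t: float) -> int:
        nonlocal next_idx
        i, j = e
        verts.append((mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i]))
                     .reshape(1, 3))
        rest.append((system.rest_positions[i]
                     + t * (system.rest_positions[j] - system.rest_positions[i]))
                    .reshape(1, 3))
        vel.append((system.velocities[i]
                    + t * (system.velocities[j] - system.velocities[i])).reshape(1, 3))
        invm.append(np.array([(system.inverse_masses[i] + system.inverse_masses[j])
                              / 2.0]))
        idx = next_idx
        next_idx += 1
        delta.added_vertices.append(idx)
        return idx

    # seam copies: per crossed edge, a vertex id per side (+1 / -1); crack-tip
    # crossings share one id for both sides
    copies: dict[tuple[int, int], dict[int, int]] = {}
    for e, (t, _) in crossings.items():
        if duplicated[e]:
            copies[e] = {+1: _new_vertex(e, t), -1: _new_vertex(e, t)}
        else:
            single = _new_vertex(e, t)
            copies[e] = {+1: single, -1: single}

    def _side_of(v: int) -> int:
        return 1 if side[v] >= 0 else -1

    new_faces: list[list[int]] = []
    replaced: dict[int, list[int]] = {}
    for fi, (a, b, c) in enumerate(mesh.faces):
        cuts = face_cuts.get(fi, [])
        if not cuts:
            new_faces.append([a, b, c])
            continue
        tri = [int(a), int(b), int(c)]
        keys = [tuple(sorted((tri[k], tri[(k + 1) % 3]))) for k in range(3)]
        cut_local = [k for k in range(3) if keys[k] in crossings]
        start = len(new_faces)
        if len(cut_local) == 1:
            k = cut_local[0]
            va, vb = tri[k], tri[(k + 1) % 3]
            vc = tri[(k + 2) % 3]
            q = copies[keys[k]]
            new_faces.append([va, q[_side_of(va)], vc])
            new_faces.append([q[_side_of(vb)], vb, vc])
        else:
            # apex = vertex shared by the two crossed edges
            edges = [keys[k] for k in cut_local]
            apex = int((set(edges[0]) & set(edges[1])).pop())
            ai = tri.index(apex)
            vb, vc = tri[(ai + 1) % 3], tri[(ai + 2) % 3]
            e_ab = tuple(sorted((apex, vb)))
            e_ca = tuple(sorted((vc, apex)))
            q_ab = copies[e_ab]
            q_ca = copies[e_ca]
            s_apex = _side_of(apex)
            s_other = -s_apex
            new_faces.append([apex, q_ab[s_apex], q_ca[s_apex]])
            new_faces.append([q_ab[s_other], vb, vc])
            new_faces.append([q_ab[s_other], vc, q_ca[s_other]])
        replaced[fi] = list(range(start, len(new_faces)))
    delta.face_replacements = replaced

    new_mesh = TriangleMesh(np.vstack(verts), np.asarray(new_faces, dtype=np.int64))
    new_system = ParticleSystem(np.vstack(verts), np.vstack(vel),
                                np.concatenate(invm), np.vstack(rest))

    # constraint delta: distance constraints follow the edge set, dihedral
    # constraints follow the interior-edge wing map; rest values come from the
    # rest configuration so the cut injects no elastic energy
    old_edges = {tuple(e) for e in map(tuple, mesh.edges())}
    new_edges = {tuple(e) for e in map(tuple, new_mesh.edges())}
    dist_stiff = (next(iter(constraints.distance.values())).stiffness
                  if constraints.distance else 1.0)
    dih_stiff = (next(iter(constraints.dihedral.values())).stiffness
                 if constraints.dihedral else 0.5)
    for e in sorted(old_edges - new_edges):
        cid = constraints.distance_id_for_edge(*e)
        if cid is not None:
            constraints.remove(cid)
            delta.removed_constraints.append(cid)
    rest_pos = new_system.rest_positions
    for (i, j) in sorted(new_edges - old_edges):
        d0 = float(np.linalg.norm(rest_pos[i] - rest_pos[j]))
        cid = constraints.add_distance(DistanceConstraint(i, j, d0, dist_stiff))
        delta.added_constraints.append(cid)

    new_wings = _interior_edge_wings(new_mesh)
    for cid, c in list(constraints.dihedral.items()):
        key = (min(c.p2, c.p3), max(c.p2, c.p3))
        w = new_wings.get(key)
        if w is None or set(w) != {c.p0, c.p1}:
            constraints.remove(cid)
            delta.removed_constraints.append(cid)
    existing = {(min(c.p2, c.p3), max(c.p2, c.p3), frozenset((c.p0, c.p1)))
                for c in constraints.dihedral.values()}
    for (i, j), (w0, w1) in new_wings.items():
        if (i, j, frozenset((w0, w1))) in existing:
            continue
        theta = dihedral_angle_k(rest_pos[w0], rest_pos[w1], rest_pos[i],
                                 rest_pos[j])
        if np.isnan(theta):
            continue
        cid = constraints.add_dihedral(
            DihedralConstraint(w0, w1, i, j, float(theta), dih_stiff))
        delta.added_constraints.append(cid)
    return new_mesh, new_system, delta


# ---------------------------------------------------------------------------
# tool frame and strand cutting
# ---------------------------------------------------------------------------


def tool_frame(rotation: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal triad of the tool: n = R·ŷ, l = R·x̂, f = R·ẑ."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9) \
            or abs(np.linalg.det(R) - 1.0) > 1e-9:
        raise ValueError("rotation must be in SO(3)")
    return R @ np.array([0.0, 1.0, 0.0]), R @ np.array([1.0, 0.0, 0.0]), \
        R @ np.array([0.0, 0.0, 1.0])


def mark_segments_for_removal(network: StrandNetwork | np.ndarray,
                              plane: CutPlane,
                              segments: np.ndarray | None = None) -> set[int]:
    """Segments that cross the cutting plane inside the ω × ω slot.

    A segment is marked iff it crosses n·(x − p) = 0 at a point with
    |l·(x − p)| < ω/2 and |f·(x − p)| < ω/2 (both width tests symmetric).
    Accepts either a StrandNetwork or raw (vertices, segments) arrays.
    """
    if isinstance(network, StrandNetwork):
        verts = network.polyline.vertices
        segs = network.polyline.segments
    else:
        verts = np.asarray(network, dtype=float)
        segs = np.asarray(segments, dtype=np.int64)
    p, n, l, f = plane.origin, plane.normal, plane.lateral, plane.forward
    half = plane.width / 2.0
    marked = set()
    for si, (i, j) in enumerate(segs):
        x0, x1 = verts[i] - p, verts[j] - p
        s0, s1 = x0 @ n, x1 @ n
        if abs(s0) < 1e-15 and abs(s1) < 1e-15:
            # segment lies in the plane: test both endpoints against the slot
            for x in (x0, x1):
                if abs(x @ l) < half and abs(x @ f) < half:
                    marked.add(si)
                    break
            continue
        if s0 * s1 > 0:
            continue
        t = s0 / (s0 - s1)
        x = x0 + t * (x1 - x0)
        if abs(x @ l) < half and abs(x @ f) < half:
            marked.add(si)
    return marked


def remove_segments(network: StrandNetwork, marked: set[int],
                    constraints: ConstraintSet | None = None,
                    ) -> tuple[list[int], list[int]]:
    """Remove marked segments in place; returns (removed constraint ids,
    newly orphaned particle ids).

    The corresponding distance constraints are removed from ``constraints``
    (matched by particle pair). Particles left in no surviving segment enter
    the diameter-decay schedule. Strand bookkeeping is updated so a strand
    whose interior segment is removed splits into independent runs.
    """
    poly = network.polyline
    marked = {s for s in marked if 0 <= s < len(poly.segments)}
    removed_ids: list[int] = []
    if not marked:
        return removed_ids, []
    keep = np.ones(len(poly.segments), dtype=bool)
    for si in marked:
        keep[si] = False
        if constraints is not None:
            i, j = map(int, poly.segments[si])
            cid = constraints.distance_id_for_edge(i, j)
            if cid is not None:
                constraints.remove(cid)
                removed_ids.append(cid)
    removed_particles = set(poly.segments[~keep].ravel().tolist())
    poly.segments = poly.segments[keep]
    surviving = set(poly.segments.ravel().tolist())
    orphans = sorted(int(pid) for pid in removed_particles - surviving)
    if not hasattr(network, "decaying"):
        network.decaying = set()  # type: ignore[attr-defined]
    network.decaying.update(orphans)  # type: ignore[attr-defined]
    # split strand runs at removed segments
    seg_set = {tuple(sorted(s)) for s in map(tuple, poly.segments)}
    new_strands = []
    for s in network.strands:
        run = [s.particle_ids[0]]
        runs = []
        for a, b in zip(s.particle_ids[:-1], s.particle_ids[1:]):
            if tuple(sorted((a, b))) in seg_set:
                run.append(b)
            else:
                if len(run) > 1:
                    runs.append(run)
                run = [b]
        if len(run) > 1:
            runs.append(run)
        for k, r in enumerate(runs):
            new_strands.append(type(s)(r, s.face_a, s.face_b, s.bary_a, s.bary_b))
        if not runs:
            continue
    network.strands = new_strands
    return removed_ids, orphans


def decay_diameters(network: StrandNetwork, steps: int = 1) -> None:
    """Apply d ← 0.96·d per step to decaying particles; hide below 6×10⁻⁴ m."""
    decaying = sorted(getattr(network, "decaying", set()))
    if not decaying:
        return
    idx = np.asarray(decaying, dtype=np.int64)
    poly = network.polyline
    for _ in range(steps):
        poly.per_vertex_diameter[idx] *= DIAMETER_DECAY
    poly.visible[idx] &= poly.per_vertex_diameter[idx] >= VISIBILITY_THRESHOLD
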