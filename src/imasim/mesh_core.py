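"""Mesh and polyline containers, ASCII OBJ/PLY I/O, and shared geometry utilities.

All coordinates are metres in a single right-handed world frame with Z up.
Vertex indexing is 0-based everywhere in memory; OBJ's 1-based indices are
converted at the I/O boundary.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriangleMesh",
    "PolylineMesh",
    "RigidTransform",
    "MeshParseError",
    "load_mesh",
    "save_mesh",
    "load_polyline_csv",
    "save_polyline_csv",
    "signed_plane_distance",
    "point_to_segment",
    "point_to_polyline_distance",
    "closest_point_on_triangle",
    "closest_point_on_mesh",
    "ray_triangle_intersect",
    "ray_mesh_intersect",
]


class MeshParseError(ValueError):
    """Raised when a mesh file is malformed; the message names the offending line."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Triangle surface mesh: vertex positions (N, 3) and face index triples (M, 3).

    ``boundary_vertex_flags`` marks vertices incident to an edge that belongs to
    exactly one face (computed on construction, recomputed via
    :meth:`recompute_boundary`).
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary_vertex_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.validate()
        if self.boundary_vertex_flags is None:
            self.recompute_boundary()

    def validate(self) -> None:
        n = len(self.vertices)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ValueError("face index out of range")
            a, b, c = self.faces.T
            if np.any(a == b) or np.any(b == c) or np.any(a == c):
                raise ValueError("degenerate face: repeated vertex index")

    # -- topology helpers --------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) int array."""
        if not self.faces.size:
            return np.empty((0, 2), dtype=np.int64)
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                       self.faces[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def edge_face_incidence(self) -> dict[tuple[int, int], list[int]]:
        """Map sorted edge -> list of face indices containing it."""
        inc: dict[tuple[int, int], list[int]] = {}
        for fi, (a, b, c) in enumerate(self.faces):
            for u, v in ((a, b), (b, c), (c, a)):
                key = (int(min(u, v)), int(max(u, v)))
                inc.setdefault(key, []).append(fi)
        return inc

    def recompute_boundary(self) -> None:
        flags = np.zeros(len(self.vertices), dtype=bool)
        for (u, v), fs in self.edge_face_incidence().items():
            if len(fs) == 1:
                flags[u] = flags[v] = True
        self.boundary_vertex_flags = flags

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            mag = np.linalg.norm(n, axis=1, keepdims=True)
            mag[mag == 0] = 1.0
            n = n / mag
        return n

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            self.boundary_vertex_flags.copy())


@dataclass
class PolylineMesh:
    """Polyline set: vertices (N, 3), segment index pairs (S, 2), per-vertex diameter.

    Diameters must be positive unless the vertex is flagged invisible (used by
    the post-dissection decay schedule).
    """

    vertices: np.ndarray
    segments: np.ndarray
    per_vertex_diameter: np.ndarray = field(default=None)  # type: ignore[assignment]
    visible: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.segments = np.asarray(self.segments, dtype=np.int64).reshape(-1, 2)
        n = len(self.vertices)
        if self.per_vertex_diameter is None:
            self.per_vertex_diameter = np.full(n, 1e-3)
        self.per_vertex_diameter = np.asarray(self.per_vertex_diameter, dtype=float)
        if self.visible is None:
            self.visible = np.ones(n, dtype=bool)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.segments.size and (self.segments.min() < 0 or self.segments.max() >= n):
            raise ValueError("segment index out of range")
        bad = (self.per_vertex_diameter <= 0) & self.visible
        if np.any(bad):
            raise ValueError(
                f"non-positive diameter on visible vertex {int(np.flatnonzero(bad)[0])}")

    def copy(self) -> "PolylineMesh":
        return PolylineMesh(self.vertices.copy(), self.segments.copy(),
                            self.per_vertex_diameter.copy(), self.visible.copy())


class RigidTransform:
    """Rotation (3x3, det +1) plus translation; an element of SE(3)."""

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation=None, translation=None):
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal (R R^T != I within 1e-9)")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant is not +1 within 1e-9")
        self.rotation = R
        self.translation = t.reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_quaternion(cls, qw, qx, qy, qz, translation=None) -> "RigidTransform":
        from scipy.spatial.transform import Rotation as _R
        return cls(_R.from_quat([qx, qy, qz, qw]).as_matrix(), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


# ---------------------------------------------------------------------------
# file I/O (ASCII OBJ / PLY; CSV polylines)
# ---------------------------------------------------------------------------


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("obj", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}; use 'obj' or 'ply'")
    return fmt


def load_mesh(path, format: str | None = None) -> TriangleMesh:
    """Load an ASCII OBJ or PLY triangle mesh, preserving file vertex order.

    Non-triangular faces are an explicit error (no silent triangulation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "obj":
        return _load_obj(path)
    return _load_ply(path)


def _load_obj(path: Path) -> TriangleMesh:
    verts: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            tag = tokens[0]
            if tag == "v":
                if len(tokens) < 4:
                    raise MeshParseError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    verts.append([float(t) for t in tokens[1:4]])
                except ValueError as exc:
                    raise MeshParseError(f"{path}:{lineno}: bad vertex: {exc}") from None
            elif tag == "f":
                idx = []
                for tok in tokens[1:]:
                    try:
                        idx.append(int(tok.split("/")[0]))
                    except ValueError:
                        raise MeshParseError(
                            f"{path}:{lineno}: bad face index {tok!r}") from None
                if len(idx) != 3:
                    raise MeshParseError(
                        f"{path}:{lineno}: non-triangular face with {len(idx)} "
                        "vertices (triangles required; no implicit triangulation)")
                # OBJ is 1-based; negative indices count from the end
                idx = [i - 1 if i > 0 else len(verts) + i for i in idx]
                faces.append(idx)
    return TriangleMesh(np.asarray(verts, dtype=float).reshape(-1, 3),
                        np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def _load_ply(path: Path) -> TriangleMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise MeshParseError(f"{path}:1: missing 'ply' magic")
    n_vert = n_face = None
    i = 1
    order: list[tuple[str, int]] = []
    while i < len(lines):
        tokens = lines[i].split()
        if not tokens:
            i += 1
            continue
        if tokens[0] == "format":
            if tokens[1] != "ascii":
                raise MeshParseError(f"{path}:{i + 1}: only ASCII PLY is supported")
        elif tokens[0] == "element":
            count = int(tokens[2])
            order.append((tokens[1], count))
            if tokens[1] == "vertex":
                n_vert = count
            elif tokens[1] == "face":
                n_face = count
        elif tokens[0] == "end_header":
            i += 1
            break
        i += 1
    else:
        raise MeshParseError(f"{path}: header never ends (no 'end_header')")
    if n_vert is None or n_face is None:
        raise MeshParseError(f"{path}: header lacks vertex or face element")
    verts = []
    for k in range(n_vert):
        lineno = i + k + 1
        try:
            verts.append([float(t) for t in lines[i + k].split()[:3]])
        except (ValueError, IndexError):
            raise MeshParseError(f"{path}:{lineno}: bad vertex line") from None
    i += n_vert
    faces = []
    for k in range(n_face):
        lineno = i + k + 1
        tokens = lines[i + k].split()
        try:
            cnt = int(tokens[0])
            idx = [int(t) for t in tokens[1:1 + cnt]]
        except (ValueError, IndexError):
            raise MeshParseError(f"{path}:{lineno}: bad face line") from None
        if cnt != 3 or len(idx) != 3:
            raise MeshParseError(
                f"{path}:{lineno}: non-triangular face with {cnt} vertices")
        faces.append(idx)
    return TriangleMesh(np.asarray(verts, dtype=float).reshape(-1, 3),
                        np.asarray(faces, dtype=np.int64).reshape(-1, 3))


def save_mesh(mesh: TriangleMesh, path, format: str | None = None) -> None:
    """Write an ASCII OBJ or PLY file (full float precision, round-trip safe)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    with open(path, "w") as fh:
        if fmt == "obj":
            for v in mesh.vertices:
                fh.write(f"v {float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        else:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(mesh.vertices)}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {len(mesh.faces)}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def save_polyline_csv(poly: PolylineMesh, vertex_path, segment_path) -> None:
    """Write a polyline as paired CSVs: vertices (id, x, y, z, diameter) + segments."""
    with open(vertex_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertex_id", "x", "y", "z", "diameter"])
        for i, (v, d) in enumerate(zip(poly.vertices, poly.per_vertex_diameter)):
            w.writerow([i, repr(float(v[0])), repr(float(v[1])), repr(float(v[2])),
                        repr(float(d))])
    with open(segment_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["v0", "v1"])
        for a, b in poly.segments:
            w.writerow([int(a), int(b)])


def load_polyline_csv(vertex_path, segment_path) -> PolylineMesh:
    verts, diams = [], []
    with open(vertex_path, newline="") as fh:
        for row in csv.DictReader(fh):
            verts.append([float(row["x"]), float(row["y"]), float(row["z"])])
            diams.append(float(row["diameter"]))
    segs = []
    with open(segment_path, newline="") as fh:
        for row in csv.DictReader(fh):
            segs.append([int(row["v0"]), int(row["v1"])])
    return PolylineMesh(np.asarray(verts), np.asarray(segs, dtype=np.int64).reshape(-1, 2),
                        np.asarray(diams))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def signed_plane_distance(point, plane_point, plane_normal) -> float:
    """Signed distance n·(x − p) of a point from the plane through ``plane_point``
    with unit normal ``plane_normal``; positive on the normal side."""
    n = np.asarray(plane_normal, dtype=float)
    mag = np.linalg.norm(n)
    if mag < 1e-12:
        raise ValueError("plane normal has zero length")
    if abs(mag - 1.0) > 1e-9:
        raise ValueError("plane normal must be unit length (|n| within 1e-9 of 1)")
    return float(n @ (np.asarray(point, dtype=float) - np.asarray(plane_point, dtype=float)))


def point_to_segment(point, a, b) -> tuple[float, np.ndarray, float]:
    """Distance from ``point`` to segment ``ab``; returns (distance, closest point, t)."""
    p = np.asarray(point, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = ab @ ab
    t = 0.0 if denom == 0.0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    q = a + t * ab
    return float(np.linalg.norm(p - q)), q, t


def point_to_polyline_distance(point, polyline: PolylineMesh,
                               cardiac_side_vector=None,
                               ) -> tuple[float, int, int]:
    """Minimum distance from a point to a polyline, with a side classification.

    Returns ``(distance, nearest_segment_index, side_sign)``. The side sign is
    −1 when the offset from the nearest centerline point has a positive
    component along ``cardiac_side_vector`` (the half-space containing the
    heart) and +1 otherwise. A point exactly on the centerline gets +1 —
    degenerate samples never count against the safe (non-cardiac) side.
    """
    if polyline.segments.size == 0:
        raise ValueError("polyline has no segments")
    best = (np.inf, -1, np.zeros(3))
    for si, (ia, ib) in enumerate(polyline.segments):
        d, q, _ = point_to_segment(point, polyline.vertices[ia], polyline.vertices[ib])
        if d < best[0]:
            best = (d, si, np.asarray(point, dtype=float) - q)
    dist, seg, offset = best
    side = 1
    if cardiac_side_vector is not None:
        s = float(np.asarray(cardiac_side_vector, dtype=float) @ offset)
        if s > 1e-15:
            side = -1
    return float(dist), int(seg), side


def closest_point_on_triangle(p, a, b, c) -> np.ndarray:
    """Closest point on triangle (a, b, c) to p (Ericson, Real-Time Collision
    Detection, §5.1.5)."""
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        return a + (d1 / (d1 - d3)) * ab
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        return a + (d2 / (d2 - d6)) * ac
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        return b + ((d4 - d3) / ((d4 - d3) + (d5 - d6))) * (c - b)
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def closest_point_on_mesh(p, mesh: TriangleMesh) -> tuple[float, np.ndarray, int]:
    """Brute-force nearest point on a triangle mesh: (distance, point, face index)."""
    best_d, best_q, best_f = np.inf, None, -1
    v, f = mesh.vertices, mesh.faces
    for fi in range(len(f)):
        q = closest_point_on_triangle(p, v[f[fi, 0]], v[f[fi, 1]], v[f[fi, 2]])
        d = float(np.linalg.norm(np.asarray(p, dtype=float) - q))
        if d < best_d:
            best_d, best_q, best_f = d, q, fi
    if best_q is None:
        raise ValueError("mesh has no faces")
    return best_d, best_q, best_f


def ray_triangle_intersect(origin, direction, a, b, c, eps: float = 1e-12):
    """Möller–Trumbore ray/triangle test; returns hit parameter t ≥ 0 or None."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    e1 = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    e2 = np.asarray(c, dtype=float) - np.asarray(a, dtype=float)
    h = np.cross(direction, e2)
    det = e1 @ h
    if abs(det) < eps:
        return None
    inv = 1.0 / det
    s = origin - np.asarray(a, dtype=float)
    u = inv * (s @ h)
    if u < -1e-12 or u > 1 + 1e-12:
        return None
    q = np.cross(s, e1)
    v = inv * (direction @ q)
    if v < -1e-12 or u + v > 1 + 1e-12:
        return None
    t = inv * (e2 @ q)
    return float(t) if t >= 0 else None


def ray_mesh_intersect(origin, direction, mesh: TriangleMesh):
    """First hit of a ray against a mesh: (t, point, face index) or None."""
    best = None
    v, f = mesh.vertices, mesh.faces
    for fi in range(len(f)):
        t = ray_triangle_intersect(origin, direction, v[f[fi, 0]], v[f[fi, 1]],
                                   v[f[fi, 2]])
        if t is not None and (best is None or t < best[0]):
            best = (t, fi)
    if best is None:
        return None
    t, fi = best
    return t, np.asarray(origin, dtype=float) + t * np.asarray(direction, dtype=float), fi
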