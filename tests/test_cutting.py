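"""Dissection: sheet cutting topology, plane-based strand removal, decay."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from imasim import anatomy, cutting, pbd
from imasim.anatomy import FasciaSpec, StrandGenSpec, build_fascia, generate_strands
from imasim.cutting import (
    CutGeometry,
    CutPlane,
    cut_fascia,
    decay_diameters,
    find_cut_vertices,
    mark_segments_for_removal,
    mesh_components,
    remove_segments,
    tool_frame,
)


@pytest.fixture()
def sheet():
    return build_fascia(FasciaSpec(width=0.08, height=0.12, resolution=(7, 9),
                                   total_mass=0.05))


class TestFindCutVertices:
    def test_far_geometry_empty(self, sheet):
        mesh, _, _ = sheet
        geom = CutGeometry((1.0, 1.0, 1.0), (1.1, 1.0, 1.0), epsilon=0.001)
        assert find_cut_vertices(mesh, geom) == set()

    def test_single_vertex_within_half_epsilon(self, sheet):
        mesh, _, _ = sheet
        v = mesh.vertices[20]
        geom = CutGeometry(v + [0, 0, 0.001], v + [0.0005, 0, 0.001],
                           epsilon=0.002)
        found = find_cut_vertices(mesh, geom)
        assert 20 in found

    def test_agrees_with_brute_force(self, rng):
        from imasim.mesh_core import TriangleMesh, point_to_segment
        for _ in range(50):
            verts = rng.normal(size=(8, 3))
            mesh = TriangleMesh(verts, np.array([[0, 1, 2], [3, 4, 5]]))
            a, b = rng.normal(size=(2, 3))
            eps = float(rng.uniform(0.1, 2.0))
            got = find_cut_vertices(mesh, CutGeometry(a, b, eps))
            want = {i for i, v in enumerate(verts)
                    if point_to_segment(v, a, b)[0] < eps}
            assert got == want


class TestCutFascia:
    def test_no_intersection_identity(self, sheet):
        mesh, cs, system = sheet
        n0 = len(cs)
        geom = CutGeometry((0.5, 0.5, 0.5), (0.6, 0.5, 0.5), epsilon=0.005)
        nm, ns, delta = cut_fascia(mesh, system, cs, geom)
        assert delta.empty
        assert nm is mesh and len(cs) == n0

    def test_full_cut_two_components(self, sheet):
        mesh, cs, system = sheet
        geom = CutGeometry((-0.01, 0.055, 0.0), (0.09, 0.055, 0.0),
                           epsilon=0.005)
        nm, ns, delta = cut_fascia(mesh, system, cs, geom)
        assert mesh_components(nm) == 2
        # every added crossing is duplicated into two copies
        assert len(delta.added_vertices) % 2 == 0

    def test_partial_cut_single_component_with_seam(self, sheet):
        mesh, cs, system = sheet
        geom = CutGeometry((-0.01, 0.055, 0.0), (0.038, 0.055, 0.0),
                           epsilon=0.005)
        nm, ns, delta = cut_fascia(mesh, system, cs, geom)
        assert mesh_components(nm) == 1
        # interior crossings add 2 vertices each, the crack tip adds 1
        assert len(delta.added_vertices) % 2 == 1
        # no constraint spans the seam: duplicated pairs are never connected
        added = delta.added_vertices
        pairs = {(added[k], added[k + 1]) for k in range(0, len(added) - 1, 2)}
        for c in cs.distance.values():
            assert (c.i, c.j) not in pairs and (c.j, c.i) not in pairs

    def test_uncut_vertices_bitwise_unchanged(self, sheet):
        mesh, cs, system = sheet
        before = system.positions.copy()
        geom = CutGeometry((-0.01, 0.055, 0.0), (0.09, 0.055, 0.0),
                           epsilon=0.005)
        nm, ns, _ = cut_fascia(mesh, system, cs, geom)
        n_old = len(before)
        assert (ns.positions[:n_old] == before).all()

    def test_no_dangling_constraint_indices(self, sheet):
        mesh, cs, system = sheet
        geom = CutGeometry((-0.01, 0.055, 0.0), (0.09, 0.055, 0.0),
                           epsilon=0.005)
        nm, ns, _ = cut_fascia(mesh, system, cs, geom)
        n = len(nm.vertices)
        for c in cs.distance.values():
            assert 0 <= c.i < n and 0 <= c.j < n
        for c in cs.dihedral.values():
            assert all(0 <= k < n for k in c.quad)

    def test_cut_injects_no_elastic_energy(self, sheet):
        mesh, cs, system = sheet
        geom = CutGeometry((-0.01, 0.055, 0.0), (0.09, 0.055, 0.0),
                           epsilon=0.005)
        _, ns, _ = cut_fascia(mesh, system, cs, geom)
        rest = pbd.ParticleSystem(ns.rest_positions.copy())
        assert np.nanmax(pbd.constraint_residuals(rest, cs)) < 1e-9

    def test_components_have_disk_topology(self, sheet):
        mesh, cs, system = sheet
        geom = CutGeometry((-0.01, 0.055, 0.0), (0.09, 0.055, 0.0),
                           epsilon=0.005)
        nm, _, _ = cut_fascia(mesh, system, cs, geom)
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components
        e = nm.edges()
        n = len(nm.vertices)
        g = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n))
        nc, labels = connected_components(g, directed=False)
        assert nc == 2
        for comp in range(nc):
            vset = set(np.flatnonzero(labels == comp).tolist())
            E = sum(1 for a, b in e if a in vset)
            F = sum(1 for f in nm.faces if int(f[0]) in vset)
            assert len(vset) - E + F == 1  # V - E + F = 1 per disk component


class TestToolFrame:
    def test_identity(self):
        n, l, f = tool_frame(np.eye(3))
        np.testing.assert_array_equal(n, [0, 1, 0])
        np.testing.assert_array_equal(l, [1, 0, 0])
        np.testing.assert_array_equal(f, [0, 0, 1])

    def test_z_rotation_matches_matrix_multiply(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        n, l, f = tool_frame(R)
        np.testing.assert_allclose(n, [-1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(l, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(f, [0, 0, 1], atol=1e-12)

    def test_random_rotations_orthonormal_right_handed(self):
        # (l, n, f) = (R x̂, R ŷ, R ẑ) is the right-handed frame; the printed
        # (n, l, f) ordering swaps the first two axes
        for k in range(10):
            R = Rotation.random(random_state=k).as_matrix()
            n, l, f = tool_frame(R)
            triad = np.column_stack([l, n, f])
            np.testing.assert_allclose(triad.T @ triad, np.eye(3), atol=1e-9)
            assert np.linalg.det(triad) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            tool_frame(np.diag([1.0, 1.0, -1.0]))


class TestMarkSegments:
    def _plane(self, width=0.01):
        return CutPlane((0, 0, 0), (0, 1, 0), (1, 0, 0), (0, 0, 1), width)

    def test_one_sided_segment_not_marked(self):
        verts = np.array([[0.0, 0.1, 0], [0.0, 0.5, 0]])
        assert mark_segments_for_removal(verts, self._plane(),
                                         np.array([[0, 1]])) == set()

    def test_crossing_at_origin_marked(self):
        verts = np.array([[0.0, -0.1, 0], [0.0, 0.1, 0]])
        assert mark_segments_for_removal(verts, self._plane(),
                                         np.array([[0, 1]])) == {0}

    def test_crossing_outside_slot_not_marked(self):
        verts = np.array([[0.02, -0.1, 0], [0.02, 0.1, 0]])
        assert mark_segments_for_removal(verts, self._plane(0.01),
                                         np.array([[0, 1]])) == set()

    def test_matches_dense_sampling_oracle(self, rng):
        plane = self._plane(width=0.4)
        p, n, l, f = plane.origin, plane.normal, plane.lateral, plane.forward
        verts = rng.normal(scale=0.5, size=(400, 3))
        segs = np.arange(400).reshape(200, 2)
        got = mark_segments_for_removal(verts, plane, segs)
        want = set()
        ts = np.linspace(0, 1, 10_001)[:, None]
        for si, (i, j) in enumerate(segs):
            pts = verts[i] * (1 - ts) + verts[j] * ts - p
            s = pts @ n
            slot = (np.abs(pts @ l) < 0.2) & (np.abs(pts @ f) < 0.2)
            # crossings show as sign changes between consecutive samples;
            # the slot test is taken at the sample nearest the plane
            flips = s[:-1] * s[1:] < 0
            near = np.where(np.abs(s[:-1]) < np.abs(s[1:]), slot[:-1], slot[1:])
            if np.any(((s == 0) & slot)) or np.any(flips & near):
                want.add(si)
        assert got == want

    def test_invariant_under_endpoint_swap(self, rng):
        plane = self._plane(width=0.3)
        verts = rng.normal(scale=0.5, size=(100, 3))
        segs = np.arange(100).reshape(50, 2)
        got = mark_segments_for_removal(verts, plane, segs)
        swapped = mark_segments_for_removal(verts, plane, segs[:, ::-1])
        assert got == swapped


class TestRemoveAndDecay:
    def _network(self, parallel_squares):
        a, b = parallel_squares
        return generate_strands(a, b, StrandGenSpec(max_distance=2.0,
                                                    segments_per_strand=3),
                                seed=6)

    def test_empty_marked_is_identity(self, parallel_squares):
        net = self._network(parallel_squares)
        n_seg = len(net.polyline.segments)
        removed, orphans = remove_segments(net, set())
        assert removed == [] and orphans == []
        assert len(net.polyline.segments) == n_seg

    def test_middle_segment_splits_strand(self, parallel_squares):
        net = self._network(parallel_squares)
        s0 = net.strands[0]
        # the middle segment of strand 0 is its second segment
        mid = None
        pids = s0.particle_ids
        for si, (i, j) in enumerate(net.polyline.segments):
            if {i, j} == {pids[1], pids[2]}:
                mid = si
                break
        n_strands0 = len(net.strands)
        remove_segments(net, {mid})
        assert len(net.strands) == n_strands0 + 1
        runs = [s.particle_ids for s in net.strands
                if set(s.particle_ids) <= set(pids)]
        assert sorted(map(len, runs)) == [2, 2]  # two 1-segment runs

    def test_constraint_count_decreases_by_marked(self, parallel_squares):
        net = self._network(parallel_squares)
        system, cs = anatomy.attach_strand_constraints(net)
        n0 = len(cs.distance)
        marked = {0, 2, 5}
        removed, _ = remove_segments(net, marked, cs)
        assert len(removed) == len(marked)
        assert len(cs.distance) == n0 - len(marked)

    def test_decay_arithmetic_single_step(self, parallel_squares):
        net = self._network(parallel_squares)
        pid = net.strands[0].particle_ids[1]
        net.polyline.per_vertex_diameter[:] = 1e-3
        # orphan the particle by removing both its segments
        segs = [si for si, (i, j) in enumerate(net.polyline.segments)
                if pid in (i, j)]
        remove_segments(net, set(segs))
        decay_diameters(net, steps=1)
        assert net.polyline.per_vertex_diameter[pid] == pytest.approx(9.6e-4)

    def test_invisible_after_13_steps_from_1mm(self, parallel_squares):
        net = self._network(parallel_squares)
        pid = net.strands[0].particle_ids[1]
        net.polyline.per_vertex_diameter[:] = 1e-3
        segs = [si for si, (i, j) in enumerate(net.polyline.segments)
                if pid in (i, j)]
        remove_segments(net, set(segs))
        for k in range(1, 20):
            decay_diameters(net, steps=1)
            if not net.polyline.visible[pid]:
                break
        assert k == 13

    def test_below_threshold_invisible_immediately(self, parallel_squares):
        net = self._network(parallel_squares)
        pid = net.strands[0].particle_ids[1]
        net.polyline.per_vertex_diameter[pid] = 5e-4
        segs = [si for si, (i, j) in enumerate(net.polyline.segments)
                if pid in (i, j)]
        remove_segments(net, set(segs))
        decay_diameters(net, steps=1)
        assert not net.polyline.visible[pid]

    def test_non_orphaned_particles_do_not_decay(self, parallel_squares):
        net = self._network(parallel_squares)
        s0 = net.strands[0]
        pids = s0.particle_ids
        mid = next(si for si, (i, j) in enumerate(net.polyline.segments)
                   if {i, j} == {pids[1], pids[2]})
        net.polyline.per_vertex_diameter[:] = 1e-3
        remove_segments(net, {mid})
        decay_diameters(net, steps=5)
        # pids[1] and pids[2] still belong to surviving 1-segment runs
        assert net.polyline.per_vertex_diameter[pids[1]] == pytest.approx(1e-3)
        assert net.polyline.per_vertex_diameter[pids[2]] == pytest.approx(1e-3)
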