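"""Procedural tissue construction: fascia grid, vessel tube, strand network."""

import warnings

import numpy as np
import pytest

from imasim import anatomy, pbd
from imasim.anatomy import (
    FasciaSpec,
    StrandGenSpec,
    assign_uniform_mass,
    attach_strand_constraints,
    build_fascia,
    build_support_cylinder,
    build_vessel,
    generate_strands,
    interpolate_display,
    update_strand_anchors,
)


class TestFascia:
    def test_2x2_counts_by_hand(self):
        # 2x2 grid, one diagonal: 4 vertices, 2 faces, 5 edges, 1 interior edge
        mesh, cs, _ = build_fascia(FasciaSpec(width=0.1, height=0.1,
                                              resolution=(2, 2), total_mass=1.0))
        assert len(mesh.vertices) == 4
        assert len(mesh.faces) == 2
        assert len(cs.distance) == 5
        assert len(cs.dihedral) == 1

    def test_3x3_perimeter_fixed(self):
        _, _, system = build_fascia(FasciaSpec(resolution=(3, 3)))
        assert (system.inverse_masses == 0).sum() == 8
        assert (system.inverse_masses > 0).sum() == 1

    def test_uniform_mass_distribution(self):
        mesh, _, system = build_fascia(FasciaSpec(resolution=(3, 3),
                                                  total_mass=1.0))
        free = system.inverse_masses > 0
        np.testing.assert_allclose(1.0 / system.inverse_masses[free], 1.0 / 9)

    @pytest.mark.parametrize("nx,ny", [(4, 5), (6, 3)])
    def test_constraint_counts_closed_form(self, nx, ny):
        # structured grid with one diagonal per cell:
        #   edges = nx(ny-1) + ny(nx-1) + (nx-1)(ny-1)
        #   interior edges = edges - perimeter edges
        mesh, cs, _ = build_fascia(FasciaSpec(resolution=(nx, ny)))
        cells = (nx - 1) * (ny - 1)
        n_edges = nx * (ny - 1) + ny * (nx - 1) + cells
        assert len(cs.distance) == n_edges
        perimeter = 2 * (nx - 1) + 2 * (ny - 1)
        assert len(cs.dihedral) == n_edges - perimeter

    def test_rest_pose_satisfies_all_constraints(self):
        _, cs, system = build_fascia(FasciaSpec(resolution=(5, 4)))
        res = pbd.constraint_residuals(system, cs)
        assert np.nanmax(res) < 1e-12


class TestUniformMass:
    @pytest.mark.parametrize("m,nv,expected", [(1.0, 100, 0.01), (0.5, 3, 0.5 / 3)])
    def test_examples(self, m, nv, expected, rng):
        from imasim.mesh_core import TriangleMesh
        mesh = TriangleMesh(rng.normal(size=(nv, 3)), np.array([[0, 1, 2]]))
        masses = assign_uniform_mass(mesh, m)
        assert masses[0] == pytest.approx(expected)
        assert masses.sum() == pytest.approx(m, abs=1e-12)

    def test_sum_property_random_sizes(self, rng):
        from imasim.mesh_core import TriangleMesh
        for _ in range(10):
            nv = int(rng.integers(3, 10_000))
            mesh = TriangleMesh(rng.normal(size=(nv, 3)), np.array([[0, 1, 2]]))
            m = float(rng.uniform(0.01, 10))
            assert assign_uniform_mass(mesh, m).sum() == pytest.approx(
                m, abs=1e-12 * max(1, m))

    def test_non_positive_mass_rejected(self):
        from imasim.mesh_core import TriangleMesh
        mesh = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(ValueError):
            assign_uniform_mass(mesh, 0.0)


class TestVessel:
    def _straight(self, n=6):
        return np.column_stack([np.zeros(n), np.linspace(0, 0.1, n), np.zeros(n)])

    def test_equal_resolution_mapping_is_identity_like(self):
        v = build_vessel(self._straight(), 0.002, sim_segments=8,
                         display_segments=8)
        # every display vertex coincides with a sim vertex: one weight ~1
        assert np.isclose(v.mapping_weights.max(axis=1), 1.0, atol=1e-9).all()

    def test_weights_are_barycentric(self):
        v = build_vessel(self._straight(), 0.002, 6, 12)
        assert (v.mapping_weights >= -1e-12).all()
        np.testing.assert_allclose(v.mapping_weights.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_rigid_translation_passes_through(self):
        v = build_vessel(self._straight(), 0.002, 6, 12)
        shift = np.array([0.01, -0.02, 0.005])
        disp = interpolate_display(v, v.sim_mesh.vertices + shift)
        np.testing.assert_allclose(disp, v.display_mesh.vertices + shift,
                                   atol=1e-12)

    def test_display_vertex_at_sim_vertex_follows_it(self):
        v = build_vessel(self._straight(), 0.002, 8, 8)
        moved = v.sim_mesh.vertices.copy()
        moved[10] += [0.0, 0.0, 0.003]
        disp = interpolate_display(v, moved)
        # the coincident display vertex moved identically
        i = int(np.argmin(np.linalg.norm(
            v.display_mesh.vertices - v.sim_mesh.vertices[10], axis=1)))
        np.testing.assert_allclose(disp[i] - v.display_mesh.vertices[i],
                                   [0, 0, 0.003], atol=1e-9)

    def test_self_intersecting_centerline_rejected(self):
        # the last segment crosses the first one at (0.075, 0, 0)
        cl = np.array([[0, 0, 0], [0.1, 0, 0], [0.1, 0.01, 0],
                       [0.05, -0.01, 0]], dtype=float)
        with pytest.raises(ValueError, match="self-intersect"):
            build_vessel(cl, 0.002)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            build_vessel(np.zeros((1, 3)), 0.002)
        with pytest.raises(ValueError):
            build_vessel(self._straight(), 0.002, 8, 4)


class TestStrands:
    def test_proximity_excludes_all(self, parallel_squares):
        a, b = parallel_squares
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = generate_strands(a, b, StrandGenSpec(max_distance=0.5), seed=1)
        assert not net.strands

    def test_counts_match_parameterization(self, parallel_squares):
        # sigma = 2 strands per eligible face, n = 3 segments -> 4 particles
        a, b = parallel_squares
        net = generate_strands(a, b, StrandGenSpec(strands_per_face=2,
                                                   segments_per_strand=3,
                                                   max_distance=2.0), seed=1)
        assert len(net.strands) == 2 * len(a.faces)
        assert all(len(s.particle_ids) == 4 for s in net.strands)

    def test_auto_dmax_coincident_centers_empty(self, parallel_squares):
        a, _ = parallel_squares
        with pytest.warns(UserWarning, match="empty strand network"):
            net = generate_strands(a, a, StrandGenSpec(max_distance=None), seed=1)
        assert not net.strands

    def test_deterministic_given_seed(self, parallel_squares):
        a, b = parallel_squares
        spec = StrandGenSpec(max_distance=2.0)
        n1 = generate_strands(a, b, spec, seed=9)
        n2 = generate_strands(a, b, spec, seed=9)
        np.testing.assert_array_equal(n1.polyline.vertices, n2.polyline.vertices)
        n3 = generate_strands(a, b, spec, seed=10)
        assert len(n3.strands) == len(n1.strands)
        assert not np.allclose(n1.polyline.vertices, n3.polyline.vertices)

    def test_endpoints_lie_on_anchor_faces(self, parallel_squares):
        a, b = parallel_squares
        net = generate_strands(a, b, StrandGenSpec(max_distance=2.0), seed=3)
        for s in net.strands:
            start = net.polyline.vertices[s.particle_ids[0]]
            np.testing.assert_allclose(
                start, s.bary_a @ a.vertices[a.faces[s.face_a]], atol=1e-9)
            end = net.polyline.vertices[s.particle_ids[-1]]
            np.testing.assert_allclose(
                end, s.bary_b @ b.vertices[b.faces[s.face_b]], atol=1e-9)

    def test_normal_deviation_bound(self, parallel_squares):
        a, b = parallel_squares
        spec = StrandGenSpec(max_distance=2.0,
                             max_angle_deviation=np.deg2rad(15))
        net = generate_strands(a, b, spec, seed=5)
        normals = a.face_normals()
        for s in net.strands:
            p = net.polyline.vertices[s.particle_ids]
            d = p[-1] - p[0]
            d /= np.linalg.norm(d)
            n = normals[s.face_a]
            if n @ (b.centroid() - a.face_centroids()[s.face_a]) < 0:
                n = -n
            assert np.arccos(np.clip(d @ n, -1, 1)) <= np.deg2rad(15) + 1e-9


class TestStrandConstraints:
    def test_one_constraint_per_segment_with_exact_rest(self, parallel_squares):
        a, b = parallel_squares
        net = generate_strands(a, b, StrandGenSpec(max_distance=2.0,
                                                   segments_per_strand=3), seed=2)
        system, cs = attach_strand_constraints(net)
        assert len(cs.distance) == len(net.polyline.segments)
        for c in cs.distance.values():
            d = np.linalg.norm(net.polyline.vertices[c.i]
                               - net.polyline.vertices[c.j])
            assert c.rest_length == pytest.approx(d, abs=1e-12)

    def test_anchor_follows_surface_pull(self, parallel_squares):
        a, b = parallel_squares
        net = generate_strands(a, b, StrandGenSpec(max_distance=2.0), seed=2)
        system, cs = attach_strand_constraints(net)
        delta = np.array([0.0, 0.0, 0.05])
        moved_a = a.vertices + delta
        update_strand_anchors(net, system, moved_a, b.vertices)
        for s in net.strands:
            expected = s.bary_a @ moved_a[a.faces[s.face_a]]
            np.testing.assert_allclose(system.positions[s.particle_ids[0]],
                                       expected, atol=1e-9)
        # solving keeps the anchored endpoint attached
        cfg = pbd.SolverConfig(external_acceleration=np.zeros(3))
        for _ in range(10):
            update_strand_anchors(net, system, moved_a, b.vertices)
            pbd.step(system, cs, cfg)
        s0 = net.strands[0]
        np.testing.assert_allclose(
            system.positions[s0.particle_ids[0]],
            s0.bary_a @ moved_a[a.faces[s0.face_a]], atol=1e-9)


def test_support_cylinder_is_closed_tube():
    m = build_support_cylinder(n_circ=10, n_axial=5)
    assert len(m.vertices) == 50
    # tube interior vertices are non-boundary; end rings are boundary
    assert m.boundary_vertex_flags.sum() == 20
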