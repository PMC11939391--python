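"""Position-based-dynamics core: prediction, projection, damping, stepping."""

import numpy as np
import pytest

from imasim import pbd
from imasim.pbd import (
    ConstraintSet,
    DihedralConstraint,
    DistanceConstraint,
    ParticleSystem,
    SolverConfig,
    apply_damping,
    dihedral_angle,
    dihedral_constraint_gradients,
    predict_positions,
    project_dihedral,
    project_distance,
    step,
)


def _no_gravity(**kw):
    return SolverConfig(external_acceleration=np.zeros(3), **kw)


class TestPredict:
    def test_rest_state_is_identity(self):
        s = ParticleSystem(np.arange(9.0).reshape(3, 3))
        np.testing.assert_array_equal(predict_positions(s, _no_gravity()),
                                      s.positions)

    def test_ballistic_prediction(self):
        s = ParticleSystem(np.zeros((1, 3)), np.array([[1.0, 0, 0]]))
        x = predict_positions(s, _no_gravity(dt=1.0))
        np.testing.assert_allclose(x, [[1.0, 0, 0]])

    def test_gravity_half_step(self):
        s = ParticleSystem(np.zeros((1, 3)))
        x = predict_positions(s, SolverConfig(dt=0.005))
        assert x[0, 2] == pytest.approx(-1.22625e-4, rel=1e-12)

    def test_fixed_particle_stays(self):
        s = ParticleSystem(np.zeros((1, 3)), np.array([[5.0, 0, 0]]),
                           np.array([0.0]))
        np.testing.assert_array_equal(predict_positions(s, SolverConfig()),
                                      np.zeros((1, 3)))

    def test_nonfinite_names_particle(self):
        s = ParticleSystem(np.array([[0.0, 0, 0], [np.nan, 0, 0]]))
        with pytest.raises(ValueError, match="particle 1"):
            predict_positions(s, SolverConfig())


class TestProjectDistance:
    def test_satisfied_constraint_zero_correction(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        c = DistanceConstraint(0, 1, 1.0)
        np.testing.assert_array_equal(
            project_distance(pos, c, np.ones(2)), np.zeros((2, 3)))

    def test_symmetric_shrink(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        corr = project_distance(pos, DistanceConstraint(0, 1, 1.0), np.ones(2))
        np.testing.assert_allclose(pos + corr,
                                   [[0.5, 0, 0], [1.5, 0, 0]], atol=1e-12)

    def test_one_sided_with_fixed_particle(self):
        pos = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        corr = project_distance(pos, DistanceConstraint(0, 1, 1.0),
                                np.array([0.0, 1.0]))
        np.testing.assert_allclose(pos + corr,
                                   [[0.0, 0, 0], [1.0, 0, 0]], atol=1e-12)

    def test_coincident_particles_warn_and_zero(self, caplog):
        pos = np.zeros((2, 3))
        with caplog.at_level("WARNING"):
            corr = project_distance(pos, DistanceConstraint(0, 1, 1.0),
                                    np.ones(2))
        np.testing.assert_array_equal(corr, 0.0)
        assert "coincident" in caplog.text

    def test_momentum_conserved_equal_masses(self, rng):
        pos = rng.normal(size=(2, 3))
        corr = project_distance(pos, DistanceConstraint(0, 1, 0.5), np.ones(2))
        np.testing.assert_allclose(corr.sum(axis=0), 0.0, atol=1e-15)


class TestDihedral:
    def test_coplanar_is_zero(self):
        p0, p1 = np.array([0.0, 1, 0]), np.array([0.0, -1, 0])
        p2, p3 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        assert dihedral_angle(p0, p1, p2, p3) == pytest.approx(0.0, abs=1e-15)

    def test_fold_by_known_rotation(self):
        # folding the p0 wing by +90 deg about the p2->p3 edge gives -pi/2
        # under the documented convention
        from scipy.spatial.transform import Rotation
        p0, p1 = np.array([0.0, 1, 0]), np.array([0.0, -1, 0])
        p2, p3 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0])
        for phi in (np.pi / 2, -np.pi / 4, 1.0):
            p0r = Rotation.from_rotvec(phi * (p3 - p2)).apply(p0)
            assert dihedral_angle(p0r, p1, p2, p3) == pytest.approx(-phi,
                                                                    abs=1e-12)

    def test_rigid_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        pts = rng.normal(size=(4, 3))
        a0 = dihedral_angle(*pts)
        t = Rotation.random(random_state=11)
        shift = rng.normal(size=3)
        a1 = dihedral_angle(*(t.apply(pts) + shift))
        assert a1 == pytest.approx(a0, abs=1e-10)

    def test_degenerate_raises(self):
        p = np.zeros(3)
        with pytest.raises(ValueError):
            dihedral_angle(p, p, p, np.array([1.0, 0, 0]))

    def test_gradient_matches_finite_differences(self, rng):
        h = 1e-6
        checked = 0
        while checked < 100:
            pts = rng.normal(size=(4, 3))
            try:
                grads = dihedral_constraint_gradients(*pts)
            except ValueError:
                continue
            num = np.zeros((4, 3))
            for k in range(4):
                for d in range(3):
                    pp, pm = pts.copy(), pts.copy()
                    pp[k, d] += h
                    pm[k, d] -= h
                    diff = dihedral_angle(*pp) - dihedral_angle(*pm)
                    diff = (diff + np.pi) % (2 * np.pi) - np.pi
                    num[k, d] = diff / (2 * h)
            scale = max(1.0, np.abs(num).max())
            assert np.abs(grads - num).max() / scale < 1e-5
            checked += 1

    def test_projection_zero_at_rest(self, rng):
        pts = rng.normal(size=(4, 3))
        theta = dihedral_angle(*pts)
        c = DihedralConstraint(0, 1, 2, 3, theta)
        np.testing.assert_allclose(project_dihedral(pts, c, np.ones(4)), 0.0,
                                   atol=1e-12)

    def test_repeated_projection_monotone_decrease(self):
        pts = np.array([[0.0, 1, 0.3], [0.0, -1, 0], [0.0, 0, 0], [1.0, 0, 0]])
        c = DihedralConstraint(0, 1, 2, 3, 0.0)
        w = np.ones(4)
        prev = abs(dihedral_angle(*pts))
        for _ in range(20):
            pts = pts + project_dihedral(pts, c, w)
            cur = abs(dihedral_angle(*pts))
            assert cur <= prev + 1e-12
            prev = cur
        assert prev < 1e-6

    def test_momentum_conserved_equal_masses(self, rng):
        pts = rng.normal(size=(4, 3))
        corr = project_dihedral(pts, DihedralConstraint(0, 1, 2, 3, 0.2),
                                np.ones(4))
        np.testing.assert_allclose(corr.sum(axis=0), 0.0, atol=1e-9)


class TestDamping:
    def test_zero_coefficients_noop(self, rng):
        v = rng.normal(size=(5, 3))
        s = ParticleSystem(rng.normal(size=(5, 3)), v.copy())
        apply_damping(s, _no_gravity(linear_damping=0.0, angular_damping=0.0))
        np.testing.assert_array_equal(s.velocities, v)

    def test_linear_damping_arithmetic(self):
        # m = 0.03 kg, k_l = 0.03 kg/s, dt = 5 ms -> one-step factor 0.995
        s = ParticleSystem(np.zeros((1, 3)), np.array([[1.0, 0, 0]]),
                           np.array([1.0 / 0.03]))
        apply_damping(s, SolverConfig(angular_damping=0.0))
        assert s.velocities[0, 0] == pytest.approx(0.995, rel=1e-12)

    def test_never_reverses_velocity(self, rng):
        for _ in range(20):
            m = rng.uniform(0.01, 1.0)
            v = rng.normal(size=(1, 3))
            s = ParticleSystem(np.zeros((1, 3)), v.copy(), np.array([1.0 / m]))
            cfg = SolverConfig(dt=0.005, linear_damping=0.03,
                               angular_damping=0.0)
            assert cfg.dt * cfg.linear_damping / m < 1
            apply_damping(s, cfg)
            assert (np.sign(s.velocities) == np.sign(v))[v != 0].all()

    def test_angular_damping_preserves_com_velocity(self, rng):
        x = rng.normal(size=(6, 3))
        omega = np.array([0.0, 0.0, 4.0])
        v = np.cross(omega, x - x.mean(axis=0)) + np.array([0.2, 0, 0])
        s = ParticleSystem(x, v, np.ones(6))
        apply_damping(s, _no_gravity(linear_damping=0.0, angular_damping=0.01))
        np.testing.assert_allclose(s.velocities.mean(axis=0),
                                   v.mean(axis=0), atol=1e-12)
        # rotational speed strictly reduced
        rot0 = np.linalg.norm(v - v.mean(axis=0))
        rot1 = np.linalg.norm(s.velocities - s.velocities.mean(axis=0))
        assert rot1 < rot0


class TestStep:
    def test_identity_when_satisfied(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        s = ParticleSystem(pos.copy())
        cs = ConstraintSet()
        cs.add_distance(DistanceConstraint(0, 1, 1.0))
        step(s, cs, _no_gravity())
        np.testing.assert_allclose(s.positions, pos, atol=1e-15)
        np.testing.assert_allclose(s.velocities, 0.0, atol=1e-15)

    def test_stretched_spring_relaxes_to_rest_length(self):
        s = ParticleSystem(np.array([[0.0, 0, 0], [2.0, 0, 0]]),
                           inverse_masses=np.array([0.0, 1.0]))
        cs = ConstraintSet()
        cs.add_distance(DistanceConstraint(0, 1, 1.0))
        for _ in range(50):
            step(s, cs, _no_gravity())
        assert np.linalg.norm(s.positions[1] - s.positions[0]) == \
            pytest.approx(1.0, abs=1e-6)
        np.testing.assert_array_equal(s.positions[0], 0.0)

    def test_chain_residual_improves_with_iterations(self):
        # 3-particle chain anchored at one end: Gauss-Seidel needs sweeps
        def residual(iters):
            s = ParticleSystem(np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]]),
                               inverse_masses=np.array([0.0, 1.0, 1.0]))
            cs = ConstraintSet()
            cs.add_distance(DistanceConstraint(0, 1, 1.0, stiffness=1.0))
            cs.add_distance(DistanceConstraint(1, 2, 1.0, stiffness=1.0))
            step(s, cs, _no_gravity(iterations=iters))
            return pbd.constraint_residuals(s, cs).max()
        assert residual(5) < residual(1)

    def test_fixed_particles_bitwise_stationary_random_steps(self, rng):
        n = 12
        inv_m = rng.uniform(0.5, 2.0, n)
        inv_m[[0, 3, 7]] = 0.0
        s = ParticleSystem(rng.normal(size=(n, 3)),
                           rng.normal(size=(n, 3)) * 0.1, inv_m)
        s.velocities[s.fixed] = 0.0
        frozen = s.positions[s.fixed].copy()
        cs = ConstraintSet()
        for _ in range(20):
            i, j = rng.choice(n, size=2, replace=False)
            cs.add_distance(DistanceConstraint(int(i), int(j),
                                               float(rng.uniform(0.5, 2.0))))
        for _ in range(200):
            step(s, cs, SolverConfig())
        assert (s.positions[s.fixed] == frozen).all()

    def test_pinned_cloth_reaches_sagged_equilibrium(self):
        from imasim import anatomy
        spec = anatomy.FasciaSpec(width=0.08, height=0.08, resolution=(6, 6),
                                  total_mass=0.02)
        _, cs, system = anatomy.build_fascia(spec)
        cfg = SolverConfig()
        for _ in range(1500):
            step(system, cs, cfg)
        before = system.positions.copy()
        step(system, cs, cfg)
        assert np.abs(system.positions - before).max() < 1e-6
        assert system.positions[:, 2].min() < -1e-4  # it actually sagged

    def test_nan_guard_names_stage(self):
        s = ParticleSystem(np.array([[0.0, 0, 0], [np.inf, 0, 0]]))
        with pytest.raises((ValueError, FloatingPointError)):
            step(s, ConstraintSet(), SolverConfig())


class TestConstraintSet:
    def test_add_remove_and_edge_lookup(self):
        cs = ConstraintSet()
        cid = cs.add_distance(DistanceConstraint(2, 5, 1.0))
        assert cs.distance_id_for_edge(5, 2) == cid
        cs.remove(cid)
        assert cs.distance_id_for_edge(2, 5) is None
        with pytest.raises(KeyError):
            cs.remove(cid)

    def test_dataframe_export(self):
        cs = ConstraintSet()
        cs.add_distance(DistanceConstraint(0, 1, 1.0))
        cs.add_dihedral(DihedralConstraint(0, 1, 2, 3, 0.0))
        df = cs.to_dataframe()
        assert set(df["type"]) == {"distance", "dihedral"}
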