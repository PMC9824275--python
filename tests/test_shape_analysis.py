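"""Moments of inertia and shape factor: closed-form oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanofib as nf
from nanofib.errors import DegenerateGeometryError, InvalidArgumentError
from nanofib.shape_analysis import shape_report


def sample_ball(n, radius, rng):
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    return pts * radius * rng.uniform(0, 1, n)[:, None] ** (1 / 3)


def sample_ellipsoid(n, semi, rng):
    return sample_ball(n, 1.0, rng) * np.asarray(semi)


class TestPrincipalMoments:
    def test_octahedron_unit_masses(self):
        pts = np.array([
            [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
        ], dtype=float)
        moments, _ = nf.principal_moments(pts, np.ones(6))
        np.testing.assert_allclose(moments, [4.0, 4.0, 4.0])

    def test_single_bead_zero(self):
        moments, _ = nf.principal_moments(np.array([[1.0, 2.0, 3.0]]), np.ones(1))
        np.testing.assert_allclose(moments, 0.0, atol=1e-12)

    def test_solid_ellipsoid_closed_form(self, rng):
        # uniform solid ellipsoid semi-axes (a,b,c): I = m/5 (b^2+c^2) etc.
        n = 100_000
        pts = sample_ellipsoid(n, (2.0, 1.0, 1.0), rng)
        moments, _ = nf.principal_moments(pts, np.ones(n))
        expected = n / 5.0 * np.array([2.0, 5.0, 5.0])
        np.testing.assert_allclose(moments, expected, rtol=0.01)

    def test_zero_mass_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nf.principal_moments(np.zeros((3, 3)), np.zeros(3))


class TestAlignment:
    def test_rod_along_z_ends_on_x(self, rng):
        pts = np.zeros((100, 3))
        pts[:, 2] = np.linspace(-5, 5, 100)
        pts += 0.01 * rng.normal(size=pts.shape)
        aligned, _ = nf.align_lowest_moi_to_x(pts)
        var = aligned.var(axis=0)
        assert var[0] == max(var)

    def test_already_aligned_identity_up_to_sign(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.arange(10, dtype=float)
        aligned, rot = nf.align_lowest_moi_to_x(pts)
        np.testing.assert_allclose(np.abs(rot), np.eye(3), atol=1e-9)

    def test_deterministic_for_degenerate_sphere(self, rng):
        pts = sample_ball(500, 1.0, rng)
        a1, r1 = nf.align_lowest_moi_to_x(pts)
        a2, r2 = nf.align_lowest_moi_to_x(pts)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(r1, r2)

    def test_rotation_is_proper(self, rng):
        pts = rng.normal(size=(50, 3))
        _, rot = nf.align_lowest_moi_to_x(pts)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)


class TestShapeFactor:
    def test_sphere_near_zero(self, rng):
        pts = sample_ball(10_000, 3.0, rng)
        assert abs(nf.shape_factor(pts)) <= 0.02

    def test_collinear_rod_exactly_one(self):
        pts = np.zeros((100, 3))
        pts[:, 0] = np.arange(100, dtype=float)
        assert nf.shape_factor(pts) == 1.0

    def test_ellipsoid_211_is_0p6(self, rng):
        pts = sample_ellipsoid(50_000, (2.0, 1.0, 1.0), rng)
        assert nf.shape_factor(pts) == pytest.approx(0.6, abs=0.02)

    def test_collocated_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            nf.shape_factor(np.ones((5, 3)))

    def test_fewer_than_two_beads_rejected(self):
        with pytest.raises(InvalidArgumentError):
            nf.shape_factor(np.array([[0.0, 0.0, 0.0]]))

    def test_rigid_transform_invariance(self, rng):
        pts = rng.normal(size=(200, 3)) * np.array([3.0, 1.0, 0.5])
        masses = rng.uniform(1, 2, 200)
        sf0 = nf.shape_factor(pts, masses)
        for _ in range(5):
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            if np.linalg.det(q) < 0:
                q[:, 2] *= -1
            moved = pts @ q.T + rng.normal(size=3) * 10
            assert abs(nf.shape_factor(moved, masses) - sf0) < 1e-10

    def test_mass_scaling_invariance(self, rng):
        pts = rng.normal(size=(100, 3))
        masses = rng.uniform(1, 5, 100)
        assert nf.shape_factor(pts, masses) == pytest.approx(
            nf.shape_factor(pts, 17.3 * masses), abs=1e-12
        )

    @settings(deadline=None, max_examples=200)
    @given(seed=st.integers(0, 10_000))
    def test_bounded_on_random_clouds(self, seed):
        r = np.random.default_rng(seed)
        pts = r.normal(size=(r.integers(4, 50), 3)) * r.uniform(0.1, 5, 3)
        sf = nf.shape_factor(pts)
        assert 0.0 <= sf <= 1.0


class TestShapeTimeseries:
    def test_rigid_trajectory_sf_constant(self, fibril, probe):
        from nanofib import make_steered_config, simulate_toy_trajectory

        cfg, inter = make_steered_config(fibril, probe, target="side", seed=0)
        traj = simulate_toy_trajectory(cfg, inter, n_frames=8, stride=3, seed=4)
        reports = nf.shape_timeseries(traj, all_frames=True)
        sfs = [r.sf for r in reports]
        np.testing.assert_allclose(sfs, sfs[0], atol=1e-9)

    def test_static_start_end_equal(self, fibril):
        from nanofib.synthetic_data import SystemConfiguration, simulate_toy_trajectory

        box = np.full(3, 20.0)
        cfg = SystemConfiguration(
            fibril=fibril, np_model=None, box=box,
            fibril_positions=fibril.positions - fibril.positions.mean(0) + box / 2,
            np_positions=None,
        )
        traj = simulate_toy_trajectory(cfg, None, n_frames=5, seed=0)
        reports = nf.shape_timeseries(traj, component=traj.fibril_index)
        assert reports[0].sf == reports[-1].sf

    def test_empty_component_rejected(self, fibril):
        from nanofib.synthetic_data import SystemConfiguration, simulate_toy_trajectory

        box = np.full(3, 20.0)
        cfg = SystemConfiguration(
            fibril=fibril, np_model=None, box=box,
            fibril_positions=fibril.positions - fibril.positions.mean(0) + box / 2,
            np_positions=None,
        )
        traj = simulate_toy_trajectory(cfg, None, n_frames=3, seed=0)
        with pytest.raises(InvalidArgumentError):
            nf.shape_timeseries(traj)

    def test_morphing_rod_to_ball_sf_decreases(self, rng):
        # synthetic trajectory: beads interpolate from a rod to a ball
        from nanofib.synthetic_data import Trajectory

        n = 200
        rod = np.zeros((n, 3))
        rod[:, 0] = np.linspace(-5, 5, n)
        ball = sample_ball(n, 2.0, rng)
        frames = np.array([rod * (1 - t) + ball * t for t in np.linspace(0, 1, 6)])
        traj = Trajectory(
            times=np.arange(6.0), frames=frames, box=np.full(3, 50.0),
            fibril_index=np.arange(0), np_index=np.arange(n),
            masses=np.ones(n),
        )
        sfs = [r.sf for r in nf.shape_timeseries(traj, all_frames=True)]
        assert all(a >= b - 1e-9 for a, b in zip(sfs, sfs[1:]))
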