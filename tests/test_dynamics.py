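"""Dynamic observables: MSDs, autocorrelations, displacement correlations."""

import numpy as np
import pytest

from ring_atg import (
    correlation_length,
    displacement_correlation,
    g3,
    g3_rel,
    scalar_autocorrelation,
    tacf,
)
from ring_atg.core import Frame, Topology, Trajectory
from ring_atg.dynamics import CorrelationSeries
from ring_atg.fixtures import (
    make_circle_ring,
    make_rigid_motion_trajectory,
    uniform_sphere_points,
)


def _static_system(M=4, N=8, spread=5.0, seed=0):
    rng = np.random.default_rng(seed)
    rings = [make_circle_ring(N, 1.0, center=rng.uniform(-spread, spread, 3))
             for _ in range(M)]
    pos = np.vstack(rings)
    topo = Topology(M=M, N=N, hot_mask=np.zeros(M * N, bool))
    return Frame(time=0.0, positions=pos, box=100.0), topo


class TestG3:
    def test_uniform_translation_is_removed_by_com_frame(self):
        frame, topo = _static_system()
        traj = make_rigid_motion_trajectory(frame, topo, motion="translation",
                                            rate=0.7, n_frames=12)
        assert np.all(np.abs(g3(traj).value) < 1e-20)

    def test_frozen_trajectory(self):
        frame, topo = _static_system()
        traj = make_rigid_motion_trajectory(frame, topo, motion="translation",
                                            rate=0.0, n_frames=6)
        assert np.all(g3(traj).value == 0.0)

    def test_random_walk_oracle_with_com_correction(self):
        # independent 3-D random walks of M ring COMs: in the global-COM
        # frame, g3(k) = 3 sigma_s^2 k (1 - 1/M)
        M, T, sig = 40, 600, 0.3
        rng = np.random.default_rng(11)
        com = np.cumsum(rng.normal(0, sig, (T, M, 3)), axis=0)
        pos = com[:, :, None, :] + make_circle_ring(4, 0.01)[None, None]
        topo = Topology(M=M, N=4, hot_mask=np.zeros(4 * M, bool))
        traj = Trajectory(times=np.arange(float(T)),
                          positions=pos.reshape(T, 4 * M, 3),
                          topology=topo, box=1e9)
        series = g3(traj)
        for k in (1, 2, 5):
            expect = 3 * sig**2 * k * (1 - 1 / M)
            n_eff = M * (T - k) / (2 * k)  # start-time overlap correction
            se = expect * np.sqrt(2.0 / 3.0) / np.sqrt(n_eff)
            assert abs(series.value[k - 1] - expect) < 3 * se

    def test_requires_two_frames(self):
        frame, topo = _static_system()
        traj = make_rigid_motion_trajectory(frame, topo, motion="translation",
                                            rate=0.0, n_frames=3)
        with pytest.raises(ValueError):
            g3(traj, t0=100.0)


class TestG3Rel:
    def test_rigid_rotation_invariance(self):
        frame, topo = _static_system()
        traj = make_rigid_motion_trajectory(frame, topo, motion="rotation",
                                            rate=0.4, n_frames=15,
                                            axis=(1.0, 2.0, -1.0))
        assert np.all(np.abs(g3_rel(traj).value) < 1e-10)

    def test_rigid_translation_invariance(self):
        frame, topo = _static_system()
        traj = make_rigid_motion_trajectory(frame, topo, motion="translation",
                                            rate=1.3, n_frames=10)
        assert np.all(np.abs(g3_rel(traj).value) < 1e-20)

    def test_single_displaced_ring_contributes_squared_shift(self):
        # two distant rings; move one by delta along the line joining them
        N, delta = 8, 0.9
        a = make_circle_ring(N, 0.5, center=(0, 0, 0))
        b = make_circle_ring(N, 0.5, center=(20.0, 0, 0))
        pos0 = np.vstack([a, b])
        pos1 = np.vstack([a, b + np.array([delta, 0, 0])])
        topo = Topology(M=2, N=N, hot_mask=np.zeros(2 * N, bool))
        traj = Trajectory(times=[0.0, 1.0], positions=np.stack([pos0, pos1]),
                          topology=topo, box=100.0)
        assert g3_rel(traj).value[0] == pytest.approx(delta**2)


class TestTacf:
    def test_frozen_configuration_flags_lower_bound(self):
        frame, topo = _static_system()
        traj = make_rigid_motion_trajectory(frame, topo, motion="translation",
                                            rate=0.0, n_frames=8)
        res = tacf(traj)
        assert np.allclose(res.series.value, 1.0)
        assert res.lower_bound_flag

    def test_rigid_planar_rotation_gives_cosine(self):
        N, omega = 16, 0.25
        ring = make_circle_ring(N, 2.0)
        topo = Topology(M=1, N=N, hot_mask=np.zeros(N, bool))
        frame = Frame(time=0.0, positions=ring, box=10.0)
        traj = make_rigid_motion_trajectory(frame, topo, motion="rotation",
                                            rate=omega, n_frames=30)
        res = tacf(traj)
        lag = res.series.abscissa
        assert np.allclose(res.series.value, np.cos(omega * lag), atol=1e-10)
        assert res.series.value[0] == 1.0
        assert np.all(np.abs(res.series.value) <= 1.0 + 1e-12)

    def test_exponential_orientation_diffusion_time(self):
        # unit vectors kicked by rotations about a random perpendicular
        # axis, angle ~ N(0, s2): each step scales <u(t).u(0)> by exactly
        # E[cos theta] = exp(-s2/2), so the TACF is exponential with
        # tau_c = -dt / ln E[cos theta] = dt / (D dt) = 1/D
        D, dt_frame, T, M = 0.05, 0.25, 4000, 150
        rng = np.random.default_rng(12)
        u = np.tile(np.array([0.0, 0.0, 1.0]), (M, 1))
        us = np.empty((T, M, 3))
        for t in range(T):
            us[t] = u
            ax = rng.standard_normal((M, 3))
            ax -= np.sum(ax * u, axis=1)[:, None] * u
            ax /= np.linalg.norm(ax, axis=1)[:, None]
            ang = rng.normal(0, np.sqrt(2 * D * dt_frame), (M, 1))
            u = u * np.cos(ang) + ax * np.sin(ang)
            u /= np.linalg.norm(u, axis=1)[:, None]
        # embed as 2-bead rings whose spanning vector is u
        pos = np.zeros((T, 2 * M, 3))
        pos[:, 0::2] = 0.5 * us
        pos[:, 1::2] = -0.5 * us
        topo = Topology(M=M, N=2, hot_mask=np.zeros(2 * M, bool))
        traj = Trajectory(times=dt_frame * np.arange(T), positions=pos,
                          topology=topo, box=10.0)
        res = tacf(traj)
        tau_c = -dt_frame / np.log(np.exp(-(2 * D * dt_frame) / 2))
        assert tau_c == pytest.approx(1 / D)
        assert res.tau_with_tail == pytest.approx(tau_c, rel=0.10)


class TestScalarAutocorrelation:
    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            scalar_autocorrelation(np.ones(50))

    def test_white_noise_decorrelates(self, rng):
        y = rng.standard_normal((2000, 10))
        acf = scalar_autocorrelation(y)
        assert acf.value[0] == pytest.approx(1.0)
        se = 1 / np.sqrt(2000 * 10)
        assert np.all(np.abs(acf.value[1:20]) < 3.5 * se)

    def test_ar1_analytic_acf(self, rng):
        phi, T, M = 0.8, 6000, 10
        y = np.zeros((T, M))
        eps = rng.standard_normal((T, M))
        for t in range(1, T):
            y[t] = phi * y[t - 1] + eps[t]
        acf = scalar_autocorrelation(y)
        for k in (1, 2, 4, 8):
            se = np.sqrt((1 + phi**2) / (1 - phi**2) / (T * M))
            assert abs(acf.value[k] - phi**k) < 4 * se


class TestDisplacementCorrelation:
    def _traj_from_disp(self, pos0, disp):
        topo = Topology(M=1, N=pos0.shape[0],
                        hot_mask=np.zeros(pos0.shape[0], bool))
        return Trajectory(times=[0.0, 1.0],
                          positions=np.stack([pos0, pos0 + disp]),
                          topology=topo, box=10.0)

    def test_identical_displacements_are_perfectly_coherent(self):
        pos0 = uniform_sphere_points(300, 5.0, seed=13)
        traj = self._traj_from_disp(pos0, np.tile([0.3, -0.1, 0.2], (300, 1)))
        cs = displacement_correlation(traj, lag=1)
        norm = cs.meta["normalized"]
        assert np.allclose(norm[cs.counts > 0], 1.0)

    def test_independent_displacements_decorrelate(self):
        rng = np.random.default_rng(14)
        pos0 = uniform_sphere_points(2000, 5.0, seed=15)
        traj = self._traj_from_disp(pos0, rng.normal(0, 0.2, (2000, 3)))
        cs = displacement_correlation(traj, lag=1)
        ok = cs.counts > 100
        se = 3 * 0.2**2 / np.sqrt(cs.counts[ok])
        assert np.all(np.abs(cs.value[ok]) < 3.5 * se)

    def test_rotating_shell_anticorrelates_at_antipodes(self):
        # rigid rotation about z: displacements at opposing shell positions
        # point opposite ways
        pts = uniform_sphere_points(800, 1.0, seed=16)
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= 4.0
        dtheta = 0.1
        disp = dtheta * np.cross([0, 0, 1.0], pts)
        traj = self._traj_from_disp(pts, disp)
        cs = displacement_correlation(traj, lag=1)
        norm = cs.meta["normalized"]
        far = (cs.abscissa > 7.0) & (cs.counts > 50)
        assert norm[far].mean() < -0.2

    def test_symmetry_in_pair_exchange(self):
        # C_s uses unordered pair products, so it is symmetric by
        # construction; verify the estimator against a direct double loop
        rng = np.random.default_rng(17)
        pos0 = uniform_sphere_points(40, 3.0, seed=18)
        disp = rng.normal(0, 0.3, (40, 3))
        traj = self._traj_from_disp(pos0, disp)
        cs = displacement_correlation(traj, lag=1, bin_width=1.0, r_min=0.0)
        acc = np.zeros_like(cs.value)
        cnt = np.zeros_like(cs.counts)
        for i in range(40):
            for j in range(i + 1, 40):
                r = np.linalg.norm(pos0[i] - pos0[j])
                b = int(r // 1.0)
                if b < len(acc):
                    acc[b] += disp[i] @ disp[j]
                    cnt[b] += 1
        ok = cnt > 0
        assert np.allclose(cs.value[ok], acc[ok] / cnt[ok])
        assert np.array_equal(cs.counts, cnt)


class TestCorrelationLength:
    def _series(self, r, c, counts=None):
        counts = np.ones_like(r, dtype=int) if counts is None else counts
        return CorrelationSeries(abscissa=r, value=c, counts=counts,
                                 meta={"normalized": c})

    def test_rectangle_profile(self):
        r = np.arange(0.9, 11.0, 0.5)
        c = np.ones_like(r)
        assert correlation_length(self._series(r, c)) == pytest.approx(10.0)

    def test_exponential_profile_integrates_to_decay_length(self):
        lam = 3.0
        r = np.arange(0.9, 60.0, 0.1)
        c = np.exp(-(r - 0.9) / lam)
        assert correlation_length(self._series(r, c)) == pytest.approx(
            lam, rel=0.01)

    def test_noise_floor(self):
        r = np.arange(0.9, 10.0, 0.6)
        c = np.r_[1.0, -0.01 * np.ones(len(r) - 1)]
        val = correlation_length(self._series(r, c))
        assert val == pytest.approx(0.6, abs=0.2)
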