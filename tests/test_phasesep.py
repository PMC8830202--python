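"""Demixing order parameter, radial profiles and tank-treading diagnostics."""

import numpy as np
import pytest

from ring_atg import (
    contour_offset,
    like_neighbor_fraction,
    order_parameter_phi,
    radial_profiles,
    tank_treading_signal,
)
from ring_atg.core import Frame, Topology, Trajectory
from ring_atg.fixtures import (
    make_circle_ring,
    make_random_mixture,
    make_rigid_motion_trajectory,
    uniform_sphere_points,
)


def _frame(positions, M, N, hot_mask, box=100.0):
    return (Frame(time=0.0, positions=positions, box=box),
            Topology(M=M, N=N, hot_mask=hot_mask))


class TestLikeNeighborFraction:
    def test_all_hot_pair_of_interleaved_rings(self, rng):
        pos = np.vstack([uniform_sphere_points(32, 2.0, seed=1),
                         uniform_sphere_points(32, 2.0, seed=2)])
        frame, topo = _frame(pos, 2, 32, np.ones(64, bool))
        assert like_neighbor_fraction(frame, topo) == 1.0

    def test_every_interchain_neighbor_unlike(self):
        # two stacked circles: chain A all cold, chain B all hot right above
        a = make_circle_ring(24, radius=5.0)
        b = make_circle_ring(24, radius=5.0, center=(0, 0, 0.5))
        mask = np.r_[np.zeros(24, bool), np.ones(24, bool)]
        frame, topo = _frame(np.vstack([a, b]), 2, 24, mask)
        assert like_neighbor_fraction(frame, topo) == 0.0

    def test_well_mixed_binomial_baseline(self):
        # random typing with hot fraction p: like fraction -> p^2 + (1-p)^2
        frame, topo = make_random_mixture(4, 2000, hot_fraction=0.125, seed=3)
        x = like_neighbor_fraction(frame, topo)
        assert x == pytest.approx(0.78125, abs=0.01)

    def test_relabel_symmetry_at_half_filling(self):
        frame, topo = make_random_mixture(4, 500, hot_fraction=0.5, seed=4)
        x = like_neighbor_fraction(frame, topo)
        topo_flipped = Topology(M=4, N=500, hot_mask=~topo.hot_mask)
        assert like_neighbor_fraction(frame, topo_flipped) == pytest.approx(x)

    def test_single_chain_rejected(self):
        frame, topo = make_random_mixture(1, 64, seed=5)
        with pytest.raises(ValueError):
            like_neighbor_fraction(frame, topo)


class TestOrderParameter:
    def test_zero_at_onset_and_for_frozen_trajectory(self):
        frame, topo = make_random_mixture(3, 200, seed=6)
        pos = np.repeat(frame.positions[None], 5, axis=0)
        traj = Trajectory(times=np.arange(5.0), positions=pos, topology=topo,
                          box=frame.box)
        phi = order_parameter_phi(traj, t0=0.0, baseline_window=1)
        assert np.allclose(phi["phi"], 0.0)

    def test_rises_to_demixed_endpoint(self):
        mixed, topo = make_random_mixture(2, 400, hot_fraction=0.5,
                                          seed=7, contiguous=True)
        # demixed endpoint: hot monomers moved to one side, cold to the other
        demixed = mixed.positions.copy()
        demixed[topo.hot_mask, 0] = np.abs(demixed[topo.hot_mask, 0]) + 5.0
        demixed[~topo.hot_mask, 0] = -np.abs(demixed[~topo.hot_mask, 0]) - 5.0
        pos = np.stack([mixed.positions, demixed])
        traj = Trajectory(times=[0.0, 1.0], positions=pos, topology=topo,
                          box=mixed.box)
        phi = order_parameter_phi(traj, baseline_window=1)
        x0 = like_neighbor_fraction(traj.frame(0), topo)
        x1 = like_neighbor_fraction(traj.frame(1), topo)
        assert phi["phi"].iloc[0] == 0.0
        assert phi["phi"].iloc[1] == pytest.approx(x1 / x0 - 1.0)
        assert phi["phi"].iloc[1] > 0.2

    def test_invariant_under_global_rotation(self):
        from scipy.spatial.transform import Rotation

        frame, topo = make_random_mixture(3, 300, seed=8)
        Rm = Rotation.from_rotvec([0.3, -0.5, 1.0]).as_matrix()
        rotated = Frame(time=0.0, positions=frame.positions @ Rm.T,
                        box=frame.box)
        assert like_neighbor_fraction(rotated, topo) == pytest.approx(
            like_neighbor_fraction(frame, topo), abs=1e-12)


class TestRadialProfiles:
    def _traj(self, n=20000, R=5.0, seed=9):
        pos = uniform_sphere_points(n, R, seed=seed)
        mask = np.zeros(n, bool)
        mask[: n // 8] = True
        topo = Topology(M=1, N=n, hot_mask=mask)
        return Trajectory(times=[0.0], positions=pos[None], topology=topo,
                          box=R)

    def test_uniform_points_give_flat_density(self):
        traj = self._traj()
        df = radial_profiles(traj, bin_width=1.0)
        n, R = 20000, 5.0
        rho0 = n / (4 / 3 * np.pi * R**3)
        edges = np.arange(0.0, R + 1.0, 1.0)
        shell_counts = rho0 * 4 / 3 * np.pi * np.diff(edges**3)
        se = np.sqrt(shell_counts) / (4 / 3 * np.pi * np.diff(edges**3))
        assert np.all(np.abs(df["all"].values - rho0) < 3.5 * se)

    def test_partition_identity_and_total_count(self):
        traj = self._traj(n=5000)
        df = radial_profiles(traj, bin_width=0.5)
        assert np.allclose(df["hot"] + df["cold"], df["all"])
        edges = np.arange(0.0, 5.0 + 0.5, 0.5)
        vols = 4 / 3 * np.pi * np.diff(edges**3)
        assert np.sum(df["all"].values * vols) == pytest.approx(5000)
        assert np.sum(df["hot"].values * vols) == pytest.approx(5000 // 8)

    def test_shell_spike(self):
        n = 1000
        pts = uniform_sphere_points(n, 1.0, seed=10)
        pts *= 2.5 / np.linalg.norm(pts, axis=1)[:, None]  # all at r = 2.5
        topo = Topology(M=1, N=n, hot_mask=np.zeros(n, bool))
        traj = Trajectory(times=[0.0], positions=pts[None], topology=topo,
                          box=5.0)
        df = radial_profiles(traj, bin_width=1.0)
        nonzero = df[df["all"] > 0]
        assert len(nonzero) == 1 and nonzero["r"].iloc[0] == 2.5


class TestTankTreading:
    def _ring_traj(self, n_frames=8, advect=0):
        N = 32
        ring = make_circle_ring(N, radius=3.0)
        mask = np.zeros(N, bool)
        mask[:8] = True
        topo = Topology(M=1, N=N, hot_mask=mask)
        pos = np.stack([np.roll(ring, -advect * k, axis=0)
                        for k in range(n_frames)])
        return Trajectory(times=np.arange(float(n_frames)), positions=pos,
                          topology=topo, box=10.0)

    def test_rigid_rotation_keeps_series_constant(self):
        N = 32
        ring = make_circle_ring(N, radius=3.0)
        mask = np.zeros(N, bool)
        mask[:8] = True
        topo = Topology(M=1, N=N, hot_mask=mask)
        frame = Frame(time=0.0, positions=ring, box=10.0)
        traj = make_rigid_motion_trajectory(frame, topo, motion="rotation",
                                            rate=0.3, n_frames=10)
        sig = tank_treading_signal(traj)
        assert np.allclose(sig["ring0"], sig["ring0"].iloc[0])

    def test_frozen_trajectory_has_zero_variance(self):
        sig = tank_treading_signal(self._ring_traj(advect=0))
        assert sig["ring0"].var() == 0.0

    def test_contour_offset_reads_advection(self):
        # monomers advected along the fixed circular contour by 2/frame
        traj = self._ring_traj(n_frames=6, advect=2)
        off = contour_offset(traj)
        assert off["ring0"].tolist() == [0, 2, 4, 6, 8, 10]
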