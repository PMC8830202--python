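"""Integrator, thermostats, initialization and angular-momentum control."""

import numpy as np
import pytest

from ring_atg import (
    initialize_melt,
    pairwise_linking_numbers,
    run_simulation,
    zero_angular_momentum,
)
from ring_atg.core import Frame, Topology
from ring_atg.params import SimParams
from ring_atg.potentials import bond_minimum
from ring_atg.simulate import (
    _Workspace,
    _advance,
    angular_momentum,
    kinetic_temperature,
    total_energy,
)


def _free_frame(params, seed=0, spread=2.0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-spread, spread, (params.n_monomers, 3))
    vel = np.zeros_like(pos)
    return Frame(time=0.0, positions=pos, box=params.R_sphere, velocities=vel)


class TestLangevinIntegration:
    def test_ballistic_free_flight(self):
        # zero forces, zero friction and noise: positions advance by v*dt
        params = SimParams(M=1, N=8, gamma_damp=0.0, seed=0)
        topo = Topology.from_params(params)
        frame = _free_frame(params)
        frame.velocities[:] = [[0.5, -0.25, 1.0]] * params.n_monomers
        traj = run_simulation(params, n_steps=100, output_every=100,
                              frame0=frame, topo=topo, forces=(),
                              store_velocities=True)
        expect = frame.positions + 100 * params.dt * frame.velocities
        assert np.allclose(traj.positions[-1], expect, atol=1e-12)

    def test_equipartition_free_particles(self):
        # ideal gas at T = 1: m<v^2> = 3T within 3 SE
        params = SimParams(M=4, N=64, N_h=0, T_cold=1.0, seed=3)
        topo = Topology.from_params(params)
        traj = run_simulation(params, n_steps=30000, output_every=500,
                              frame0=_free_frame(params), topo=topo,
                              forces=(), store_velocities=True)
        temps = np.array([kinetic_temperature(f.velocities) for f in traj][10:])
        se = temps.std(ddof=1) / np.sqrt(len(temps))
        assert abs(temps.mean() - 1.0) < 3 * se + 0.01

    def test_two_temperature_ideal_gas(self):
        # hot block at 3.0, rest at 1.0; no interactions couple them
        params = SimParams(M=4, N=64, T_cold=1.0, T_hot=3.0, seed=4)
        topo = Topology.from_params(params)
        traj = run_simulation(params, n_steps=60000, output_every=500,
                              frame0=_free_frame(params), topo=topo,
                              forces=(), store_velocities=True)
        th = np.array([kinetic_temperature(f.velocities, mask=topo.hot_mask)
                       for f in traj][20:])
        tc = np.array([kinetic_temperature(f.velocities, mask=~topo.hot_mask)
                       for f in traj][20:])
        assert abs(th.mean() - 3.0) < 3 * th.std(ddof=1) / np.sqrt(len(th))
        assert abs(tc.mean() - 1.0) < 3 * tc.std(ddof=1) / np.sqrt(len(tc))

    def test_same_seed_reproduces_trajectory(self):
        kw = dict(n_steps=2000, output_every=500,
                  init_kwargs=dict(ramp_steps=500, burnin_steps=1000))
        t1 = run_simulation(SimParams(M=2, N=32, seed=42), **kw)
        t2 = run_simulation(SimParams(M=2, N=32, seed=42), **kw)
        assert np.array_equal(t1.positions, t2.positions)

    def test_energy_conservation_without_thermostat(self, small_melt):
        # gamma = 0, no noise: symplectic quality means the energy error
        # stays a bounded oscillation (no blow-up) whose envelope shrinks
        # roughly as dt^2 when the step is refined
        params, frame, topo = small_melt
        envelopes = {}
        for dt in (0.005, 0.002):
            p = params.with_(dt=dt)
            pos = frame.positions.copy()
            vel = frame.velocities.copy()
            ws = _Workspace.for_n(p.n_monomers)
            temps = np.full(p.n_monomers, 1.0)
            rng = np.random.default_rng(0)
            energies = []
            for _ in range(51):
                f = Frame(time=0.0, positions=pos, box=p.R_sphere,
                          velocities=vel)
                energies.append(total_energy(f, topo, p))
                _advance(pos, vel, topo, p, 200, temps, rng, ws, gamma=0.0)
            energies = np.asarray(energies)
            envelopes[dt] = np.abs(energies - energies[0]).max() / p.n_monomers
            # secular drift: first-half vs second-half means stay within
            # the oscillation envelope (no runaway heating)
            drift = abs(energies[25:].mean() - energies[:25].mean())
            assert drift / p.n_monomers < 2 * envelopes[dt] + 1e-12
        assert envelopes[0.005] < 5e-2
        assert envelopes[0.002] < 5e-3
        assert envelopes[0.002] < envelopes[0.005] / 2


class TestInitialization:
    def test_melt_satisfies_all_invariants(self, small_melt):
        params, frame, topo = small_melt
        frame.check(topo, params.r_max)  # inside sphere, bonds intact
        topo.validate()  # one contiguous hot block per ring
        assert topo.N_h == params.N_h
        assert frame.velocities is not None
        # pairwise nonconcatenation by construction
        assert np.all(pairwise_linking_numbers(frame.positions, topo) == 0)

    def test_confinement_radius_from_density(self):
        # R^3 = 3 M N / (4 pi rho)
        p = SimParams(M=46, N=200, rho=0.85)
        assert p.R_sphere == pytest.approx(13.72, abs=0.005)

    def test_nonconcatenation_preserved_through_dynamics(self, small_melt):
        params, frame, topo = small_melt
        traj = run_simulation(params, n_steps=10000, output_every=5000,
                              frame0=frame, topo=topo)
        for i in range(len(traj)):
            lk = pairwise_linking_numbers(traj.positions[i], topo)
            assert np.all(lk == 0)

    def test_dilute_bond_distribution_peaks_at_combined_minimum(self):
        # a single ring in a huge sphere: the bond-length mode sits at the
        # FENE + WCA minimizer (the r^2 Jacobian shifts it < 0.01 sigma)
        p = SimParams(M=1, N=32, rho=0.01, seed=7)
        frame, topo = initialize_melt(p, ramp_steps=2000, burnin_steps=3000)
        traj = run_simulation(p, n_steps=60000, output_every=250,
                              frame0=frame, topo=topo)
        bl = np.concatenate([
            np.linalg.norm(traj.positions[i][topo.next_in_ring]
                           - traj.positions[i], axis=1)
            for i in range(len(traj) // 3, len(traj))])
        hist, edges = np.histogram(bl, bins=np.arange(0.85, 1.10, 0.01))
        c = 0.5 * (edges[:-1] + edges[1:])
        k = int(np.argmax(hist))
        coef = np.polyfit(c[max(k - 2, 0):k + 3], hist[max(k - 2, 0):k + 3], 2)
        mode = -coef[1] / (2 * coef[0])
        assert mode == pytest.approx(bond_minimum(), abs=0.01)

    def test_passive_run_with_no_hot_monomers(self, small_melt):
        params, frame, topo = small_melt
        p = params.with_(N_h=0)
        topo0 = Topology.from_params(p)
        traj = run_simulation(p, n_steps=2000, output_every=1000,
                              frame0=frame, topo=topo0, store_velocities=True)
        assert not topo0.hot_mask.any()
        t = kinetic_temperature(traj.frame(-1).velocities)
        assert 0.5 < t < 1.6  # stays near T_cold, nowhere near T_hot


class TestAngularMomentumControl:
    def test_pure_rotation_is_fully_removed(self, rng):
        pos = rng.normal(0, 2, (64, 3))
        omega = np.array([0.4, -0.1, 0.7])
        frame = Frame(time=0.0, positions=pos, box=10.0,
                      velocities=np.cross(omega, pos))
        zero_angular_momentum(frame)
        assert np.abs(frame.velocities).max() < 1e-12

    def test_random_frame_ends_with_zero_angular_momentum(self, rng):
        frame = Frame(time=0.0, positions=rng.normal(0, 2, (64, 3)), box=10.0,
                      velocities=rng.normal(0, 1, (64, 3)))
        zero_angular_momentum(frame)
        assert np.linalg.norm(angular_momentum(frame)) < 1e-10

    def test_idempotent_when_already_zero(self, rng):
        frame = Frame(time=0.0, positions=rng.normal(0, 2, (64, 3)), box=10.0,
                      velocities=rng.normal(0, 1, (64, 3)))
        zero_angular_momentum(frame)
        before = frame.velocities.copy()
        zero_angular_momentum(frame)
        assert np.allclose(frame.velocities, before, atol=1e-12)

    def test_collinear_configuration_rejected(self):
        pos = np.outer(np.arange(10.0), [1.0, 0, 0])
        frame = Frame(time=0.0, positions=pos, box=20.0,
                      velocities=np.zeros((10, 3)))
        with pytest.raises(ValueError):
            zero_angular_momentum(frame)

    def test_velocities_required(self):
        frame = Frame(time=0.0, positions=np.zeros((4, 3)), box=5.0)
        with pytest.raises(ValueError):
            zero_angular_momentum(frame)
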