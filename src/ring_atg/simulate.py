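"""Two-temperature Langevin dynamics of confined nonconcatenated ring melts.

The integrator is velocity Verlet with per-monomer Langevin friction and
noise; hot monomers couple to a bath at ``T_hot``, the rest to ``T_cold``.
Initial states are built in-package: rings start as small, mutually unlinked
circles, are inflated by a capped soft-repulsion ramp and relaxed by a short
passive burn-in, so nonconcatenation holds by construction and is verified
through pairwise Gauss linking numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .core import Frame, Topology, Trajectory
from .params import SimParams
from .potentials import BondBrokenError, MonomerEscapedError

_CHUNK = 1000  # steps integrated per engine call (noise generated per chunk)

_STATUS_ERRORS = {
    _engine.STATUS_BOND_BROKEN: BondBrokenError,
    _engine.STATUS_ESCAPED: MonomerEscapedError,
}


class InitializationError(RuntimeError):
    """Ring placement or push-off failed within the retry budget."""


@dataclass
class _Workspace:
    f: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    ref_pos: np.ndarray

    @classmethod
    def for_n(cls, n: int, cap_per_atom: int = 64) -> "_Workspace":
        return cls(
            f=np.zeros((n, 3)),
            pair_i=np.zeros(n * cap_per_atom, dtype=np.int64),
            pair_j=np.zeros(n * cap_per_atom, dtype=np.int64),
            ref_pos=np.zeros((n, 3)),
        )

    def grow(self) -> None:
        cap = 2 * self.pair_i.shape[0]
        self.pair_i = np.zeros(cap, dtype=np.int64)
        self.pair_j = np.zeros(cap, dtype=np.int64)


def _advance(pos: np.ndarray, vel: np.ndarray, topo: Topology, params: SimParams,
             n_steps: int, temps: np.ndarray, rng: np.random.Generator,
             ws: _Workspace, *, pair_style: int = _engine.PAIR_WCA,
             soft_A: tuple[float, float] = (0.0, 0.0),
             forces: Sequence[str] = ("pair", "bond", "angle", "wall"),
             gamma: Optional[float] = None, skin: float = 0.3,
             f_cap: float = 0.0, bond_style: int = _engine.BOND_FENE) -> None:
    """Integrate n_steps in place, chunking noise generation."""
    n = pos.shape[0]
    g = params.gamma_damp if gamma is None else gamma
    pref = np.sqrt(2.0 * params.mass * g * np.asarray(temps, float) / params.dt)
    bonds = topo.bonds().astype(np.int64)
    angles = topo.angle_triples().astype(np.int64)
    ring_of = topo.ring_of.astype(np.int64)
    use_pair = "pair" in forces
    use_bond = "bond" in forces
    use_angle = "angle" in forces
    use_wall = "wall" in forces
    done = 0
    while done < n_steps:
        nsub = min(_CHUNK, n_steps - done)
        if g > 0:
            noise = rng.standard_normal((nsub, n, 3))
            noise *= pref[None, :, None]
        else:
            noise = np.zeros((1, n, 3))
        a0 = soft_A[0] + (soft_A[1] - soft_A[0]) * done / max(n_steps - 1, 1)
        a1 = soft_A[0] + (soft_A[1] - soft_A[0]) * (done + nsub - 1) / max(n_steps - 1, 1)
        while True:
            status, steps = _engine.run_chunk(
                pos, vel, ws.f, nsub, params.dt, params.mass, g, noise,
                bonds, angles, ring_of, ws.pair_i, ws.pair_j, ws.ref_pos,
                params.R_sphere, params.epsilon, params.sigma,
                params.K_fene, params.r_max, params.k_theta,
                use_pair, use_bond, use_angle, use_wall,
                pair_style, a0, a1, skin, f_cap, bond_style)
            if status == _engine.STATUS_NLIST_OVERFLOW:
                ws.grow()
                continue
            break
        if status != _engine.STATUS_OK:
            exc = _STATUS_ERRORS[status]
            raise exc(
                f"integration aborted at step {done + steps}: "
                f"{'bond length >= r_max' if status == 1 else 'monomer left the sphere'}; "
                f"frame dump: max|r|={np.linalg.norm(pos, axis=1).max():.4f}, "
                f"R={params.R_sphere:.4f}")
        done += nsub


def maxwell_boltzmann_velocities(n: int, T: float, mass: float,
                                 rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3)) * math.sqrt(T / mass)
    v -= v.mean(axis=0)
    return v


def kinetic_temperature(velocities: np.ndarray, mass: float = 1.0,
                        mask: Optional[np.ndarray] = None) -> float:
    """Instantaneous kinetic temperature m <v^2> / 3 of (a subset of) monomers."""
    v = velocities if mask is None else velocities[mask]
    return float(mass * np.mean(np.sum(v * v, axis=1)) / 3.0)


def _place_ring_circles(params: SimParams, rng: np.random.Generator,
                        max_tries: int = 20000) -> np.ndarray:
    """Positions of M rings laid out as small unlinked circles.

    A pairwise center separation > 2a + gap (a the circle radius, gap beyond
    the WCA range) guarantees the circles start unlinked AND outside each
    other's interaction range, so the inter-ring WCA repulsion kept on
    during the push-off preserves nonconcatenation throughout.  The circle
    radius shrinks adaptively until the placement fits.
    """
    R = params.R_sphere
    wall_gap = min(0.8, 0.3 * R)
    gap = 1.2 * params.sigma  # > WCA cutoff: no initial inter-ring forces
    a = min(1.0 * params.sigma, 0.25 * R)
    while a >= 0.3:
        r_centers = R - a - wall_gap
        min_sep = 2.0 * a + gap
        if r_centers > 0:
            centers = _rsa_centers(params.M, r_centers, min_sep, rng, max_tries)
            if centers is not None:
                break
        a *= 0.8
    else:
        raise InitializationError(
            f"could not place {params.M} unlinked ring circles inside sphere "
            f"of radius {R:.2f} after {max_tries} attempts per radius")
    pos = np.empty((params.M * params.N, 3))
    phis = 2.0 * np.pi * np.arange(params.N) / params.N
    for r, c in enumerate(centers):
        # random orientation
        u = _random_unit(rng)
        e1 = _perp_unit(u, rng)
        e2 = np.cross(u, e1)
        ring = c[None, :] + a * (np.cos(phis)[:, None] * e1[None, :]
                                 + np.sin(phis)[:, None] * e2[None, :])
        pos[r * params.N:(r + 1) * params.N] = ring
    return pos


def _rsa_centers(M: int, r_max: float, min_sep: float,
                 rng: np.random.Generator, max_tries: int):
    """Random sequential addition of M centers in a ball; None on failure."""
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < M:
        if tries > max_tries:
            return None
        tries += 1
        c = rng.uniform(-r_max, r_max, 3)
        if np.linalg.norm(c) > r_max:
            continue
        if any(np.linalg.norm(c - o) < min_sep for o in centers):
            continue
        centers.append(c)
    return centers


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            return v / nv


def _perp_unit(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        v -= np.dot(v, u) * u
        nv = np.linalg.norm(v)
        if nv > 1e-8:
            return v / nv


def pairwise_linking_numbers(positions: np.ndarray, topo: Topology) -> np.ndarray:
    """(M, M) matrix of rounded Gauss linking numbers between all ring pairs."""
    from .threading_analysis import gauss_linking_number

    M = topo.M
    lk = np.zeros((M, M), dtype=int)
    for i in range(M):
        for j in range(i + 1, M):
            val, _ = gauss_linking_number(positions[topo.ring_slice(i)],
                                          positions[topo.ring_slice(j)])
            lk[i, j] = lk[j, i] = val
    return lk


def initialize_melt(params: SimParams, *, ramp_steps: int = 5000,
                    burnin_steps: int = 20000, soft_A_max: float = 150.0,
                    max_retries: int = 3, check_linking: bool = True,
                    hot_start: int = 0) -> tuple[Frame, Topology]:
    """Build an equilibrated-enough passive starting state.

    Rings are placed as small unlinked circles, inflated under a capped soft
    pair repulsion whose amplitude ramps to ``soft_A_max`` over
    ``ramp_steps``, then relaxed with the full WCA/FENE/bending force field
    for ``burnin_steps`` passive Langevin steps at ``T_cold``.  Velocities are
    Maxwell-Boltzmann at ``T_cold``.  Nonconcatenation is verified via Gauss
    linking numbers when ``check_linking`` is set.
    """
    topo = Topology.from_params(params, hot_start=hot_start)
    temps = np.full(params.n_monomers, params.T_cold)
    last_err: Optional[Exception] = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 100 + attempt]))
        try:
            pos = _place_ring_circles(params, rng)
            vel = maxwell_boltzmann_velocities(params.n_monomers, params.T_cold,
                                               params.mass, rng)
            ws = _Workspace.for_n(params.n_monomers)
            small = params.with_(dt=params.dt / 5.0)
            # overdamped, small-step ramp with unbreakable harmonic bonds:
            # inflation is quasi-static and cannot snap the chain
            _advance(pos, vel, topo, small, ramp_steps, temps, rng, ws,
                     gamma=5.0, f_cap=100.0, bond_style=_engine.BOND_HARMONIC,
                     pair_style=_engine.PAIR_SOFT_INTRA, soft_A=(0.0, soft_A_max))
            # remove residual overlaps under full WCA, bonds still harmonic,
            # until every bond is safely below the FENE divergence
            for _ in range(10):
                vel[:] = maxwell_boltzmann_velocities(params.n_monomers,
                                                      params.T_cold, params.mass, rng)
                _advance(pos, vel, topo, small, 2000, temps, rng, ws,
                         gamma=5.0, f_cap=200.0,
                         bond_style=_engine.BOND_HARMONIC,
                         pair_style=_engine.PAIR_WCA)
                blen = np.linalg.norm(pos[topo.next_in_ring] - pos, axis=1)
                if blen.max() < min(1.2 * params.sigma, 0.8 * params.r_max):
                    break
            else:
                raise InitializationError(
                    f"push-off left overstretched bonds (max {blen.max():.3f})")
            # hand over to FENE gently, then the passive burn-in proper
            _advance(pos, vel, topo, small, max(min(2000, burnin_steps // 4), 1),
                     temps, rng, ws, pair_style=_engine.PAIR_WCA)
            _advance(pos, vel, topo, params, burnin_steps,
                     temps, rng, ws, pair_style=_engine.PAIR_WCA)
        except (InitializationError, BondBrokenError, MonomerEscapedError) as err:
            last_err = err
            continue
        if check_linking:
            lk = pairwise_linking_numbers(pos, topo)
            if np.any(lk != 0):
                last_err = InitializationError(
                    f"concatenated ring pair after push-off (attempt {attempt}): "
                    f"{np.argwhere(lk != 0)[:4].tolist()}")
                continue
        frame = Frame(time=0.0, positions=pos, box=params.R_sphere, velocities=vel)
        frame.check(topo, params.r_max)
        return frame, topo
    raise InitializationError(f"initialization failed after {max_retries} attempts: {last_err}")


def run_simulation(params: SimParams, *, n_steps: int, output_every: int = 1000,
                   activity_start: int = 0, frame0: Optional[Frame] = None,
                   topo: Optional[Topology] = None, store_velocities: bool = False,
                   forces: Sequence[str] = ("pair", "bond", "angle", "wall"),
                   zero_L_every: int = 1000, init_kwargs: Optional[dict] = None,
                   ) -> Trajectory:
    """Run the two-temperature dynamics and collect frames at a fixed cadence.

    Steps ``0 .. activity_start`` are fully passive (every monomer at
    ``T_cold``); from ``activity_start`` on, hot monomers couple to ``T_hot``.
    With ``params.N_h == 0`` the run is a passive reference at any
    ``activity_start``.  Frames are stored every ``output_every`` steps
    (including step 0); times are in tau with t = 0 at the start of the run.
    Identical ``(params, schedule)`` give bit-identical trajectories.
    """
    if frame0 is None or topo is None:
        frame0, topo = initialize_melt(params, **(init_kwargs or {}))
    pos = frame0.positions.copy()
    vel = (frame0.velocities.copy() if frame0.velocities is not None
           else np.zeros_like(pos))
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 200]))
    ws = _Workspace.for_n(params.n_monomers)
    temps_cold = np.full(params.n_monomers, params.T_cold)
    temps_active = np.where(topo.hot_mask, params.T_hot, params.T_cold)

    frames = [Frame(time=0.0, positions=pos.copy(), box=params.R_sphere,
                    velocities=vel.copy() if store_velocities else None)]
    step = 0
    while step < n_steps:
        events = [((step // output_every) + 1) * output_every, n_steps]
        if step < activity_start:
            events.append(activity_start)
        if params.zero_Lz and zero_L_every > 0:
            events.append(((step // zero_L_every) + 1) * zero_L_every)
        target = min(events)
        temps = temps_cold if step < activity_start else temps_active
        _advance(pos, vel, topo, params, target - step, temps, rng, ws, forces=forces)
        step = target
        if params.zero_Lz and zero_L_every > 0 and step % zero_L_every == 0:
            f = Frame(time=step * params.dt, positions=pos, box=params.R_sphere,
                      velocities=vel)
            zero_angular_momentum(f)
        if step % output_every == 0 or step == n_steps:
            frames.append(Frame(time=step * params.dt, positions=pos.copy(),
                                box=params.R_sphere,
                                velocities=vel.copy() if store_velocities else None))
    return Trajectory.from_frames(frames, topo)


def langevin_step(frame: Frame, topo: Topology, params: SimParams,
                  rng: np.random.Generator, *, active: bool = True,
                  n_steps: int = 1) -> Frame:
    """Advance a frame by ``n_steps`` Langevin velocity-Verlet steps.

    Convenience single-step interface over the chunked engine; for long runs
    prefer :func:`run_simulation`.
    """
    pos = frame.positions.copy()
    vel = (frame.velocities.copy() if frame.velocities is not None
           else np.zeros_like(pos))
    temps = (np.where(topo.hot_mask, params.T_hot, params.T_cold) if active
             else np.full(pos.shape[0], params.T_cold))
    ws = _Workspace.for_n(pos.shape[0])
    _advance(pos, vel, topo, params, n_steps, temps, rng, ws)
    return Frame(time=frame.time + n_steps * params.dt, positions=pos,
                 box=frame.box, velocities=vel)


def zero_angular_momentum(frame: Frame) -> Frame:
    """Remove the rigid-body rotation about the sphere center, in place.

    The angular velocity follows from the total angular momentum and inertia
    tensor about the origin (the sphere center); subtracting omega x r zeroes
    the total angular momentum exactly.  The total linear momentum changes by
    -m_total * omega x r_cm, negligible for a melt whose center of mass sits
    near the sphere center.
    """
    if frame.velocities is None:
        raise ValueError("frame has no velocities")
    r = frame.positions
    v = frame.velocities
    L = np.sum(np.cross(r, v), axis=0)
    r2 = np.sum(r * r, axis=1)
    inertia = np.eye(3) * r2.sum() - r.T @ r
    try:
        omega = np.linalg.solve(inertia, L)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular inertia tensor (collinear configuration)") from err
    cond = np.linalg.cond(inertia)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("singular inertia tensor (collinear configuration)")
    v -= np.cross(np.broadcast_to(omega, r.shape), r)
    return frame


def angular_momentum(frame: Frame, mass: float = 1.0) -> np.ndarray:
    if frame.velocities is None:
        raise ValueError("frame has no velocities")
    return mass * np.sum(np.cross(frame.positions, frame.velocities), axis=0)


def total_energy(frame: Frame, topo: Topology, params: SimParams) -> float:
    """Kinetic plus potential energy (small systems; O(n^2) pair loop)."""
    from .potentials import total_potential_energy

    if frame.velocities is None:
        raise ValueError("frame has no velocities")
    ke = 0.5 * params.mass * float(np.sum(frame.velocities**2))
    return ke + total_potential_energy(frame.positions, topo, params)
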