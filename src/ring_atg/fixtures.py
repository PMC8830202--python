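"""Deterministic and stochastic test inputs with known ground truth.

Every generator is a pure function of its arguments (including the seed), so
all observables can be validated against closed-form or enumerable answers
without running molecular dynamics.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np

from .core import Frame, Topology, Trajectory
from .params import SimParams


def make_circle_ring(N: int, radius: float = 1.0,
                     plane: Literal["xy", "xz", "yz"] = "xy",
                     center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """N beads equally spaced on a circle; bond length 2 R sin(pi/N)."""
    if N < 3:
        raise ValueError("need N >= 3")
    phi = 2.0 * np.pi * np.arange(N) / N
    cx, sx = radius * np.cos(phi), radius * np.sin(phi)
    zeros = np.zeros(N)
    cols = {"xy": (cx, sx, zeros), "xz": (cx, zeros, sx), "yz": (zeros, cx, sx)}
    ring = np.column_stack(cols[plane]) + np.asarray(center, dtype=float)
    return ring


def make_threading_pair(kind: Literal["hopf", "thread_unlinked",
                                      "double_thread", "separated"],
                        N: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Canonical two-ring geometries with known (linking number, crossings).

    hopf            -> (1, 1): unit circles in orthogonal planes, one passing
                       through the other's center region.
    separated       -> (0, 0): far-apart coplanar circles.
    thread_unlinked -> (0, 2): a hairpin "pin" dips through the opening and
                       returns, threading without linking.
    double_thread   -> (0, 2): same topology with a wider, deeper pin whose
                       two passes pierce the spanning disk well apart.

    A closed curve unlinked from the boundary crosses any spanning disk an
    even number of times, so every threading-but-unlinked fixture has an
    even crossing count.
    """
    a = make_circle_ring(N, 1.0, "xy")
    if kind == "hopf":
        b = make_circle_ring(N, 1.0, "xz", center=(1.0, 0.0, 0.0))
    elif kind == "separated":
        b = make_circle_ring(N, 1.0, "xy", center=(5.0, 0.0, 0.0))
    elif kind in ("thread_unlinked", "double_thread"):
        # rounded-rectangle pin in the xz-plane: two vertical legs pass
        # through the unit disk (z = 0) at x = +-dx, joined above and below
        dx = 0.25 if kind == "thread_unlinked" else 0.55
        height = 1.5 if kind == "thread_unlinked" else 2.5
        n4 = max(N // 4, 4)
        leg1 = np.column_stack([np.full(n4, dx), np.zeros(n4),
                                np.linspace(-height, height, n4, endpoint=False)])
        top = np.column_stack([np.linspace(dx, -dx, n4, endpoint=False),
                               np.zeros(n4), np.full(n4, height)])
        leg2 = np.column_stack([np.full(n4, -dx), np.zeros(n4),
                                np.linspace(height, -height, n4, endpoint=False)])
        bot = np.column_stack([np.linspace(-dx, dx, n4, endpoint=False),
                               np.zeros(n4), np.full(n4, -height)])
        b = np.vstack([leg1, top, leg2, bot])
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return a, b


def make_torus_link(N: int = 200, R0: float = 2.0, r0: float = 0.8,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """The (2, 4) torus link: two curves each winding twice around the tube.

    Its components have |Lk| = 2.
    """
    t = 2.0 * np.pi * np.arange(N) / N
    rings = []
    for phase in (0.0, np.pi):
        w = 2.0 * t + phase
        x = (R0 + r0 * np.cos(w)) * np.cos(t)
        y = (R0 + r0 * np.cos(w)) * np.sin(t)
        z = r0 * np.sin(w)
        rings.append(np.column_stack([x, y, z]))
    return rings[0], rings[1]


def make_rigid_motion_trajectory(frame: Frame, topo: Topology, *,
                                 motion: Literal["rotation", "translation"],
                                 rate: float, n_frames: int,
                                 dt_frame: float = 1.0,
                                 axis=(0.0, 0.0, 1.0),
                                 with_velocities: bool = False) -> Trajectory:
    """Apply a cumulative isometry to a frame: rigid rotation or translation.

    ``rate`` is the angular velocity (rad/tau) about ``axis`` through the
    origin, or the translation speed (sigma/tau) along ``axis``.  Velocities,
    when requested, are the exact rigid-motion velocities.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    times = frame.time + dt_frame * np.arange(n_frames)
    pos = np.empty((n_frames, frame.n_monomers, 3))
    vel = np.empty_like(pos) if with_velocities else None
    for k in range(n_frames):
        if motion == "rotation":
            ang = rate * dt_frame * k
            Rm = _rotation_matrix(axis, ang)
            pos[k] = frame.positions @ Rm.T
            if with_velocities:
                vel[k] = np.cross(rate * axis, pos[k])
        elif motion == "translation":
            pos[k] = frame.positions + rate * dt_frame * k * axis
            if with_velocities:
                vel[k] = np.broadcast_to(rate * axis, pos[k].shape)
        else:
            raise ValueError(f"unknown motion {motion!r}")
    return Trajectory(times=times, positions=pos, topology=topo,
                      box=frame.box, velocities=vel)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(angle * axis).as_matrix()


def make_gaussian_ring_ensemble(N: int, b: float, n_samples: int,
                                seed: int = 0) -> np.ndarray:
    """(n_samples, N, 3) closed Brownian-bridge random walks.

    Bond vectors are i.i.d. Gaussians with total variance b^2 conditioned on
    ring closure, giving the exact internal-distance law
    <d^2(s)> = b^2 s (N - s) / N.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    steps = rng.standard_normal((n_samples, N, 3)) * (b / math.sqrt(3.0))
    steps -= steps.mean(axis=1, keepdims=True)  # condition on closure
    pos = np.cumsum(steps, axis=1)
    return pos - pos.mean(axis=1, keepdims=True)


def gaussian_ring_internal_d2(N: int, b: float, s) -> np.ndarray:
    """Closed form <d^2(s)> = b^2 s (N - s) / N of the Gaussian ring."""
    s = np.asarray(s, dtype=float)
    return b * b * s * (N - s) / N


def gaussian_ring_contact_probability(N: int, b: float, s, cutoff: float,
                                      ) -> np.ndarray:
    """P(|d(s)| < cutoff) for the Gaussian ring (chi-square closed form)."""
    from scipy.stats import chi2

    var_per_comp = gaussian_ring_internal_d2(N, b, s) / 3.0
    return chi2.cdf(cutoff**2 / var_per_comp, df=3)


def make_random_mixture(M: int, N: int, hot_fraction: float = 0.125,
                        density: float = 0.85, seed: int = 0, *,
                        contiguous: bool = False,
                        ) -> tuple[Frame, Topology]:
    """Random positions in a sphere at the given density with typed monomers.

    With ``contiguous`` the hot labels form one block of round(hot_fraction*N)
    monomers per ring (the melt layout); otherwise each monomer is hot
    independently with probability ``hot_fraction`` (well-mixed baseline for
    the binomial like-neighbor oracle).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 57]))
    n = M * N
    R = (3.0 * n / (4.0 * np.pi * density)) ** (1.0 / 3.0)
    pos = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-R, R, (2 * (n - got) + 16, 3))
        keep = cand[np.sum(cand * cand, axis=1) < R * R][: n - got]
        pos[got : got + len(keep)] = keep
        got += len(keep)
    if contiguous:
        n_h = int(round(hot_fraction * N))
        mask = np.zeros(n, dtype=bool)
        for r in range(M):
            mask[r * N : r * N + n_h] = True
    else:
        mask = rng.random(n) < hot_fraction
    topo = Topology(M=M, N=N, hot_mask=mask)
    frame = Frame(time=0.0, positions=pos, box=R)
    return frame, topo


def uniform_sphere_points(n: int, R: float, seed: int = 0) -> np.ndarray:
    """n points uniformly distributed in a ball of radius R."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-R, R, (2 * (n - got) + 16, 3))
        keep = cand[np.sum(cand * cand, axis=1) < R * R][: n - got]
        pts[got : got + len(keep)] = keep
        got += len(keep)
    return pts
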