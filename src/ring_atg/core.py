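"""In-memory containers: ring topology, single frames, trajectories."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .params import SimParams


@dataclass
class Topology:
    """Connectivity and activity labels of a melt of M rings of N beads.

    Monomers are stored ring by ring, in contour order within each ring, so
    monomer ``r * N + i`` is bead ``i`` of ring ``r`` and its circular
    successor is ``r * N + (i + 1) % N``.
    """

    M: int
    N: int
    hot_mask: np.ndarray  # (M*N,) bool

    def __post_init__(self) -> None:
        self.hot_mask = np.asarray(self.hot_mask, dtype=bool)
        if self.hot_mask.shape != (self.M * self.N,):
            raise ValueError("hot_mask must have one entry per monomer")

    @classmethod
    def from_params(cls, params: SimParams, hot_start: int = 0) -> "Topology":
        """Hot labels on the contiguous block [hot_start, hot_start + N_h) of each ring."""
        mask = np.zeros(params.M * params.N, dtype=bool)
        for r in range(params.M):
            idx = (hot_start + np.arange(params.N_h)) % params.N
            mask[r * params.N + idx] = True
        return cls(M=params.M, N=params.N, hot_mask=mask)

    @property
    def n_monomers(self) -> int:
        return self.M * self.N

    @property
    def N_h(self) -> int:
        return int(self.hot_mask[: self.N].sum())

    @property
    def ring_of(self) -> np.ndarray:
        return np.repeat(np.arange(self.M), self.N)

    @property
    def next_in_ring(self) -> np.ndarray:
        nxt = np.arange(self.n_monomers) + 1
        nxt[self.N - 1 :: self.N] -= self.N
        return nxt

    def bonds(self) -> np.ndarray:
        """(M*N, 2) array of bonded index pairs (i, successor of i)."""
        return np.column_stack([np.arange(self.n_monomers), self.next_in_ring])

    def angle_triples(self) -> np.ndarray:
        """(M*N, 3) array (prev, center, next) for every bead of every ring."""
        i = np.arange(self.n_monomers)
        nxt = self.next_in_ring
        prv = np.empty_like(nxt)
        prv[nxt] = i
        return np.column_stack([prv, i, nxt])

    def ring_slice(self, r: int) -> slice:
        return slice(r * self.N, (r + 1) * self.N)

    def hot_segment_center(self, r: int) -> int:
        """Local index (0..N-1) of the midpoint of ring r's hot block."""
        local = self.hot_mask[self.ring_slice(r)]
        n_h = int(local.sum())
        if n_h == 0:
            raise ValueError(f"ring {r} has no hot monomers")
        # the block is contiguous on the cycle; find its start
        idx = np.flatnonzero(local)
        if n_h == self.N:
            return 0
        start = idx[0]
        for j in idx:
            if not local[(j - 1) % self.N]:
                start = j
                break
        return int((start + n_h // 2) % self.N)

    def validate(self) -> None:
        per_ring = self.hot_mask.reshape(self.M, self.N)
        counts = per_ring.sum(axis=1)
        if len(set(counts.tolist())) > 1:
            raise ValueError("rings carry different numbers of hot labels")
        for r in range(self.M):
            local = per_ring[r]
            n_h = int(local.sum())
            if n_h in (0, self.N):
                continue
            # contiguity on the cycle: exactly one False->True transition
            trans = int(np.sum(~local & np.roll(local, -1)))
            if trans != 1:
                raise ValueError(f"hot block of ring {r} is not contiguous")


@dataclass
class Frame:
    """Snapshot of the melt: positions (and optionally velocities) at one time."""

    time: float
    positions: np.ndarray  # (M*N, 3), sigma
    box: float  # confinement sphere radius, sigma
    velocities: Optional[np.ndarray] = None  # (M*N, 3), sigma/tau

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)

    @property
    def n_monomers(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            time=self.time,
            positions=self.positions.copy(),
            box=self.box,
            velocities=None if self.velocities is None else self.velocities.copy(),
        )

    def check(self, topo: Topology, r_max: float = 1.5) -> None:
        """Assert confinement and bond-length invariants."""
        r = np.linalg.norm(self.positions, axis=1)
        if not np.all(r < self.box):
            raise ValueError("monomer escaped: |position| >= sphere radius")
        b = self.positions[topo.next_in_ring] - self.positions
        blen = np.linalg.norm(b, axis=1)
        if not np.all(blen < r_max):
            raise ValueError("broken bond: bonded distance >= r_max")


@dataclass
class Trajectory:
    """Time-ordered stack of frames sharing one topology and sphere radius."""

    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, M*N, 3)
    topology: Topology
    box: float
    velocities: Optional[np.ndarray] = None  # (T, M*N, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("positions must be (T, n, 3) matching times")
        if np.any(np.diff(self.times) <= 0) and len(self.times) > 1:
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def frame(self, i: int) -> Frame:
        return Frame(
            time=float(self.times[i]),
            positions=self.positions[i],
            box=self.box,
            velocities=None if self.velocities is None else self.velocities[i],
        )

    def __iter__(self) -> Iterator[Frame]:
        for i in range(len(self)):
            yield self.frame(i)

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "Trajectory":
        """Sub-trajectory with t_min <= t <= t_max."""
        sel = (self.times >= t_min) & (self.times <= t_max)
        if not np.any(sel):
            raise ValueError("empty frame selection")
        return Trajectory(
            times=self.times[sel],
            positions=self.positions[sel],
            topology=self.topology,
            box=self.box,
            velocities=None if self.velocities is None else self.velocities[sel],
        )

    def ring_positions(self, i: int, r: int) -> np.ndarray:
        """(N, 3) positions of ring r in frame i."""
        return self.positions[i, self.topology.ring_slice(r)]

    @classmethod
    def from_frames(cls, frames: list[Frame], topology: Topology) -> "Trajectory":
        if not frames:
            raise ValueError("no frames")
        has_vel = all(f.velocities is not None for f in frames)
        return cls(
            times=np.array([f.time for f in frames]),
            positions=np.stack([f.positions for f in frames]),
            topology=topology,
            box=frames[0].box,
            velocities=np.stack([f.velocities for f in frames]) if has_vel else None,
        )
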