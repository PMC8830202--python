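"""Model parameters in reduced Lennard-Jones units.

Lengths are measured in the bead diameter sigma, energies in epsilon, masses
in the bead mass m, and times in tau = sigma * sqrt(m / epsilon).  Boltzmann's
constant is 1, so temperatures are quoted in units of epsilon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from typing import Optional


@dataclass(frozen=True)
class SimParams:
    """All model constants of the confined active ring-melt model.

    The melt consists of ``M`` nonconcatenated, unknotted ring polymers of
    ``N`` Kremer-Grest beads each, confined in a repulsive sphere whose radius
    follows from the total monomer density ``rho``.  A contiguous block of
    ``N_h`` monomers per ring (default ``N // 8``) is coupled to a Langevin
    bath at ``T_hot`` while the rest stays at ``T_cold``.

    Parameters
    ----------
    M, N : int
        Number of rings and monomers per ring.
    N_h : int, optional
        Hot (active) monomers per ring; defaults to ``N // 8``.
    K_fene, r_max : float
        FENE bond strength (epsilon/sigma^2) and maximum extension (sigma).
    k_theta : float
        Bending stiffness (epsilon); the default 1.5 corresponds to an
        entanglement length of about 28 beads at rho = 0.85 sigma^-3.
    rho : float
        Total monomer number density (sigma^-3) fixing the sphere radius.
    T_cold, T_hot : float
        Bath temperatures (epsilon) of the passive and active blocks.
    gamma_damp : float
        Langevin friction *rate* (tau^-1).
    dt : float
        Velocity-Verlet time step (tau).
    zero_Lz : bool
        Periodically remove the global rigid-body rotation.  Off by default:
        the active steady state develops physical coherent rotations that the
        removal would mask; switch on only for equilibrium reference runs.
    seed : int
        Master RNG seed; every stochastic element derives from it.
    """

    M: int = 10
    N: int = 100
    N_h: Optional[int] = None
    epsilon: float = 1.0
    sigma: float = 1.0
    mass: float = 1.0
    K_fene: float = 30.0
    r_max: float = 1.5
    k_theta: float = 1.5
    rho: float = 0.85
    T_cold: float = 1.0
    T_hot: float = 3.0
    gamma_damp: float = 2.0 / 3.0
    dt: float = 0.005
    zero_Lz: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N_h is None:
            object.__setattr__(self, "N_h", self.N // 8)
        if self.M < 1 or self.N < 3:
            raise ValueError("need M >= 1 rings of N >= 3 monomers")
        if not 0 <= self.N_h <= self.N:
            raise ValueError(f"N_h={self.N_h} must lie in [0, N={self.N}]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    @property
    def n_monomers(self) -> int:
        return self.M * self.N

    @property
    def R_sphere(self) -> float:
        """Confinement radius: sphere volume holds M*N monomers at density rho."""
        return confinement_radius(self.M, self.N, self.rho, self.sigma)

    @property
    def wca_cutoff(self) -> float:
        return 2.0 ** (1.0 / 6.0) * self.sigma

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def confinement_radius(M: int, N: int, rho: float = 0.85, sigma: float = 1.0) -> float:
    """Radius R (sigma) with R^3 = 3 M N / (4 pi rho)."""
    return (3.0 * M * N / (4.0 * math.pi * rho)) ** (1.0 / 3.0) * sigma


def entanglement_number(N: int, N_e: int = 28) -> int:
    """Entanglement number Z = N / N_e (truncated to whole entanglements)."""
    return N // N_e
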