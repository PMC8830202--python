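"""Interaction energies and forces of the model as pure functions of geometry.

All interactions are the standard semiflexible Kremer-Grest set: a purely
repulsive, cut-and-shifted Lennard-Jones (WCA) pair potential, FENE bonds,
a cosine bending potential U = k_theta * (1 + cos theta) that vanishes for a
straight trimer, and the same WCA barrier acting between each monomer and the
confining sphere.  Everything is in reduced LJ units.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np

from .params import SimParams

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class BondBrokenError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension r_max."""


class MonomerEscapedError(RuntimeError):
    """A monomer left the confining sphere."""


def wca_energy_force(r, params: SimParams = SimParams()) -> Tuple[np.ndarray, np.ndarray]:
    """WCA pair energy and radial force -dU/dr at separation(s) ``r``.

    U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps for r < 2^(1/6) sigma,
    exactly zero beyond the cutoff.  The returned force is positive
    (repulsive) inside the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("WCA requires r > 0")
    eps, sig = params.epsilon, params.sigma
    rc = WCA_CUTOFF * sig
    inside = r < rc
    sr6 = np.where(inside, (sig / np.where(inside, r, rc)) ** 6, 0.0)
    sr12 = sr6 * sr6
    energy = np.where(inside, 4.0 * eps * (sr12 - sr6) + eps, 0.0)
    force = np.where(inside, 24.0 * eps * (2.0 * sr12 - sr6) / np.where(inside, r, rc), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def fene_energy_force(r, params: SimParams = SimParams()) -> Tuple[np.ndarray, np.ndarray]:
    """FENE bond energy and radial force -dU/dr at bond length(s) ``r``.

    U(r) = -(1/2) K r_max^2 ln(1 - (r/r_max)^2); the force is attractive and
    diverges as r -> r_max.  Raises :class:`BondBrokenError` at r >= r_max
    rather than returning NaN.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    K, rmax = params.K_fene, params.r_max
    if np.any(r >= rmax):
        raise BondBrokenError(f"bond length >= r_max = {rmax}")
    x2 = (r / rmax) ** 2
    energy = -0.5 * K * rmax**2 * np.log1p(-x2)
    force = -K * r / (1.0 - x2)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


def bond_minimum(params: SimParams = SimParams()) -> float:
    """Bond length minimizing the combined FENE + WCA bond energy."""
    from scipy.optimize import minimize_scalar

    def u(r: float) -> float:
        return fene_energy_force(r, params)[0] + wca_energy_force(r, params)[0]

    res = minimize_scalar(u, bounds=(0.5 * params.sigma, 0.999 * params.r_max), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def bending_energy_force(a, b, c, params: SimParams = SimParams()):
    """Bending energy and forces for the trimer (a, b, c) with center bead b.

    U = k_theta (1 + cos theta) with theta the bond angle at b, so a straight
    trimer (theta = pi) has zero energy and a fully folded one 2 k_theta.
    Returns ``(energy, (F_a, F_b, F_c))``; the three forces sum to zero.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    k = params.k_theta
    u = a - b
    v = c - b
    lu = np.linalg.norm(u)
    lv = np.linalg.norm(v)
    if lu == 0 or lv == 0:
        raise ValueError("degenerate trimer: coincident bonded beads")
    cth = float(np.clip(np.dot(u, v) / (lu * lv), -1.0, 1.0))
    energy = k * (1.0 + cth)
    dcos_da = (v / lv - cth * u / lu) / lu
    dcos_dc = (u / lu - cth * v / lv) / lv
    f_a = -k * dcos_da
    f_c = -k * dcos_dc
    f_b = -(f_a + f_c)
    return energy, (f_a, f_b, f_c)


def bending_energy(theta, params: SimParams = SimParams()):
    """U = k_theta (1 + cos theta) for bond angle(s) theta (straight = pi)."""
    theta = np.asarray(theta, dtype=float)
    e = params.k_theta * (1.0 + np.cos(theta))
    return float(e) if e.ndim == 0 else e


def wall_energy_force(pos, params: SimParams) -> Tuple[float, np.ndarray]:
    """Confining-sphere energy and force vector on a monomer at ``pos``.

    The wall is a smooth, structureless, purely repulsive barrier applying
    the WCA potential to d = R_sphere - |pos|, the distance from the monomer
    center to the sphere; the force points toward the sphere center.
    """
    pos = np.asarray(pos, dtype=float)
    R = params.R_sphere
    rnorm = float(np.linalg.norm(pos))
    if rnorm >= R:
        raise MonomerEscapedError(f"|pos| = {rnorm:.6g} >= R_sphere = {R:.6g}")
    d = R - rnorm
    e, f = wca_energy_force(d, params)
    if rnorm == 0.0:
        return float(e), np.zeros(3)
    return float(e), -f * pos / rnorm


def total_potential_energy(positions: np.ndarray, topo, params: SimParams) -> float:
    """Total WCA + FENE + bending + wall energy of a configuration.

    O(n^2) pair loop; intended for validation on small systems.
    """
    n = positions.shape[0]
    rc = params.wca_cutoff
    d = positions[:, None, :] - positions[None, :, :]
    r = np.sqrt((d**2).sum(-1))
    iu = np.triu_indices(n, 1)
    rr = r[iu]
    close = rr < rc
    e_pair = float(wca_energy_force(rr[close], params)[0].sum()) if np.any(close) else 0.0
    bonds = topo.bonds()
    blen = np.linalg.norm(positions[bonds[:, 1]] - positions[bonds[:, 0]], axis=1)
    e_bond = float(np.sum(fene_energy_force(blen, params)[0]))
    # bonded pairs also interact via WCA (already included in the pair loop)
    e_ang = 0.0
    for p, i, nx in topo.angle_triples():
        e_ang += bending_energy_force(positions[p], positions[i], positions[nx], params)[0]
    e_wall = 0.0
    for i in range(n):
        e_wall += wall_energy_force(positions[i], params)[0]
    return e_pair + e_bond + e_ang + e_wall
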