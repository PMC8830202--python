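"""Steady-state conformational observables of ring melts.

Size and shape (gyration tensor, spanning distance), contact probability
P(s), mean-square internal distances <d^2(s)>, and log-log power-law
exponent fits.  Averaging for summary tables is time-average per ring first,
then ring-average, with standard errors from ring-to-ring scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .core import Topology, Trajectory

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


@dataclass
class ShapeRecord:
    """Shape summary of one ring in one frame (sigma^2 units)."""

    ring: int
    R_g2: float
    lambda1: float
    lambda2: float
    lambda3: float
    R_ee2: float


def gyration_tensor(ring: np.ndarray) -> tuple[float, float, float, float]:
    """(R_g^2, lambda1, lambda2, lambda3) of one ring, eigenvalues descending.

    G_ab = (1/N) sum (r_a - <r>_a)(r_b - <r>_b); the trace equals R_g^2.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.shape[0] < 2:
        raise ValueError("need at least 2 monomers")
    d = ring - ring.mean(axis=0)
    g = d.T @ d / ring.shape[0]
    lam = np.sort(np.linalg.eigvalsh(g))[::-1]
    lam = np.clip(lam, 0.0, None)
    return float(lam.sum()), float(lam[0]), float(lam[1]), float(lam[2])


def spanning_distance_sq(ring: np.ndarray) -> float:
    """Mean over all reference monomers i of |r_i - r_{i+N/2}|^2."""
    ring = np.asarray(ring, dtype=float)
    half = ring.shape[0] // 2
    d = ring - np.roll(ring, -half, axis=0)
    return float(np.mean(np.sum(d * d, axis=1)))


def shape_records(traj: Trajectory, t_min: float = -np.inf) -> list[ShapeRecord]:
    """Time-averaged shape record per ring over frames with t >= t_min."""
    topo = traj.topology
    sel = traj.times >= t_min
    if not np.any(sel):
        raise ValueError("empty frame selection")
    out = []
    for r in range(topo.M):
        acc = np.zeros(5)
        cnt = 0
        for i in np.flatnonzero(sel):
            ring = traj.ring_positions(i, r)
            rg2, l1, l2, l3 = gyration_tensor(ring)
            acc += (rg2, l1, l2, l3, spanning_distance_sq(ring))
            cnt += 1
        acc /= cnt
        out.append(ShapeRecord(ring=r, R_g2=acc[0], lambda1=acc[1],
                               lambda2=acc[2], lambda3=acc[3], R_ee2=acc[4]))
    return out


def shape_summary(traj: Trajectory, t_min: float = -np.inf) -> pd.DataFrame:
    """Ring-averaged shape table with standard errors from ring scatter."""
    recs = shape_records(traj, t_min)
    df = pd.DataFrame([r.__dict__ for r in recs]).set_index("ring")
    M = len(df)
    mean = df.mean()
    se = df.std(ddof=1) / np.sqrt(M) if M > 1 else df.std(ddof=0) * 0.0
    return pd.DataFrame({"mean": mean, "se": se})


def _segment_type_ok(hot: np.ndarray, s: int,
                     type_filter: Literal["all", "hot", "cold"]) -> np.ndarray:
    """Boolean mask over start monomers i for segments (i, i+s)."""
    if type_filter == "all":
        return np.ones(hot.shape[0], dtype=bool)
    end = np.roll(hot, -s)
    if type_filter == "hot":
        return hot & end
    if type_filter == "cold":
        return ~hot & ~end
    raise ValueError(f"unknown type_filter {type_filter!r}")


def contact_probability(traj: Trajectory, *, cutoff: float = WCA_CUTOFF,
                        t_min: float = -np.inf,
                        type_filter: Literal["all", "hot", "cold"] = "all",
                        ) -> pd.DataFrame:
    """P(s): fraction of segments of contour length s with endpoints in contact.

    For each s = 1..N/2, the fraction of (frame, ring, start monomer) triples
    with |r_i - r_{i+s}| below ``cutoff``, averaged over the segment position
    within the ring and over rings.  ``type_filter`` restricts to segments
    whose BOTH endpoints are hot (or cold), so the hot curve extends to
    s = N_h at most.
    """
    d2, counts, svals = _internal_d2_counts(traj, t_min, type_filter, cutoff=cutoff)
    ok = counts > 0
    return pd.DataFrame({"s": svals[ok], "P": d2[ok] / counts[ok],
                         "n": counts[ok]})


def internal_distance_sq(traj: Trajectory, *, t_min: float = -np.inf,
                         type_filter: Literal["all", "hot", "cold"] = "all",
                         nu: float = 0.588) -> pd.DataFrame:
    """<d^2(s)> for s = 1..N/2, plus the rescaled profile d2 * s^(-2 nu) / <R_ee^2>.

    The rescaled column divides by the trajectory's mean spanning distance,
    making the self-avoiding-walk regime appear as a plateau.
    """
    d2, counts, svals = _internal_d2_counts(traj, t_min, type_filter, cutoff=None)
    ok = counts > 0
    d2m = d2[ok] / counts[ok]
    sv = svals[ok]
    ree2 = np.mean([spanning_distance_sq(traj.ring_positions(i, r))
                    for i in np.flatnonzero(traj.times >= t_min)
                    for r in range(traj.topology.M)])
    return pd.DataFrame({"s": sv, "d2": d2m,
                         "d2_rescaled": d2m * sv**(-2.0 * nu) / ree2,
                         "n": counts[ok]})


def _internal_d2_counts(traj: Trajectory, t_min: float,
                        type_filter: str, cutoff: Optional[float]):
    """Accumulate sum of d^2 (or contact indicators) and counts per s <= N/2."""
    topo = traj.topology
    N = topo.N
    half = N // 2
    svals = np.arange(1, half + 1)
    acc = np.zeros(half)
    counts = np.zeros(half)
    frames = np.flatnonzero(traj.times >= t_min)
    if frames.size == 0:
        raise ValueError("empty frame selection")
    for i in frames:
        for r in range(topo.M):
            ring = traj.ring_positions(i, r)
            hot = topo.hot_mask[topo.ring_slice(r)]
            for k, s in enumerate(svals):
                mask = _segment_type_ok(hot, s, type_filter)
                if not np.any(mask):
                    continue
                d = ring - np.roll(ring, -s, axis=0)
                dist2 = np.sum(d * d, axis=1)[mask]
                if cutoff is None:
                    acc[k] += dist2.sum()
                else:
                    acc[k] += np.count_nonzero(dist2 < cutoff * cutoff)
                counts[k] += dist2.size
    return acc, counts, svals


def fit_scaling_exponent(s: np.ndarray, y: np.ndarray,
                         window: tuple[float, float]) -> tuple[float, float]:
    """Least-squares slope of log y vs log s within the s-window.

    Returns (exponent, standard error).  Requires >= 5 points with positive
    values inside the window.
    """
    s = np.asarray(s, dtype=float)
    y = np.asarray(y, dtype=float)
    sel = (s >= window[0]) & (s <= window[1])
    if sel.sum() < 5:
        raise ValueError(f"need >= 5 points in window, got {int(sel.sum())}")
    if np.any(y[sel] <= 0) or np.any(s[sel] <= 0):
        raise ValueError("non-positive values in fit window")
    x = np.log(s[sel])
    z = np.log(y[sel])
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, z, rcond=None)
    n = len(x)
    if n > 2 and res.size:
        s2 = res[0] / (n - 2)
        sxx = np.sum((x - x.mean()) ** 2)
        se = float(np.sqrt(s2 / sxx))
    else:
        se = 0.0
    return float(coef[0]), se
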