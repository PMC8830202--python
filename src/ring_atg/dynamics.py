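"""Steady-state dynamic observables: MSDs, autocorrelations, coherent motion.

g3 is the mean-square displacement of ring centers of mass in the frame of
the instantaneous global center of mass; g3_rel, built from scalar COM-COM
distances, is invariant under global rotations and isolates genuine relative
rearrangement.  The terminal autocorrelation function (TACF) follows the
unit vector joining monomers half a ring apart; C_s(r; dt) correlates
monomer displacement vectors as a function of their initial separation, and
L_corr integrates its normalized profile into a coherence length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Trajectory


@dataclass
class CorrelationSeries:
    """Lag- or distance-binned statistic with per-bin sample counts."""

    abscissa: np.ndarray
    value: np.ndarray
    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self, xname: str = "x", yname: str = "y") -> pd.DataFrame:
        return pd.DataFrame({xname: self.abscissa, yname: self.value,
                             "n": self.counts})


def _steady_frames(traj: Trajectory, t0: float) -> np.ndarray:
    idx = np.flatnonzero(traj.times >= t0)
    if idx.size < 2:
        raise ValueError("fewer than 2 frames in the steady-state window")
    return idx


def ring_centers(traj: Trajectory) -> np.ndarray:
    """(T, M, 3) centers of mass of each ring (equal monomer masses)."""
    T = len(traj)
    M, N = traj.topology.M, traj.topology.N
    return traj.positions.reshape(T, M, N, 3).mean(axis=2)


def g3(traj: Trajectory, t0: float = 0.0) -> CorrelationSeries:
    """MSD of ring COMs relative to the instantaneous global center of mass.

    <|R_i(t' + dt) - R_i(t')|^2> over rings i and all start times t' >= t0.
    A uniform translation of the whole system contributes exactly zero.
    """
    idx = _steady_frames(traj, t0)
    com = ring_centers(traj)[idx]
    com = com - traj.positions[idx].mean(axis=1, keepdims=True)
    return _msd_from_series(com, traj.times[idx])


def _msd_from_series(x: np.ndarray, times: np.ndarray) -> CorrelationSeries:
    T = x.shape[0]
    lags = np.arange(1, T)
    vals = np.empty(T - 1)
    cnts = np.empty(T - 1, dtype=int)
    for k in lags:
        d = x[k:] - x[:-k]
        vals[k - 1] = np.mean(np.sum(d * d, axis=-1))
        cnts[k - 1] = d.shape[0] * (d.shape[1] if d.ndim == 3 else 1)
    return CorrelationSeries(abscissa=times[1:] - times[0], value=vals,
                             counts=cnts, meta={"kind": "msd"})


def g3_rel(traj: Trajectory, t0: float = 0.0) -> CorrelationSeries:
    """Relative MSD: <(d_ij(t' + dt) - d_ij(t'))^2> over all ring pairs.

    d_ij is the scalar COM-COM distance, so the observable is exactly
    invariant under rigid rotations and translations of every frame.
    """
    if traj.topology.M < 2:
        raise ValueError("need at least 2 rings")
    idx = _steady_frames(traj, t0)
    com = ring_centers(traj)[idx]
    iu, ju = np.triu_indices(traj.topology.M, 1)
    d = np.linalg.norm(com[:, iu] - com[:, ju], axis=-1)  # (T, n_pairs)
    T = d.shape[0]
    lags = np.arange(1, T)
    vals = np.empty(T - 1)
    cnts = np.empty(T - 1, dtype=int)
    for k in lags:
        dd = d[k:] - d[:-k]
        vals[k - 1] = np.mean(dd * dd)
        cnts[k - 1] = dd.size
    return CorrelationSeries(abscissa=traj.times[idx][1:] - traj.times[idx][0],
                             value=vals, counts=cnts, meta={"kind": "g3_rel"})


@dataclass
class TacfResult:
    series: CorrelationSeries
    tau_trapezoid: float
    tau_with_tail: float
    lower_bound_flag: bool


def tacf(traj: Trajectory, t0: float = 0.0) -> TacfResult:
    """Terminal autocorrelation <u(t).u(0)> of the N/2-spanning unit vector.

    u is the unit vector joining monomers i and i + N/2, averaged over all i
    within each ring, over rings, and over start times.  tau_uu integrates
    the lag curve by trapezoid up to the first sustained zero crossing; an
    exponential tail fitted to the last decaying stretch extends it beyond
    the window.  If the TACF never decays below 1/e the integral is flagged
    as a lower bound.
    """
    topo = traj.topology
    idx = _steady_frames(traj, t0)
    N = topo.N
    half = N // 2
    pos = traj.positions[idx].reshape(idx.size, topo.M, N, 3)
    u = pos - np.roll(pos, -half, axis=2)
    norm = np.linalg.norm(u, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    u = u / norm
    T = idx.size
    vals = np.empty(T)
    cnts = np.empty(T, dtype=int)
    vals[0] = 1.0
    cnts[0] = u[0].size // 3 * T
    for k in range(1, T):
        dot = np.sum(u[k:] * u[:-k], axis=-1)
        vals[k] = dot.mean()
        cnts[k] = dot.size
    lag = traj.times[idx] - traj.times[idx][0]
    series = CorrelationSeries(abscissa=lag, value=vals, counts=cnts,
                               meta={"kind": "tacf"})
    tau_trap, tau_tail, flagged = _integrate_acf(lag, vals)
    return TacfResult(series=series, tau_trapezoid=tau_trap,
                      tau_with_tail=tau_tail, lower_bound_flag=flagged)


def _first_sustained_nonpositive(vals: np.ndarray, run: int = 3) -> Optional[int]:
    nonpos = vals <= 0
    for i in range(len(vals) - run + 1):
        if nonpos[i : i + run].all():
            return i
    return None


def _integrate_acf(lag: np.ndarray, vals: np.ndarray) -> tuple[float, float, bool]:
    cut = _first_sustained_nonpositive(vals)
    end = len(vals) if cut is None else cut + 1
    tau_trap = float(np.trapezoid(vals[:end], lag[:end]))
    flagged = bool(vals.min() > np.exp(-1.0))
    tau_tail = tau_trap
    if cut is None and not flagged:
        # exponential-tail extrapolation from the last decaying stretch
        pos = vals > 0
        tail = np.flatnonzero(pos)[-max(3, len(vals) // 5):]
        if len(tail) >= 3 and vals[tail[-1]] < vals[tail[0]]:
            y = np.log(vals[tail])
            x = lag[tail]
            slope = np.polyfit(x, y, 1)[0]
            if slope < 0:
                tau_tail = tau_trap + vals[tail[-1]] * (-1.0 / slope)
    elif flagged:
        tau_tail = tau_trap  # lower bound: window length scale
    return tau_trap, tau_tail, flagged


def scalar_autocorrelation(series: np.ndarray, times: Optional[np.ndarray] = None,
                           ) -> CorrelationSeries:
    """Normalized ACF of per-ring scalar series (e.g. R_g^2(t) or d_ee^2(t)).

    ``series`` is (T,) or (T, M); each column is mean-subtracted, the lag
    products are averaged over columns and start times, and the result is
    normalized to 1 at zero lag.  Zero variance raises.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    T = y.shape[0]
    dy = y - y.mean(axis=0, keepdims=True)
    var = np.mean(dy * dy)
    if var == 0:
        raise ValueError("zero-variance series has no normalized ACF")
    vals = np.empty(T)
    cnts = np.empty(T, dtype=int)
    for k in range(T):
        prod = dy[k:] * dy[: T - k]
        vals[k] = prod.mean() / var
        cnts[k] = prod.size
    x = np.arange(T, dtype=float) if times is None else np.asarray(times) - times[0]
    return CorrelationSeries(abscissa=x, value=vals, counts=cnts,
                             meta={"kind": "acf"})


def rg2_series(traj: Trajectory) -> np.ndarray:
    """(T, M) squared radius of gyration of each ring over time."""
    T = len(traj)
    M, N = traj.topology.M, traj.topology.N
    pos = traj.positions.reshape(T, M, N, 3)
    d = pos - pos.mean(axis=2, keepdims=True)
    return np.mean(np.sum(d * d, axis=-1), axis=-1)


def displacement_correlation(traj: Trajectory, lag: int, *,
                             t0: float = 0.0, bin_width: float = 0.6,
                             r_min: float = 0.6, r_max: Optional[float] = None,
                             stride: int = 1, monomer_stride: int = 1,
                             ) -> CorrelationSeries:
    """Spatiotemporal displacement correlation C_s(r; dt) and its normalization.

    C_s(r; dt) = <dr_i . dr_j> over ordered pairs i != j whose separation at
    the start time falls in the r-bin, averaged over start frames (every
    ``stride``-th frame in the steady window that still has a partner
    ``lag`` frames later).  The returned series carries the raw profile; the
    normalized profile (divided by the first populated bin, centered at
    r_min + bin_width/2) is in ``meta["normalized"]``.  ``monomer_stride``
    subsamples monomers uniformly, which leaves the estimator unbiased.
    """
    idx = _steady_frames(traj, t0)
    if lag < 1 or lag >= idx.size:
        raise ValueError(f"lag must be in [1, {idx.size - 1}] frames")
    if r_max is None:
        r_max = 2.0 * traj.box
    edges = np.arange(r_min, r_max + bin_width, bin_width)
    nb = len(edges) - 1
    acc = np.zeros(nb)
    cnt = np.zeros(nb, dtype=np.int64)
    starts = idx[: idx.size - lag : stride]
    for a, i in enumerate(starts):
        j = idx[np.flatnonzero(idx == i)[0] + lag]
        p = traj.positions[i, ::monomer_stride]
        disp = traj.positions[j, ::monomer_stride] - p
        iu, ju = np.triu_indices(p.shape[0], 1)
        rij = np.linalg.norm(p[iu] - p[ju], axis=1)
        dots = np.sum(disp[iu] * disp[ju], axis=1)
        which = np.floor((rij - r_min) / bin_width).astype(int)
        ok = (which >= 0) & (which < nb)
        np.add.at(acc, which[ok], dots[ok])
        np.add.at(cnt, which[ok], 1)
    vals = np.divide(acc, cnt, out=np.zeros(nb), where=cnt > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    populated = np.flatnonzero(cnt > 0)
    norm = None
    if populated.size:
        ref = vals[populated[0]]
        if ref != 0:
            norm = vals / ref
    lag_time = float(traj.times[idx[lag]] - traj.times[idx[0]])
    return CorrelationSeries(abscissa=centers, value=vals, counts=cnt,
                             meta={"kind": "C_s", "lag_frames": lag,
                                   "lag_time": lag_time,
                                   "normalized": norm})


def correlation_length(series: CorrelationSeries, *, R: Optional[float] = None,
                       zero_run: int = 3) -> float:
    """L_corr: trapezoid integral of the normalized C_s profile.

    Integrates from the first populated bin center to the first sustained
    zero crossing (``zero_run`` consecutive non-positive bins), capped at 2R
    when no crossing occurs.  A profile that is non-positive everywhere past
    the first bin returns the bin width as a floor.
    """
    norm = series.meta.get("normalized")
    if norm is None:
        raise ValueError("series has no normalized profile")
    r = series.abscissa
    ok = series.counts > 0
    rr = r[ok]
    cc = norm[ok]
    if len(rr) < 2 or np.all(cc[1:] <= 0):
        return float(r[1] - r[0]) if len(r) > 1 else 0.0
    cut = _first_sustained_nonpositive(cc[1:], run=zero_run)
    end = len(cc) if cut is None else cut + 2
    if cut is None and R is not None:
        end = min(end, int(np.searchsorted(rr, 2.0 * R, side="right")))
    return float(np.trapezoid(cc[:end], rr[:end]))
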