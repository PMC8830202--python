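"""Active-passive microphase separation observables.

The demixing order parameter Phi(t) = x(t)/x(0) - 1 tracks the excess of
like-type interchain contacts over the activity-onset baseline; radial
profiles resolve where hot/cold monomers sit in the sphere; the
tank-treading diagnostics follow the hot block along the ring contour.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Frame, Topology, Trajectory

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


def like_neighbor_fraction(frame: Frame, topo: Topology,
                           r_c: float = WCA_CUTOFF, *,
                           denominator: Literal["interchain", "all"] = "interchain",
                           ) -> float:
    """Mean fraction of like-type monomers among a monomer's interchain neighbors.

    For each monomer, neighbors are monomers of *other* chains within
    ``r_c``; the fraction sharing its hot/cold type is averaged over all
    monomers that have at least one interchain neighbor.  With
    ``denominator="all"`` the like-type count is instead divided by the total
    neighbor count (intra + inter chain), an alternative reading of the same
    mixing measure.
    """
    if topo.M < 2:
        raise ValueError("need at least 2 chains")
    pos = frame.positions
    hot = topo.hot_mask
    ring = topo.ring_of
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r_c, output_type="ndarray")
    n = pos.shape[0]
    inter = ring[pairs[:, 0]] != ring[pairs[:, 1]]
    like = hot[pairs[:, 0]] == hot[pairs[:, 1]]
    n_inter = np.zeros(n)
    n_like = np.zeros(n)
    n_all = np.zeros(n)
    ip = pairs[inter]
    lk = like[inter]
    np.add.at(n_inter, ip[:, 0], 1)
    np.add.at(n_inter, ip[:, 1], 1)
    np.add.at(n_like, ip[lk, 0], 1)
    np.add.at(n_like, ip[lk, 1], 1)
    np.add.at(n_all, pairs[:, 0], 1)
    np.add.at(n_all, pairs[:, 1], 1)
    has = n_inter > 0
    if not np.any(has):
        raise ValueError("no monomer has interchain neighbors")
    denom = n_inter if denominator == "interchain" else n_all
    return float(np.mean(n_like[has] / denom[has]))


def order_parameter_phi(traj: Trajectory, t0: float = 0.0, *,
                        r_c: float = WCA_CUTOFF, baseline_window: int = 10,
                        denominator: Literal["interchain", "all"] = "interchain",
                        ) -> pd.DataFrame:
    """Phi(t) = x(t)/x(0) - 1 for every frame with t >= t0.

    x(0) is averaged over up to ``baseline_window`` frames starting at the
    first frame with t >= t0, damping shot noise in the baseline.
    """
    idx = np.flatnonzero(traj.times >= t0)
    if idx.size == 0:
        raise ValueError(f"no frames at t >= {t0}")
    x = np.array([like_neighbor_fraction(traj.frame(i), traj.topology, r_c,
                                         denominator=denominator)
                  for i in idx])
    x0 = float(x[: max(1, min(baseline_window, len(x)))].mean())
    if x0 == 0:
        raise ValueError("baseline like-neighbor fraction is zero")
    return pd.DataFrame({"t": traj.times[idx], "x": x, "phi": x / x0 - 1.0})


def radial_profiles(traj: Trajectory, *, bin_width: float = 0.5,
                    t_min: float = -np.inf, normalize: bool = False,
                    ) -> pd.DataFrame:
    """Shell number density of hot / cold / all monomers vs distance from center.

    Density is count / shell volume averaged over selected frames; with
    ``normalize`` the profiles integrate to 1 (probability density in r).
    The hot and cold columns sum bin-wise to the all column exactly.
    """
    sel = np.flatnonzero(traj.times >= t_min)
    if sel.size == 0:
        raise ValueError("empty frame selection")
    R = traj.box
    edges = np.arange(0.0, R + bin_width, bin_width)
    if edges[-1] < R:
        edges = np.append(edges, R)
    shell_vol = 4.0 / 3.0 * np.pi * np.diff(edges**3)
    hot = traj.topology.hot_mask
    counts = {"hot": np.zeros(len(edges) - 1), "cold": np.zeros(len(edges) - 1),
              "all": np.zeros(len(edges) - 1)}
    for i in sel:
        r = np.linalg.norm(traj.positions[i], axis=1)
        counts["hot"] += np.histogram(r[hot], bins=edges)[0]
        counts["cold"] += np.histogram(r[~hot], bins=edges)[0]
    counts["all"] = counts["hot"] + counts["cold"]
    out = {"r": 0.5 * (edges[:-1] + edges[1:])}
    for k, c in counts.items():
        dens = c / sel.size / shell_vol
        if normalize:
            total = np.sum(dens * shell_vol)
            dens = dens / total if total > 0 else dens
        out[k] = dens
    return pd.DataFrame(out)


def tank_treading_signal(traj: Trajectory, t0: float = 0.0) -> pd.DataFrame:
    """Per-ring d_ee^2(t): squared distance between a hot and a cold marker.

    For each ring the marker pair is fixed at t0: h* is the hot-segment
    midpoint monomer and c* = h* + N/2 its antipode along the contour.  A
    rigid motion of the ring leaves the series constant; tank-treading, which
    carries the hot material block along the spatial contour, modulates it.
    """
    topo = traj.topology
    N = topo.N
    idx = np.flatnonzero(traj.times >= t0)
    if idx.size == 0:
        raise ValueError(f"no frames at t >= {t0}")
    cols = {"t": traj.times[idx]}
    for r in range(topo.M):
        h = topo.hot_segment_center(r)
        c = (h + N // 2) % N
        gi = r * N + h
        gc = r * N + c
        d = traj.positions[idx, gi] - traj.positions[idx, gc]
        cols[f"ring{r}"] = np.sum(d * d, axis=1)
    return pd.DataFrame(cols)


def contour_offset(traj: Trajectory, t0: float = 0.0) -> pd.DataFrame:
    """Direct tank-treading angle: contour shift of each ring vs its t0 shape.

    For every frame, finds the cyclic label shift k minimizing
    sum_i |r_i(t) - r_{(i+k) mod N}(t0)|^2 for each ring; a steady
    tank-treading motion shows as a drifting k while rigid-body motion and
    shape fluctuations leave k near 0.  Signed offsets are reported in
    (-N/2, N/2].
    """
    topo = traj.topology
    N = topo.N
    i0 = int(np.flatnonzero(traj.times >= t0)[0])
    idx = np.flatnonzero(traj.times >= t0)
    cols = {"t": traj.times[idx]}
    for r in range(topo.M):
        ref = traj.ring_positions(i0, r)
        offs = np.empty(idx.size, dtype=int)
        for a, i in enumerate(idx):
            ring = traj.ring_positions(i, r)
            # cost(k) = sum_i |ring_i - ref_{i+k}|^2; expand and use cyclic
            # cross-correlation of the coordinates for the dot-product term
            best_k = 0
            best = np.inf
            for k in range(N):
                cost = np.sum((ring - np.roll(ref, -k, axis=0)) ** 2)
                if cost < best:
                    best = cost
                    best_k = k
            offs[a] = best_k if best_k <= N // 2 else best_k - N
        cols[f"ring{r}"] = offs
    return pd.DataFrame(cols)
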