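"""Named study conditions: desk-scale benchmark runs and long-run presets.

The cluster-scale steady states (M = 46 rings, N up to 1600, multi-million
tau horizons) are encoded here as configuration presets only; the desk-scale
benchmark is sized so the qualitative activity response -- simultaneous rise
of ring size, threading and demixing, with demixing leading -- is measurable
in minutes on one core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Trajectory
from .params import SimParams

#: Cluster-scale confined systems: M = 46 chains at rho = 0.85 sigma^-3, one
#: hot block of N/8 monomers per ring, steady state after ~3e6 tau.  These
#: are long-run horizons, provided as presets, not run by the tests.
LONG_RUN_SYSTEMS = {
    N: dict(M=46, N=N, N_h=N // 8, rho=0.85, T_cold=1.0, T_hot=3.0,
            steady_after_tau=3.0e6, total_tau=1.0e7)
    for N in (200, 400, 800, 1600)
}

#: Reference entanglement length of the semiflexible melt at this density.
N_ENTANGLEMENT = 28


@dataclass
class DeskAtgResult:
    """Summary of the desk-scale activity-switch benchmark."""

    trajectory: Trajectory
    onset_time: float
    rg2_passive: float
    rg2_active: float
    ntn_passive: float
    ntn_active: float
    phi_final: float
    t_half_phi: float
    t_half_rg2: float
    t_plateau_rg2: float


def half_rise_time(t: np.ndarray, y: np.ndarray, *, baseline_frames: int = 5,
                   final_frac: float = 0.2, smooth: int = 5) -> float:
    """First time a rising series reaches halfway from baseline to plateau.

    The baseline is the mean of the first ``baseline_frames`` points, the
    plateau the mean of the trailing ``final_frac`` fraction; the series is
    boxcar-smoothed over ``smooth`` points before thresholding.  NaN when
    the series does not rise.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    base = y[:baseline_frames].mean()
    fin = y[-max(int(len(y) * final_frac), 1):].mean()
    if fin <= base:
        return float("nan")
    target = base + 0.5 * (fin - base)
    kernel = np.ones(smooth) / smooth
    ys = np.convolve(y, kernel, mode="same")
    above = np.flatnonzero(ys >= target)
    return float(t[above[0]]) if above.size else float("nan")


def plateau_time(t: np.ndarray, y: np.ndarray, *, baseline_frames: int = 5,
                 final_frac: float = 0.2, smooth: int = 5,
                 level: float = 0.9) -> float:
    """First time a rising series reaches ``level`` of its baseline-to-plateau
    rise -- the onset of its plateau.  NaN when the series does not rise."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    base = y[:baseline_frames].mean()
    fin = y[-max(int(len(y) * final_frac), 1):].mean()
    if fin <= base:
        return float("nan")
    target = base + level * (fin - base)
    kernel = np.ones(smooth) / smooth
    ys = np.convolve(y, kernel, mode="same")
    above = np.flatnonzero(ys >= target)
    return float(t[above[0]]) if above.size else float("nan")


def run_desk_atg(seed: int = 1, *, n_steps: int = 500_000,
                 passive_steps: int = 100_000, output_every: int = 2000,
                 M: int = 10, N: int = 100, N_h: int = 12,
                 traj: Optional[Trajectory] = None) -> DeskAtgResult:
    """Desk-scale activity-switch benchmark (M=10, N=100, N_h=12 rings).

    Runs ``passive_steps`` of fully passive dynamics (the equilibrium
    baseline) followed by the activity switch-on, then summarizes the
    response: mean ring R_g^2 and threaded-neighbor count in the passive
    window versus the late active window (last 20%), the final demixing
    order parameter Phi, the half-rise times of Phi and R_g^2 after the
    onset, and the R_g^2 plateau-onset time (90% of the rise).  Pass
    ``traj`` to re-summarize an existing run.
    """
    from .dynamics import rg2_series
    from .phasesep import order_parameter_phi
    from .simulate import run_simulation
    from .threading_analysis import threaded_neighbors

    params = SimParams(M=M, N=N, N_h=N_h, seed=seed)
    if traj is None:
        traj = run_simulation(params, n_steps=n_steps,
                              output_every=output_every,
                              activity_start=passive_steps)
    onset = passive_steps * params.dt
    t = traj.times
    rg2 = rg2_series(traj).mean(axis=1)
    passive_sel = t < onset
    late_sel = t >= t[-1] - 0.2 * (t[-1] - onset)

    def mean_ntn(frames: np.ndarray) -> float:
        vals = [threaded_neighbors(traj.frame(i), traj.topology, n_refine=1)[1]
                for i in frames]
        return float(np.mean(vals))

    pas_frames = np.flatnonzero(passive_sel)
    pas_frames = pas_frames[pas_frames >= 2][::max(len(pas_frames) // 6, 1)][:6]
    late_frames = np.flatnonzero(late_sel)[::max(late_sel.sum() // 6, 1)][:6]
    phi = order_parameter_phi(traj, t0=onset)
    act_sel = t >= onset
    return DeskAtgResult(
        trajectory=traj,
        onset_time=onset,
        rg2_passive=float(rg2[passive_sel].mean()),
        rg2_active=float(rg2[late_sel].mean()),
        ntn_passive=mean_ntn(pas_frames),
        ntn_active=mean_ntn(late_frames),
        phi_final=float(phi["phi"].tail(max(len(phi) // 5, 1)).mean()),
        t_half_phi=half_rise_time(phi["t"].values - onset, phi["phi"].values),
        t_half_rg2=half_rise_time(t[act_sel] - onset, rg2[act_sel]),
        t_plateau_rg2=plateau_time(t[act_sel] - onset, rg2[act_sel]),
    )
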