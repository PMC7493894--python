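"""Molecular-timer grid screen over APAF1 x PC9 concentrations.

For every cell of a linearly spaced 25 x 25 APAF1 x PC9 matrix the network is
simulated for 4 h (XIAP absent, synthesis/degradation off) and the IETDase
activity trace is summarised by four metrics: maximum activity, time to
maximum, half-life of the post-maximum decay (one-phase-decay fit with y0
fixed to the maximum) and integrated activity (trapezoidal AUC).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import IntegrationError, apply_momp, build_network, simulate
from .params import (
    InitialState,
    KineticParameterSet,
    VARIANTS,
    default_initial_state,
)

__all__ = ["IETDaseMetrics", "GridScreenResult", "ietdase_metrics", "screen_grid"]


@dataclass(frozen=True)
class IETDaseMetrics:
    max_activity: float
    t_max: float
    t_half: float       # inf for a non-decaying (timer-off) trace
    auc: float
    decay_valid: bool


def ietdase_metrics(t: np.ndarray, activity: np.ndarray) -> IETDaseMetrics:
    """Summarise one IETDase activity trace.

    The decay half-life comes from fitting the post-maximum segment to
    ``y = (y0 - plateau) exp(-k x) + plateau`` with the time axis re-zeroed
    at the maximum, y0 fixed to the maximum activity and plateau constrained
    to be nonnegative.
    """
    t = np.asarray(t, dtype=float)
    a = np.asarray(activity, dtype=float)
    if t.shape != a.shape or t.size < 3:
        raise ValueError("need matching time/activity arrays with >= 3 points")
    i_max = int(np.argmax(a))
    a_max = float(a[i_max])
    t_max = float(t[i_max])
    auc = float(np.trapezoid(a, t))
    if a_max <= 0:
        return IETDaseMetrics(0.0, 0.0, float("inf"), auc, decay_valid=False)
    td = t[i_max:] - t_max
    yd = a[i_max:]
    # non-decaying trace (e.g. timer-off): no resolvable half-life
    if td.size < 3 or yd[-1] > 0.9 * a_max:
        return IETDaseMetrics(a_max, t_max, float("inf"), auc, decay_valid=False)

    def decay(x, plateau, k):
        return (a_max - plateau) * np.exp(-k * x) + plateau

    half_level = 0.5 * (a_max + float(yd[-1]))
    below = np.nonzero(yd <= half_level)[0]
    t_half_guess = float(td[below[0]]) if below.size else float(td[-1]) / 2.0
    k0 = np.log(2.0) / max(t_half_guess, float(td[1]))
    try:
        popt, _ = curve_fit(
            decay,
            td,
            yd,
            p0=(max(float(yd[-1]), 0.0), float(k0)),
            bounds=([0.0, 1e-10], [a_max, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        return IETDaseMetrics(a_max, t_max, float("inf"), auc, decay_valid=False)
    k = float(popt[1])
    return IETDaseMetrics(a_max, t_max, float(np.log(2.0) / k), auc, decay_valid=True)


@dataclass
class GridScreenResult:
    """Four 25 x 25 metric matrices over the APAF1 x PC9 grid."""

    apaf1: np.ndarray
    pc9: np.ndarray
    max_activity: np.ndarray   # shape (n_apaf1, n_pc9)
    t_max: np.ndarray
    t_half: np.ndarray
    auc: np.ndarray
    momp_fraction: float

    def to_long_frame(self) -> pd.DataFrame:
        """Heat-map-ready long table (apaf1, pc9, metric, value)."""
        rows = []
        for name in ("max_activity", "t_max", "t_half", "auc"):
            m = getattr(self, name)
            for i, a in enumerate(self.apaf1):
                for j, p in enumerate(self.pc9):
                    rows.append((a, p, name, m[i, j]))
        return pd.DataFrame(rows, columns=["apaf1", "pc9", "metric", "value"])


def screen_grid(
    params: KineticParameterSet,
    apaf1_range: tuple[float, float],
    pc9_range: tuple[float, float],
    n: int = 25,
    momp_fraction: float = 1.0,
    base_state: InitialState | None = None,
    horizon: float = 240.0,
) -> GridScreenResult:
    """Run the n x n grid (XIAP absent, synthesis/degradation off).

    Cells are independent simulations; a per-cell integrator failure is
    recorded as NaN rather than aborting the screen.
    """
    apaf1_vals = np.linspace(apaf1_range[0], apaf1_range[1], n)
    pc9_vals = np.linspace(pc9_range[0], pc9_range[1], n)
    base = base_state or default_initial_state()
    net = build_network(params, VARIANTS["no_xiap"])
    mats = {m: np.full((n, n), np.nan) for m in ("max_activity", "t_max", "t_half", "auc")}
    for i, a in enumerate(apaf1_vals):
        for j, p in enumerate(pc9_vals):
            state = apply_momp(base.replace(apaf1=float(a), pc9=float(p)), momp_fraction)
            try:
                traj = simulate(net, state, horizon)
            except IntegrationError:
                continue
            met = ietdase_metrics(traj.t, traj.ietdase_activity())
            mats["max_activity"][i, j] = met.max_activity
            mats["t_max"][i, j] = met.t_max
            mats["t_half"][i, j] = met.t_half
            mats["auc"][i, j] = met.auc
    return GridScreenResult(
        apaf1=apaf1_vals,
        pc9=pc9_vals,
        momp_fraction=momp_fraction,
        **mats,
    )
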