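"""Extraction of apoptosome binding kinetics from dissociation traces.

A dissociation trace (e.g. an SPR sensorgram dissociation phase, or an
IETDase-activity decay) is fitted to a one-phase exponential decay

    y(x) = (y0 - plateau) * exp(-k x) + plateau,

the half-life t1/2 = ln(2)/k gives the dissociation rate k_off = ln(2)/t1/2,
and the association rate follows from the equilibrium constant,
k_on = k_off / K_D.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayTrace",
    "OnePhaseDecayFit",
    "BindingKinetics",
    "one_phase_decay",
    "fit_one_phase_decay",
    "koff_from_halftime",
    "kon_from_kd",
]

LN2 = float(np.log(2.0))


def one_phase_decay(x, y0: float, plateau: float, k: float):
    """y = (y0 - plateau) * exp(-k x) + plateau."""
    return (y0 - plateau) * np.exp(-k * np.asarray(x, dtype=float)) + plateau


@dataclass(frozen=True)
class DecayTrace:
    """Time/response table for one dissociation curve.

    ``time_unit`` declares the unit of ``time`` ('min' or 's'); the canonical
    internal unit is minutes.
    """

    time: np.ndarray
    response: np.ndarray
    label: str = ""
    time_unit: str = "min"

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.size < 5:
            raise ValueError("a decay trace needs at least 5 points")
        if t.size != r.size:
            raise ValueError("time and response must have equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.time_unit not in ("min", "s"):
            raise ValueError("time_unit must be 'min' or 's'")

    def in_minutes(self) -> "DecayTrace":
        if self.time_unit == "min":
            return self
        return DecayTrace(self.time / 60.0, self.response, self.label, "min")


@dataclass(frozen=True)
class OnePhaseDecayFit:
    """Fitted one-phase decay: y0, plateau, rate k and derived half-life."""

    y0: float
    plateau: float
    k: float
    r_squared: float
    valid: bool = True

    @property
    def t_half(self) -> float:
        return LN2 / self.k if self.k > 0 else float("inf")

    def predict(self, x):
        return one_phase_decay(x, self.y0, self.plateau, self.k)


@dataclass(frozen=True)
class BindingKinetics:
    """Mutually consistent (K_D, k_off, k_on) triple for one interaction."""

    kd: float      # uM
    k_off: float   # min^-1
    k_on: float    # uM^-1 min^-1
    label: str = ""

    def __post_init__(self):
        if min(self.kd, self.k_off, self.k_on) <= 0:
            raise ValueError("kd, k_off and k_on must all be > 0")
        if abs(self.kd - self.k_off / self.k_on) > 1e-9 * self.kd:
            raise ValueError("K_D must equal k_off / k_on")

    @classmethod
    def from_spr(cls, kd: float, t_half: float, label: str = "") -> "BindingKinetics":
        """Build from a published K_D and a fitted dissociation half-life."""
        k_off = koff_from_halftime(t_half)
        return cls(kd=kd, k_off=k_off, k_on=kon_from_kd(k_off, kd), label=label)


def koff_from_halftime(t_half: float) -> float:
    """k_off = ln(2) / t1/2."""
    if t_half <= 0:
        raise ValueError("half-life must be > 0")
    return LN2 / t_half


def kon_from_kd(k_off: float, kd: float) -> float:
    """k_on = k_off / K_D."""
    if kd <= 0:
        raise ValueError("K_D must be > 0")
    return k_off / kd


def _start_heuristic(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start: y0 = first value, plateau = last value, k from a
    log-linear fit of the first third of the (baseline-subtracted) trace."""
    y0, plateau = float(y[0]), float(y[-1])
    amp = y0 - plateau
    n3 = max(t.size // 3, 3)
    k0 = 1.0 / max(t[-1] - t[0], 1e-12)
    if amp > 0:
        z = y[:n3] - plateau
        mask = z > 1e-12 * abs(amp)
        if mask.sum() >= 2:
            slope = np.polyfit(t[:n3][mask], np.log(z[mask]), 1)[0]
            if slope < 0:
                k0 = -float(slope)
    return y0, plateau, k0


def fit_one_phase_decay(
    trace: DecayTrace, initial_guess: tuple[float, float, float] | None = None
) -> OnePhaseDecayFit:
    """Least-squares fit of the one-phase decay model to a trace.

    Uses a bounded trust-region local optimizer from a deterministic start
    (monotone decays need no random restarts).  A trace with no resolvable
    decay (flat, or fitted k <= 0) is returned flagged invalid.
    """
    trace = trace.in_minutes()
    t, y = trace.time, trace.response
    span = float(y.max() - y.min())
    if span <= 1e-12 * max(abs(y).max(), 1.0):
        return OnePhaseDecayFit(float(y[0]), float(y[0]), 0.0, 0.0, valid=False)
    p0 = initial_guess if initial_guess is not None else _start_heuristic(t, y)
    lo = [-np.inf, -np.inf, 1e-12]
    hi = [np.inf, np.inf, np.inf]
    p0 = (p0[0], p0[1], min(max(p0[2], 1e-10), 1e6))
    try:
        popt, _ = curve_fit(
            one_phase_decay, t, y, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as err:
        resid = y - one_phase_decay(t, *p0)
        raise RuntimeError(
            f"one-phase decay fit failed for trace '{trace.label}': {err}; "
            f"start residual SS={float(resid @ resid):.4g}"
        ) from err
    y0, plateau, k = (float(v) for v in popt)
    resid = y - one_phase_decay(t, y0, plateau, k)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    valid = k > 1e-10 and y0 >= plateau
    return OnePhaseDecayFit(y0, plateau, k, r2, valid=valid)


def fit_traces(traces: list[DecayTrace]) -> dict[str, OnePhaseDecayFit]:
    """Fit a batch of labelled traces; keyed by label."""
    return {tr.label or str(i): fit_one_phase_decay(tr) for i, tr in enumerate(traces)}
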