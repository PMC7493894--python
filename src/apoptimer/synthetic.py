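"""Synthetic data generators.

Everything the pipeline consumes can be generated here without downloads:
one-phase-decay SPR dissociation traces, Boltzmann-shaped substrate-cleavage
and timer-decay training sets, and patient cohorts with class-dependent
survival.  Every generator is a pure function of (spec, seed).

Protein concentrations in patient cohorts are log-normal, parameterised by
median and coefficient of variation (CV); the default CVs target the
dispersion reported for stage III colorectal tumours (XIAP 100%, PC9 154%,
PC3 144%, SMAC 135%).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import TrainingSet, boltzmann
from .kinetics import DecayTrace, one_phase_decay

__all__ = [
    "generate_spr_trace",
    "generate_training_set",
    "CohortSpec",
    "generate_patient_cohort",
    "DEFAULT_BOLTZMANN",
    "DEFAULT_TIMER_DECAY",
]

#: HeLa-like substrate cleavage training curve: bottom %, top %, half-time
#: V50 (min post-MOMP) and slope (min).
DEFAULT_BOLTZMANN = {"bottom": 0.0, "top": 100.0, "v50": 15.0, "slope": 2.5}

#: Timer training decay: relative maximal cleavage rate vs preincubation
#: delay; floor = residual (XIAP-insensitive fraction persisting at long
#: delays), t_half in min.
DEFAULT_TIMER_DECAY = {"floor": 0.15, "t_half": 15.0}

#: Default log-normal medians (uM) and CVs for the synthetic patient cohort.
DEFAULT_PATIENT_PROTEINS = {
    "pc9": {"median": 0.02, "cv": 1.54},
    "pc3": {"median": 0.30, "cv": 1.44},
    "xiap": {"median": 0.15, "cv": 1.00},
    "smac": {"median": 0.20, "cv": 1.35},
}


def generate_spr_trace(
    k_off: float,
    y0: float = 100.0,
    plateau: float = 0.0,
    noise_sd: float = 0.0,
    n_points: int = 60,
    seed: int | None = 0,
    t_max: float | None = None,
    label: str = "",
    time_unit: str = "min",
) -> DecayTrace:
    """One-phase-decay dissociation trace with seeded Gaussian noise."""
    if k_off <= 0:
        raise ValueError("k_off must be > 0")
    if t_max is None:
        t_max = 5.0 * np.log(2.0) / k_off  # five half-lives
    t = np.linspace(0.0, t_max, n_points)
    y = one_phase_decay(t, y0, plateau, k_off)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return DecayTrace(time=t, response=y, label=label, time_unit=time_unit)


def generate_training_set(
    boltzmann_params: dict | None = None,
    timer_params: dict | None = None,
    noise: float = 0.0,
    seed: int | None = 0,
) -> TrainingSet:
    """Sampled cleavage and timer training points (generating truth recorded).

    ``noise`` is the Gaussian SD applied to the cleavage points (in %) and,
    scaled by the amplitude, to the relative timer rates.
    """
    bp = dict(DEFAULT_BOLTZMANN, **(boltzmann_params or {}))
    tp = dict(DEFAULT_TIMER_DECAY, **(timer_params or {}))
    if not (0 <= tp["floor"] < 1) or tp["t_half"] <= 0:
        raise ValueError("invalid timer decay parameters")
    rng = np.random.default_rng(seed)
    times = np.arange(2.0, 61.0, 2.0)
    cleav = boltzmann(times, bp["bottom"], bp["top"], bp["v50"], bp["slope"])
    delays = np.arange(5.0, 31.0, 5.0)
    k = np.log(2.0) / tp["t_half"]
    rates = tp["floor"] + (1.0 - tp["floor"]) * np.exp(-k * (delays - delays[0]))
    if noise > 0:
        cleav = cleav + rng.normal(0.0, noise, size=cleav.shape)
        rates = rates + rng.normal(0.0, noise / 100.0, size=rates.shape)
    cleav = np.clip(cleav, 0.0, 100.0)
    rates = np.clip(rates, 1e-6, None)
    return TrainingSet(
        cleavage_times=times,
        cleavage_values=cleav,
        timer_delays=delays,
        timer_rates=rates,
        truth={"boltzmann": bp, "timer": tp, "noise": noise, "seed": seed},
    )


@dataclass
class CohortSpec:
    """Specification of a synthetic patient cohort.

    Survival: exponential event times with a class-dependent hazard
    (``hazard_ratio`` for apoptosis-resistant vs capable), independent
    exponential censoring plus administrative censoring at follow-up end.
    Times are in months.
    """

    n: int = 200
    proteins: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_PATIENT_PROTEINS.items()
    })
    apaf1: float = 0.123
    seed: int | None = 0
    baseline_hazard_dfs: float = np.log(2.0) / 60.0   # median DFS 60 months
    baseline_hazard_os: float = np.log(2.0) / 90.0    # median OS 90 months
    hazard_ratio: float = 2.0
    censor_rate: float = 0.004
    followup_months: float = 120.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be > 0")
        for name, cfg in self.proteins.items():
            if cfg["cv"] <= 0 or cfg["median"] <= 0:
                raise ValueError(f"invalid distribution for {name}")


def _lognormal(rng, median: float, cv: float, n: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def generate_patient_cohort(
    spec: CohortSpec,
    classifier=None,
) -> pd.DataFrame:
    """Patient table: log-normal protein profiles, simulation-derived
    apoptosis class, and class-dependent survival.

    ``classifier`` maps a concentration dict to True (apoptosis resistant) /
    False; by default the execution model at the calibrated parameters
    (full MOMP, 300-min horizon, 25% threshold).  Warns if the cohort does
    not exercise both classes.
    """
    rng = np.random.default_rng(spec.seed)
    cols = {
        name: _lognormal(rng, cfg["median"], cfg["cv"], spec.n)
        for name, cfg in spec.proteins.items()
    }
    df = pd.DataFrame(cols)
    df.insert(0, "id", [f"P{i:04d}" for i in range(spec.n)])
    df["apaf1"] = spec.apaf1

    if classifier is None:
        from .patients import PatientRecord, classify_patient

        def classifier(conc):
            rec = PatientRecord(
                id="tmp",
                pc9=conc["pc9"], pc3=conc["pc3"],
                xiap=conc["xiap"], smac=conc["smac"], apaf1=conc["apaf1"],
                dfs_time=1.0, dfs_event=0, os_time=1.0, os_event=0,
            )
            return classify_patient(rec).resistant

    resistant = np.array(
        [
            bool(classifier({k: df[k].iloc[i] for k in ("pc9", "pc3", "xiap", "smac", "apaf1")}))
            for i in range(spec.n)
        ]
    )
    if resistant.all() or (~resistant).all():
        warnings.warn(
            "synthetic cohort exercises only one apoptosis class; "
            "adjust protein medians or CVs",
            stacklevel=2,
        )
    df["resistant"] = resistant

    for endpoint, base in (
        ("dfs", spec.baseline_hazard_dfs),
        ("os", spec.baseline_hazard_os),
    ):
        lam = np.where(resistant, base * spec.hazard_ratio, base)
        event_t = rng.exponential(1.0 / lam)
        censor_t = (
            rng.exponential(1.0 / spec.censor_rate, size=spec.n)
            if spec.censor_rate > 0
            else np.full(spec.n, np.inf)
        )
        censor_t = np.minimum(censor_t, spec.followup_months)
        df[f"{endpoint}_time"] = np.minimum(event_t, censor_t)
        df[f"{endpoint}_event"] = (event_t <= censor_t).astype(int)
    return df
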