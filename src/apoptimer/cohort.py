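"""Virtual-cell population screens.

Cells are sampled from physiological concentration ranges (CytC and ATP
fixed at the HeLa values 10 and 920 uM), simulated under four regulatory
variants (normal, no XIAP, no molecular timer, neither) after full or
minority MOMP, and analysed by survival curves, logrank tests, apoptosis /
timer-dependence classification, ROC screens of single proteins and the
XIAP-SMAC balance, and Webb's fractional-product synergy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.metrics import roc_auc_score

from .core import (
    IntegrationError,
    apply_momp,
    build_network,
    detect_death_event,
    simulate,
)
from .params import (
    InitialState,
    KineticParameterSet,
    VARIANTS,
    default_initial_state,
    default_ranges,
)

__all__ = [
    "VirtualCell",
    "sample_cohort",
    "run_conditions",
    "run_classification",
    "survival_curve",
    "survival_fraction",
    "logrank",
    "classify_cells",
    "xiap_smac_balance",
    "ROCResult",
    "roc_auc",
    "SynergyScore",
    "webb_synergy",
    "timer_contribution",
    "timer_rescue_fraction",
]

SURVIVAL_VARIANTS = ("normal", "no_xiap", "no_timer", "no_xiap_no_timer")
CHECKPOINTS = (15.0, 30.0, 60.0, 240.0)
PROTEINS = ("apaf1", "pc9", "pc3", "xiap", "smac")


@dataclass(frozen=True)
class VirtualCell:
    """One sampled protein profile (uM); CytC/ATP fixed at HeLa values."""

    id: int
    apaf1: float
    pc9: float
    pc3: float
    xiap: float
    smac: float

    def to_initial_state(self, base: InitialState | None = None) -> InitialState:
        base = base or default_initial_state()
        return base.replace(
            apaf1=self.apaf1,
            pc9=self.pc9,
            pc3=self.pc3,
            xiap=self.xiap,
            smac_mito=self.smac,
        )


def sample_cohort(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 1000,
    seed: int | None = 0,
    mode: str = "linear",
    max_retries: int = 100,
) -> list[VirtualCell]:
    """Sample ``n`` entirely unique protein combinations.

    Each protein is drawn independently and uniformly over its configured
    [min, max] (``mode='log'`` switches to log-uniform).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("linear", "log"):
        raise ValueError("mode must be 'linear' or 'log'")
    ranges = ranges or default_ranges()
    rng = np.random.default_rng(seed)

    def draw_one() -> tuple[float, ...]:
        vals = []
        for prot in PROTEINS:
            lo, hi = ranges[prot]
            if mode == "log":
                vals.append(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
            else:
                vals.append(float(rng.uniform(lo, hi)))
        return tuple(vals)

    cells: list[tuple[float, ...]] = []
    seen: set[tuple[float, ...]] = set()
    while len(cells) < n:
        combo = draw_one()
        retries = 0
        while combo in seen:
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    "could not sample unique combinations (degenerate ranges)"
                )
            combo = draw_one()
        seen.add(combo)
        cells.append(combo)
    return [VirtualCell(i, *c) for i, c in enumerate(cells)]


def _cell_frame(cohort: list[VirtualCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.id, c.apaf1, c.pc9, c.pc3, c.xiap, c.smac) for c in cohort],
        columns=["id", *PROTEINS],
    )


def run_conditions(
    cohort: list[VirtualCell],
    params: KineticParameterSet,
    momp_fraction: float = 1.0,
    horizon: float = 240.0,
    threshold: float = 0.25,
    variants: tuple[str, ...] = SURVIVAL_VARIANTS,
    base_state: InitialState | None = None,
) -> pd.DataFrame:
    """Per-cell, per-variant death events and checkpoint cleavages.

    Returns a tidy frame (id, variant, died, event_time, cleav15, cleav30,
    cleav60, cleav240).  Per-cell integration failures are excluded with a
    warning reporting the count; cells are independent, so results do not
    depend on execution order.
    """
    nets = {v: build_network(params, VARIANTS[v]) for v in variants}
    rows = []
    failures = 0
    n_grid = int(round(horizon / 2.5)) + 1  # 2.5-min grid hits all checkpoints
    for cell in cohort:
        state0 = cell.to_initial_state(base_state)
        state = apply_momp(state0, momp_fraction)
        for vname, net in nets.items():
            try:
                traj = simulate(
                    net, state, horizon, n_grid=n_grid, death_threshold=threshold
                )
            except IntegrationError:
                failures += 1
                continue
            ev = detect_death_event(traj, threshold=threshold, censor_at=horizon)
            cps = [float(traj.c3_substrate_cleavage(min(t, horizon))) for t in CHECKPOINTS]
            rows.append((cell.id, vname, ev.died, ev.event_time, *cps))
    if failures:
        warnings.warn(f"{failures} cell/variant simulations failed and were excluded")
    return pd.DataFrame(
        rows,
        columns=["id", "variant", "died", "event_time", "cleav15", "cleav30", "cleav60", "cleav240"],
    )


def run_classification(
    cohort: list[VirtualCell],
    params: KineticParameterSet,
    momp_fraction: float = 1.0,
    t_eval: float = 60.0,
    base_state: InitialState | None = None,
) -> pd.DataFrame:
    """Light-weight screen: cleavage at ``t_eval`` for the normal and
    timer-off variants only (the ROC-screen protocol)."""
    nets = {v: build_network(params, VARIANTS[v]) for v in ("normal", "no_timer")}
    rows = []
    for cell in cohort:
        state = apply_momp(cell.to_initial_state(base_state), momp_fraction)
        vals = {}
        try:
            for vname, net in nets.items():
                traj = simulate(net, state, t_eval, n_grid=25)
                vals[vname] = float(traj.c3_substrate_cleavage(t_eval))
        except IntegrationError:
            continue
        rows.append((cell.id, vals["normal"], vals["no_timer"]))
    df = pd.DataFrame(rows, columns=["id", "cleav_normal", "cleav_no_timer"])
    return df.merge(_cell_frame(cohort), on="id")


def survival_curve(outcomes: pd.DataFrame, variant: str) -> KaplanMeierFitter:
    """Kaplan-Meier product-limit curve for one variant."""
    sub = outcomes[outcomes["variant"] == variant]
    if sub.empty:
        raise ValueError(f"no outcomes for variant {variant!r}")
    kmf = KaplanMeierFitter(label=variant)
    kmf.fit(sub["event_time"], event_observed=sub["died"].astype(int))
    return kmf


def survival_fraction(outcomes: pd.DataFrame, variant: str, t: float) -> float:
    """Fraction of cells alive at time t (no competing censoring before the
    horizon, so the raw fraction equals the product-limit estimate)."""
    sub = outcomes[outcomes["variant"] == variant]
    if sub.empty:
        raise ValueError(f"no outcomes for variant {variant!r}")
    dead = (sub["died"]) & (sub["event_time"] <= t)
    return float(1.0 - dead.mean())


def logrank(outcomes_a: pd.DataFrame, outcomes_b: pd.DataFrame):
    """Two-sided logrank test between two outcome groups.

    Returns (chi2 statistic, p value).  With no events in either group the
    test is undefined; returns (0, 1) with a warning.
    """
    if outcomes_a.empty or outcomes_b.empty:
        raise ValueError("both groups must be nonempty")
    if outcomes_a["died"].sum() == 0 and outcomes_b["died"].sum() == 0:
        warnings.warn("no events in either group; logrank undefined, p = 1")
        return 0.0, 1.0
    res = logrank_test(
        outcomes_a["event_time"],
        outcomes_b["event_time"],
        event_observed_A=outcomes_a["died"].astype(int),
        event_observed_B=outcomes_b["died"].astype(int),
    )
    return float(res.test_statistic), float(res.p_value)


def classify_cells(
    outcomes: pd.DataFrame,
    threshold: float = 0.25,
    cleavage_col: str = "cleav60",
) -> pd.DataFrame:
    """Apoptosis capability and timer dependence per cell.

    resistant  <=>  cleavage(normal) <= threshold at the evaluation time;
    among resistant cells, timer-dependent <=> cleavage(no_timer) > threshold.
    Accepts either a tidy ``run_conditions`` frame (pivoted on variant) or a
    ``run_classification`` frame.
    """
    if "variant" in outcomes.columns:
        wide = outcomes.pivot(index="id", columns="variant", values=cleavage_col)
        missing = {"normal", "no_timer"} - set(wide.columns)
        if missing:
            raise ValueError(f"outcomes missing variants: {sorted(missing)}")
        normal, no_timer = wide["normal"], wide["no_timer"]
        out = wide.reset_index()[["id"]]
    else:
        for col in ("cleav_normal", "cleav_no_timer"):
            if col not in outcomes.columns:
                raise ValueError(f"missing column {col}")
        normal = outcomes["cleav_normal"]
        no_timer = outcomes["cleav_no_timer"]
        out = outcomes[["id"]].copy()
    resistant = (normal <= threshold).to_numpy()
    timer_dep = resistant & (no_timer > threshold).to_numpy()
    out["resistant"] = resistant
    out["timer_dependent"] = timer_dep
    return out


def xiap_smac_balance(xiap, smac, metric: str = "log_ratio"):
    """XIAP-SMAC balance score: log10(XIAP/SMAC) (0 at equimolarity), or the
    absolute difference when ``metric='difference'``."""
    xiap = np.asarray(xiap, dtype=float)
    smac = np.asarray(smac, dtype=float)
    if metric == "difference":
        return xiap - smac
    if np.any(xiap <= 0) or np.any(smac <= 0):
        raise ValueError("concentrations must be > 0 for the log-ratio balance")
    return np.log10(xiap / smac)


@dataclass(frozen=True)
class ROCResult:
    """AUC of one concentration-based classifier (ties count 1/2)."""

    name: str
    auc: float
    orientation: int  # +1: larger score predicts the positive class
    n_positive: int
    n_negative: int


def roc_auc(scores, labels, name: str = "") -> ROCResult:
    """AUC = P(random positive outranks random negative); orientation chosen
    so the reported AUC is >= 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, scores))
    orientation = 1
    if auc < 0.5:
        auc, orientation = 1.0 - auc, -1
    return ROCResult(name=name, auc=auc, orientation=orientation, n_positive=n_pos, n_negative=n_neg)


@dataclass(frozen=True)
class SynergyScore:
    """Webb's fractional product at one checkpoint; < 0.9 flags synergy."""

    t: float
    s_normal: float
    s_no_xiap: float
    s_no_timer: float
    s_both: float
    score: float
    synergistic: bool
    defined: bool = True


def webb_synergy(outcomes: pd.DataFrame, t: float) -> SynergyScore:
    """Webb's fractional product from survival fractions at time ``t``,
    normalised against the standard model:

        score = (S_both / S_normal) /
                ((S_noXIAP / S_normal) * (S_noTimer / S_normal))
    """
    s = {v: survival_fraction(outcomes, v, t) for v in SURVIVAL_VARIANTS}
    s_n, s_x, s_t, s_b = (
        s["normal"], s["no_xiap"], s["no_timer"], s["no_xiap_no_timer"]
    )
    if s_n <= 0 or s_x <= 0 or s_t <= 0:
        return SynergyScore(t, s_n, s_x, s_t, s_b, float("nan"), False, defined=False)
    score = (s_b / s_n) / ((s_x / s_n) * (s_t / s_n))
    return SynergyScore(t, s_n, s_x, s_t, s_b, score, bool(score < 0.9))


def timer_contribution(cleav_normal, cleav_no_timer):
    """Difference in substrate cleavage without vs with the molecular timer."""
    return np.asarray(cleav_no_timer, dtype=float) - np.asarray(cleav_normal, dtype=float)


def timer_rescue_fraction(outcomes: pd.DataFrame) -> float:
    """Fraction of cells dying without the timer that the timer rescues:
    among cells with a death event under the timer-off variant, the share
    censored under the normal variant."""
    wide_died = outcomes.pivot(index="id", columns="variant", values="died")
    if "normal" not in wide_died or "no_timer" not in wide_died:
        raise ValueError("outcomes must include normal and no_timer variants")
    would_die = wide_died["no_timer"].astype(bool)
    if would_die.sum() == 0:
        return float("nan")
    rescued = would_die & ~wide_died["normal"].astype(bool)
    return float(rescued.sum() / would_die.sum())
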