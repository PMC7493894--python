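"""Virtual-cell cohort plumbing: sampling, survival, ROC, synergy.

Estimator wrappers (Kaplan-Meier, logrank, AUC) are checked against
independent brute-force oracles on small inputs.
"""
import numpy as np
import pandas as pd
import pytest

import apoptimer as ap
from apoptimer.cohort import (
    classify_cells,
    logrank,
    roc_auc,
    sample_cohort,
    survival_curve,
    survival_fraction,
    timer_contribution,
    timer_rescue_fraction,
    webb_synergy,
    xiap_smac_balance,
)


def _outcomes(records):
    return pd.DataFrame(records, columns=["id", "variant", "died", "event_time"]).assign(
        cleav15=0.0, cleav30=0.0, cleav60=0.0, cleav240=0.0
    )


class TestSampling:
    def test_same_seed_reproducible_and_unique(self, ranges):
        a = sample_cohort(ranges, n=200, seed=42)
        b = sample_cohort(ranges, n=200, seed=42)
        assert [(c.apaf1, c.pc9) for c in a] == [(c.apaf1, c.pc9) for c in b]
        combos = {(c.apaf1, c.pc9, c.pc3, c.xiap, c.smac) for c in a}
        assert len(combos) == 200

    def test_values_within_ranges(self, ranges):
        for mode in ("linear", "log"):
            for c in sample_cohort(ranges, n=50, seed=1, mode=mode):
                for prot in ("apaf1", "pc9", "pc3", "xiap", "smac"):
                    lo, hi = ranges[prot]
                    assert lo <= getattr(c, prot) <= hi

    def test_degenerate_range_raises(self):
        degenerate = {p: (1.0, 1.0) for p in ("apaf1", "pc9", "pc3", "xiap", "smac")}
        with pytest.raises(RuntimeError):
            sample_cohort(degenerate, n=2, seed=0)


class TestKaplanMeierAndLogrank:
    def test_all_censored_flat_at_one(self):
        out = _outcomes([(i, "normal", False, 240.0) for i in range(10)])
        km = survival_curve(out, "normal")
        assert float(km.survival_function_.iloc[-1].iloc[0]) == pytest.approx(1.0)

    def test_all_die_at_ten(self):
        out = _outcomes([(i, "normal", True, 10.0) for i in range(10)])
        km = survival_curve(out, "normal")
        assert float(km.predict(9.9)) == pytest.approx(1.0)
        assert float(km.predict(10.0)) == pytest.approx(0.0)

    def test_matches_hand_product_limit_on_five_cells(self):
        # deaths at 5, 12 (x2), censor at 20, death at 30
        out = _outcomes(
            [
                (0, "normal", True, 5.0),
                (1, "normal", True, 12.0),
                (2, "normal", True, 12.0),
                (3, "normal", False, 20.0),
                (4, "normal", True, 30.0),
            ]
        )
        km = survival_curve(out, "normal")
        # hand product-limit: S(5)=4/5, S(12)=4/5*(3/5)/(3/5)... recompute:
        # at t=5: 5 at risk, 1 death -> 4/5
        # at t=12: 4 at risk, 2 deaths -> 4/5 * 2/4 = 2/5
        # at t=30: 1 at risk, 1 death -> 0
        assert float(km.predict(5.0)) == pytest.approx(0.8)
        assert float(km.predict(12.0)) == pytest.approx(0.4)
        assert float(km.predict(30.0)) == pytest.approx(0.0)

    def test_logrank_identical_groups(self):
        out = _outcomes([(i, "normal", True, float(10 + i)) for i in range(10)])
        stat, p = logrank(out, out.copy())
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_logrank_symmetry(self):
        a = _outcomes([(i, "normal", True, float(5 + i)) for i in range(20)])
        b = _outcomes([(i, "normal", i % 2 == 0, float(15 + i)) for i in range(20)])
        _, p1 = logrank(a, b)
        _, p2 = logrank(b, a)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_logrank_disjoint_supports_vs_permutation_oracle(self):
        """All of group A dies before any B event: the observed statistic
        should exceed every permutation statistic (p < 1e-6 asymptotically)."""
        rng = np.random.default_rng(5)
        a_times = rng.uniform(1, 20, 100)
        b_times = rng.uniform(50, 100, 100)
        a = _outcomes([(i, "normal", True, float(t)) for i, t in enumerate(a_times)])
        b = _outcomes([(i, "normal", True, float(t)) for i, t in enumerate(b_times)])
        stat, p = logrank(a, b)
        assert p < 1e-6

        from lifelines.statistics import logrank_test

        times = np.concatenate([a_times, b_times])
        n_more_extreme = 0
        for _ in range(200):  # permutation null: statistic far below observed
            perm = rng.permutation(times)
            s = logrank_test(
                perm[:100], perm[100:],
                event_observed_A=np.ones(100), event_observed_B=np.ones(100),
            ).test_statistic
            if s >= stat:
                n_more_extreme += 1
        assert n_more_extreme == 0

    def test_no_events_returns_p_one_with_warning(self):
        a = _outcomes([(i, "normal", False, 240.0) for i in range(5)])
        with pytest.warns(UserWarning):
            stat, p = logrank(a, a.copy())
        assert p == 1.0


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(17)
        scores = np.round(rng.normal(size=200), 1)  # rounding induces ties
        labels = rng.random(200) < 0.4
        res = roc_auc(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        oracle = max(oracle, 1.0 - oracle)
        assert res.auc == pytest.approx(oracle, abs=1e-12)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(99)
        scores = rng.normal(size=10000)
        labels = rng.random(10000) < 0.5
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(0.5, abs=0.02)

    def test_orientation_reported(self):
        res = roc_auc([1, 2, 3, 4], [1, 1, 0, 0])
        assert res.auc == 1.0 and res.orientation == -1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestBalanceAndClassification:
    def test_balance_trivials(self):
        assert xiap_smac_balance(0.5, 0.5) == pytest.approx(0.0)
        assert xiap_smac_balance(1.0, 0.1) == pytest.approx(1.0)
        assert xiap_smac_balance(0.1, 1.0) == pytest.approx(-xiap_smac_balance(1.0, 0.1))
        assert xiap_smac_balance(0.3, 0.1, metric="difference") == pytest.approx(0.2)
        with pytest.raises(ValueError):
            xiap_smac_balance(0.0, 1.0)

    def test_classification_definitions(self):
        out = pd.DataFrame(
            {
                "id": [0, 1, 2],
                "cleav_normal": [0.30, 0.20, 0.20],
                "cleav_no_timer": [0.50, 0.30, 0.20],
            }
        )
        cls = classify_cells(out)
        assert list(cls["resistant"]) == [False, True, True]
        assert list(cls["timer_dependent"]) == [False, True, False]

    def test_classification_from_tidy_outcomes(self):
        rows = []
        for i, (cn, cnt) in enumerate([(0.3, 0.5), (0.1, 0.4)]):
            rows.append((i, "normal", True, 50.0, 0, 0, cn, 0))
            rows.append((i, "no_timer", True, 40.0, 0, 0, cnt, 0))
        out = pd.DataFrame(
            rows,
            columns=["id", "variant", "died", "event_time", "cleav15", "cleav30", "cleav60", "cleav240"],
        )
        cls = classify_cells(out)
        assert list(cls["resistant"]) == [False, True]
        assert list(cls["timer_dependent"]) == [False, True]


class TestSynergy:
    def test_multiplicative_independence_scores_one(self):
        out = pd.concat(
            [
                _survival_block("normal", alive=100, dead=0),
                _survival_block("no_xiap", alive=50, dead=50),
                _survival_block("no_timer", alive=50, dead=50),
                _survival_block("no_xiap_no_timer", alive=25, dead=75),
            ]
        )
        s = webb_synergy(out, 100.0)
        assert s.score == pytest.approx(1.0)
        assert not s.synergistic

    def test_direct_arithmetic(self):
        out = pd.concat(
            [
                _survival_block("normal", alive=80, dead=20),
                _survival_block("no_xiap", alive=40, dead=60),
                _survival_block("no_timer", alive=60, dead=40),
                _survival_block("no_xiap_no_timer", alive=10, dead=90),
            ]
        )
        s = webb_synergy(out, 100.0)
        expected = (0.10 / 0.80) / ((0.40 / 0.80) * (0.60 / 0.80))
        assert s.score == pytest.approx(expected)
        assert expected == pytest.approx(1.0 / 3.0, rel=1e-9)
        assert s.synergistic

    def test_threshold_is_strict(self):
        out = pd.concat(
            [
                _survival_block("normal", alive=100, dead=0),
                _survival_block("no_xiap", alive=100, dead=0),
                _survival_block("no_timer", alive=100, dead=0),
                _survival_block("no_xiap_no_timer", alive=90, dead=10),
            ]
        )
        s = webb_synergy(out, 100.0)
        assert s.score == 0.9  # exactly representable here
        assert not s.synergistic  # exactly 0.9 is NOT synergistic

    def test_zero_denominator_flagged(self):
        out = pd.concat(
            [
                _survival_block("normal", alive=0, dead=100),
                _survival_block("no_xiap", alive=50, dead=50),
                _survival_block("no_timer", alive=50, dead=50),
                _survival_block("no_xiap_no_timer", alive=25, dead=75),
            ]
        )
        s = webb_synergy(out, 100.0)
        assert not s.defined


class TestTimerContribution:
    def test_increases_with_weaker_c9_binding(self, params):
        """Weakening C9 platform binding (a faster timer) enlarges the
        cleavage difference between the timer-off and normal variants.  At
        the calibrated constants C9 is already nearly unbound, so the
        monotone trend is small but strictly resolved by the integrator."""
        cell = ap.default_initial_state(apaf1=0.3, pc9=0.005, pc3=0.3, xiap=0.5, smac_mito=0.3)
        state = ap.apply_momp(cell, 1.0)

        def contribution(p):
            c = {}
            for v in ("normal", "no_timer"):
                net = ap.build_network(p, ap.VARIANTS[v])
                c[v] = float(ap.simulate(net, state, 240.0, n_grid=49).c3_substrate_cleavage(240.0))
            return timer_contribution(c["normal"], c["no_timer"])

        slow = contribution(params.replace(koff_c9=params.koff_c9 / 20))
        fast = contribution(params.replace(koff_c9=params.koff_c9 * 10))
        assert slow >= -1e-9
        assert fast > slow

    def test_difference_and_rescue(self):
        assert timer_contribution(0.2, 0.5) == pytest.approx(0.3)
        assert timer_contribution(0.2, 0.2) == pytest.approx(0.0)
        rows = []
        # 4 cells die without timer; 1 of them survives with it
        for i, (d_norm, d_nt) in enumerate([(1, 1), (1, 1), (0, 1), (1, 1), (0, 0)]):
            rows.append((i, "normal", bool(d_norm), 100.0, 0, 0, 0, 0))
            rows.append((i, "no_timer", bool(d_nt), 80.0, 0, 0, 0, 0))
        out = pd.DataFrame(
            rows,
            columns=["id", "variant", "died", "event_time", "cleav15", "cleav30", "cleav60", "cleav240"],
        )
        assert timer_rescue_fraction(out) == pytest.approx(1.0 / 4.0)


def _survival_block(variant, alive, dead, death_time=50.0):
    rows = [(f"{variant}-a{i}", variant, False, 240.0) for i in range(alive)]
    rows += [(f"{variant}-d{i}", variant, True, death_time) for i in range(dead)]
    df = pd.DataFrame(rows, columns=["id", "variant", "died", "event_time"])
    for c in ("cleav15", "cleav30", "cleav60", "cleav240"):
        df[c] = 0.0
    return df


def test_survival_fraction_counts_raw_alive():
    out = _survival_block("normal", alive=3, dead=7, death_time=30.0)
    assert survival_fraction(out, "normal", 29.0) == pytest.approx(1.0)
    assert survival_fraction(out, "normal", 30.0) == pytest.approx(0.3)
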