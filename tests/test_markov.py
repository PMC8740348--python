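"""Markov cohort engine: death-probability conversion, single-cycle
arithmetic against hand enumeration, discounting identities, an exhaustive
branch-path oracle, and cohort-level invariants."""

import math

import numpy as np
import pytest

from evtdelay import (
    annual_death_prob,
    cycle_update,
    evaluate_all_strategies,
    evaluate_strategy,
    MRSDistribution,
    run_cohort,
)
from evtdelay.markov import _redistribution_matrix

from conftest import short_horizon


class TestAnnualDeathProb:
    def test_closed_form_matches_rate_formula(self, base_config):
        cfg = base_config.model_copy(deep=True)
        cfg.mortality.life_table[66] = 0.02
        got = annual_death_prob(66, 0, cfg.mortality)  # HR 1.54
        assert got == pytest.approx(1 - 0.98**1.54, abs=1e-12)
        assert got == pytest.approx(
            1 - math.exp(-(-math.log(1 - 0.02)) * 1.54), abs=1e-12
        )
        assert got == pytest.approx(0.030634, abs=2e-6)

    def test_identity_hazard_ratio_returns_life_table_value(self, config):
        config.mortality.hr_by_mrs[0].base = 1.0
        config.mortality.life_table[70] = 0.0123
        assert annual_death_prob(70, 0, config.mortality) == pytest.approx(0.0123)

    def test_certain_death_regardless_of_hr(self, config):
        config.mortality.life_table[99] = 1.0
        assert annual_death_prob(99, 5, config.mortality) == 1.0

    def test_uncovered_age_mentions_horizon_cap(self, base_config):
        with pytest.raises(ValueError, match="horizon"):
            annual_death_prob(130, 2, base_config.mortality)


class TestCycleUpdate:
    def test_all_dead_is_absorbing(self, base_config):
        state = np.array([0, 0, 0, 0, 0, 0, 1.0])
        nxt, qaly, cost = cycle_update(state, 70, 3, base_config)
        assert nxt == pytest.approx(state)
        assert qaly == 0.0 and cost == 0.0

    def test_static_cohort_accrues_state_utilities(self, config):
        for iv in config.mortality.hr_by_mrs:
            iv.base = 1.0
        for age in config.mortality.life_table:
            config.mortality.life_table[age] = 0.0
        config.recurrence.rate_by_year = {1: 0.0}
        state = np.array([0.3, 0.2, 0.1, 0.2, 0.1, 0.1, 0.0])
        nxt, qaly, cost = cycle_update(state, 70, 1, config)
        assert nxt == pytest.approx(state)
        assert qaly == pytest.approx(
            float(state[:6] @ config.utilities.base_array())
        )

    def test_single_state_hand_enumerated_branches(self, config):
        """Start all in mRS 2; compare against a by-hand expansion of the
        death / recur / stay branches to machine precision."""
        config.mortality.life_table[70] = 0.02
        config.recurrence.rate_by_year = {1: 0.082}
        config.recur_mrs_dist = MRSDistribution(p=[0, 0, 0, 0.5, 0.3, 0.1, 0.1])
        state = np.array([0, 0, 1.0, 0, 0, 0, 0])
        nxt, qaly, cost = cycle_update(state, 70, 1, config)

        hr2 = config.mortality.hr_by_mrs[2].base  # 2.18
        qd = 1 - 0.98**hr2
        surv = 1 - qd
        rec = surv * 0.082
        stay = surv - rec
        # truncation at s=2 leaves the distribution unchanged (no mass below)
        expected = np.zeros(7)
        expected[2] = stay
        expected[3] = rec * 0.5
        expected[4] = rec * 0.3
        expected[5] = rec * 0.1
        expected[6] = qd + rec * 0.1
        assert nxt == pytest.approx(expected, abs=1e-12)
        assert qaly == pytest.approx(surv * 0.74, abs=1e-12)
        assert cost == pytest.approx(
            surv * config.costs.longterm_mrs_0_2.base
            + rec * config.costs.recurrent_stroke.base,
            abs=1e-9,
        )

    def test_truncation_never_improves_disability(self, base_config):
        redis = _redistribution_matrix(base_config.recur_mrs_dist, "truncated")
        for s in range(6):
            assert redis[s, :s].sum() == 0.0
            assert redis[s].sum() == pytest.approx(1.0)


class TestRunCohort:
    def test_dead_on_entry_accrues_nothing(self, base_config):
        trace = run_cohort(MRSDistribution(p=[0, 0, 0, 0, 0, 0, 1]), base_config)
        assert trace.total_qaly == 0.0
        assert trace.total_cost == 0.0

    def test_undiscounted_annuity_identity(self, config):
        cfg = short_horizon(config, 10)
        cfg.discount_rate = 0.0
        for iv in cfg.mortality.hr_by_mrs:
            iv.base = 1.0
        for age in cfg.mortality.life_table:
            cfg.mortality.life_table[age] = 0.0
        cfg.recurrence.rate_by_year = {1: 0.0}
        cfg.utilities.u[0].base = 1.0
        trace = run_cohort(MRSDistribution(p=[1, 0, 0, 0, 0, 0, 0]), cfg)
        assert trace.total_qaly == pytest.approx(10.0, abs=1e-12)

    def test_three_percent_discount_geometric_series(self, config):
        cfg = short_horizon(config, 10)
        for iv in cfg.mortality.hr_by_mrs:
            iv.base = 1.0
        for age in cfg.mortality.life_table:
            cfg.mortality.life_table[age] = 0.0
        cfg.recurrence.rate_by_year = {1: 0.0}
        cfg.utilities.u[0].base = 1.0
        trace = run_cohort(MRSDistribution(p=[1, 0, 0, 0, 0, 0, 0]), cfg)
        expected = sum(1.03 ** -(c - 1) for c in range(1, 11))
        assert trace.total_qaly == pytest.approx(expected, abs=1e-9)
        assert round(expected, 4) == 8.7861

    def test_zero_discount_equals_sum_of_undiscounted_cycles(self, config):
        cfg = config
        cfg.discount_rate = 0.0
        trace = run_cohort(cfg.evt_mrs_dist["61-120"], cfg)
        assert trace.total_qaly == pytest.approx(trace.qaly_undisc.sum(), rel=1e-14)
        assert trace.total_cost == pytest.approx(trace.cost_undisc.sum(), rel=1e-14)

    def test_mass_conserved_and_death_absorbing(self, base_config):
        trace = run_cohort(base_config.nonevt_mrs_dist, base_config)
        sums = trace.occupancy.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, 6]) >= -1e-12)
        assert np.all(np.diff(np.cumsum(trace.qaly_disc)) >= 0)
        assert np.all(np.diff(np.cumsum(trace.cost_disc)) >= 0)


def enumerate_branch_paths(initial, config):
    """Independent oracle: expected discounted QALYs/costs by exhaustively
    expanding every death/recur/stay branch path (feasible for short
    horizons).  Accrual conventions mirror the documented cycle order:
    survivors accrue a full year; recurrence redistributes with truncation."""
    redis = _redistribution_matrix(
        config.recur_mrs_dist, config.recurrence_redistribution
    )
    u = config.utilities.base_array()
    lt = [config.costs.longterm_mrs_0_2.base] * 3 + [
        config.costs.longterm_mrs_3_5.base
    ] * 3
    n_cycles = config.horizon_age_cap - config.start_age
    totals = {"qaly": 0.0, "cost": 0.0}

    def recurse(s, cycle, prob):
        if cycle > n_cycles or prob == 0.0 or s == 6:
            return
        age = config.start_age + cycle - 1
        qd = annual_death_prob(age, s, config.mortality)
        r = config.recurrence.rate(cycle)
        disc = (1 + config.discount_rate) ** -(cycle - 1)
        surv_p = prob * (1 - qd)
        totals["qaly"] += surv_p * u[s] * disc
        totals["cost"] += surv_p * lt[s] * disc
        totals["cost"] += surv_p * r * config.costs.recurrent_stroke.base * disc
        recurse(s, cycle + 1, surv_p * (1 - r))
        for t in range(7):
            if redis[s, t] > 0:
                recurse(t, cycle + 1, surv_p * r * redis[s, t])

    p = initial.as_array()
    for s in range(6):
        recurse(s, 1, p[s])
    return totals["qaly"], totals["cost"]


def test_engine_matches_exhaustive_branch_oracle(config):
    cfg = short_horizon(config, 3)
    cfg.recur_mrs_dist = MRSDistribution(p=[0, 0, 0.2, 0.4, 0, 0.2, 0.2])
    initial = MRSDistribution(p=[0.0, 0.3, 0.4, 0.2, 0.0, 0.05, 0.05])
    trace = run_cohort(initial, cfg)
    q, c = enumerate_branch_paths(initial, cfg)
    assert trace.total_qaly == pytest.approx(q, abs=1e-10)
    assert trace.total_cost == pytest.approx(c, abs=1e-10)


class TestEvaluateStrategy:
    def test_zero_utilities_give_zero_qalys(self, config):
        for iv in config.utilities.u:
            iv.base = 0.0
        for o in evaluate_all_strategies(config):
            assert o.total_qaly == 0.0

    def test_window_matters_only_through_eligibility_and_distribution(self, config):
        for w in config.windows:
            w.evt_eligibility.base = 0.0
        a = evaluate_strategy(config.window("121-180"), config)
        b = evaluate_strategy(config.window("301-360"), config)
        assert a.total_qaly == pytest.approx(b.total_qaly, rel=1e-14)
        assert a.total_cost == pytest.approx(b.total_cost, rel=1e-14)

    def test_worse_initial_distribution_never_gains_qalys(self, base_config):
        better = MRSDistribution(p=[0.3, 0.3, 0.2, 0.1, 0.05, 0.05, 0.0])
        # shift mass from mRS 0 toward mRS 4 and death
        worse = MRSDistribution(p=[0.1, 0.3, 0.2, 0.1, 0.15, 0.05, 0.1])
        assert np.all(better.cumulative() >= worse.cumulative() - 1e-12)
        t_better = run_cohort(better, base_config)
        t_worse = run_cohort(worse, base_config)
        assert t_worse.total_qaly <= t_better.total_qaly

    def test_trace_export_has_one_row_per_cycle(self, base_config):
        trace = run_cohort(base_config.nonevt_mrs_dist, base_config)
        df = trace.to_frame()
        assert len(df) == base_config.horizon_age_cap - base_config.start_age
        assert {"cycle", "age", "dead", "qaly_disc", "cost_disc"} <= set(df.columns)
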