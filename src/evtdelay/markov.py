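"""Lifetime Markov cohort engine over mRS health states with annual cycles.

After the acute phase the cohort occupies seven states: living mRS 0..5 and
dead (absorbing; 90-day mRS 6 enters dead directly).  Each one-year cycle,
in order: (1) death, combining the age-specific life-table probability with
the mRS-specific excess-mortality hazard ratio; (2) recurrent stroke among
survivors at the years-since-index rate, redistributing over the recurrent
90-day mRS distribution (by default truncated so disability cannot
improve); (3) everyone else remains in state.  Utilities and annual costs
accrue on cycle survivors — those dying within a cycle accrue nothing that
cycle unless the half-cycle correction is enabled, in which case they accrue
half a year.  Cycle c (c = 1, 2, ...) is discounted by (1+r)^-(c-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acute import acute_phase
from .config import ModelConfig, MortalityInputs, MRSDistribution, TimeWindow

_STATE_NAMES = ["mrs0", "mrs1", "mrs2", "mrs3", "mrs4", "mrs5", "dead"]


def annual_death_prob(age: int, mrs: int, mortality: MortalityInputs) -> float:
    """Annual death probability at a given age and mRS state.

    The life-table probability q is converted to a hazard rate -ln(1-q),
    scaled by the state's hazard ratio, and converted back:
    1 - exp(-rate * HR), algebraically 1 - (1-q)^HR.
    """
    if not 0 <= mrs <= 5:
        raise ValueError("mrs must be in 0..5")
    if age not in mortality.life_table:
        raise ValueError(
            f"life table does not cover age {age}; extend it or lower "
            f"horizon_age_cap"
        )
    q = mortality.life_table[age]
    if q >= 1.0:
        return 1.0
    hr = mortality.hr_by_mrs[mrs].base
    return 1.0 - math.exp(math.log1p(-q) * hr)


def _redistribution_matrix(
    recur_dist: MRSDistribution, mode: str
) -> np.ndarray:
    """Row s: destination distribution over the 7 states after a recurrent
    stroke from living state s.  In ``truncated`` mode mass below s is
    removed and the row renormalized (disability cannot improve); a row with
    no remaining mass degenerates to staying in s."""
    g = recur_dist.as_array()
    rows = np.zeros((6, 7))
    for s in range(6):
        if mode == "untruncated":
            w = g.copy()
        else:
            w = g.copy()
            w[:s] = 0.0
        tot = w.sum()
        if tot <= 0:
            rows[s, s] = 1.0
        else:
            rows[s] = w / tot
    return rows


def _single_step(
    state: np.ndarray,
    qd: np.ndarray,
    recur_rate: float,
    u: np.ndarray,
    annual_cost: np.ndarray,
    recur_cost: float,
    redis: np.ndarray,
    half_cycle: bool,
) -> tuple[np.ndarray, float, float]:
    living = state[:6]
    dead_new = living * qd
    surv = living - dead_new
    rec = surv * recur_rate
    stay = surv - rec
    moved = rec @ redis
    nxt = np.empty(7)
    nxt[:6] = stay + moved[:6]
    nxt[6] = state[6] + dead_new.sum() + moved[6]
    qaly = float(surv @ u)
    cost = float(surv @ annual_cost) + float(rec.sum()) * recur_cost
    if half_cycle:
        qaly += 0.5 * float(dead_new @ u)
        cost += 0.5 * float(dead_new @ annual_cost)
    return nxt, qaly, cost


class _CompiledModel:
    """Per-config precomputation shared by all cycles (and all strategies)."""

    def __init__(self, config: ModelConfig):
        self.n_cycles = config.horizon_age_cap - config.start_age
        self.start_age = config.start_age
        self.u = config.utilities.base_array()
        lt02 = config.costs.longterm_mrs_0_2.base
        lt35 = config.costs.longterm_mrs_3_5.base
        self.annual_cost = np.array([lt02] * 3 + [lt35] * 3)
        hr = config.mortality.hr_base_array()
        q = np.array(
            [config.mortality.life_table[config.start_age + c] for c in range(self.n_cycles)]
        )
        with np.errstate(divide="ignore"):
            self.qd = 1.0 - np.exp(np.outer(np.log1p(-q), hr))
        self.recur_rate = np.array(
            [config.recurrence.rate(c + 1) for c in range(self.n_cycles)]
        )
        self.recur_cost = config.costs.recurrent_stroke.base
        self.redis = _redistribution_matrix(
            config.recur_mrs_dist, config.recurrence_redistribution
        )
        self.disc = (1.0 + config.discount_rate) ** (-np.arange(self.n_cycles))
        self.half_cycle = config.half_cycle_correction


def cycle_update(
    state: np.ndarray | list[float],
    age: int,
    year_since_index: int,
    config: ModelConfig,
) -> tuple[np.ndarray, float, float]:
    """One annual cycle: returns (next state vector, cycle QALYs, cycle cost).

    ``state`` is the 7-vector over {mRS 0..5, dead}; QALYs and cost are
    undiscounted.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (7,):
        raise ValueError("state vector must have 7 entries (mRS 0..5, dead)")
    qd = np.array(
        [annual_death_prob(age, s, config.mortality) for s in range(6)]
    )
    lt02 = config.costs.longterm_mrs_0_2.base
    lt35 = config.costs.longterm_mrs_3_5.base
    return _single_step(
        state,
        qd,
        config.recurrence.rate(year_since_index),
        config.utilities.base_array(),
        np.array([lt02] * 3 + [lt35] * 3),
        config.costs.recurrent_stroke.base,
        _redistribution_matrix(
            config.recur_mrs_dist, config.recurrence_redistribution
        ),
        config.half_cycle_correction,
    )


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run (cycle c covers age start_age+c-1)."""

    cycles: np.ndarray
    ages: np.ndarray
    occupancy: np.ndarray  # (n_cycles + 1, 7): start-of-cycle states plus final
    qaly_undisc: np.ndarray
    qaly_disc: np.ndarray
    cost_undisc: np.ndarray
    cost_disc: np.ndarray

    @property
    def total_qaly(self) -> float:
        return float(self.qaly_disc.sum())

    @property
    def total_cost(self) -> float:
        return float(self.cost_disc.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy[:-1], columns=_STATE_NAMES)
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", self.cycles)
        df["qaly_undisc"] = self.qaly_undisc
        df["qaly_disc"] = self.qaly_disc
        df["cost_undisc"] = self.cost_undisc
        df["cost_disc"] = self.cost_disc
        df["cum_qaly_disc"] = np.cumsum(self.qaly_disc)
        df["cum_cost_disc"] = np.cumsum(self.cost_disc)
        return df


@dataclass(frozen=True)
class StrategyOutcome:
    """Lifetime discounted totals for one treatment-initiation window."""

    window: TimeWindow
    total_cost: float
    total_qaly: float

    @property
    def label(self) -> str:
        return self.window.label


def _run_compiled(initial: MRSDistribution, cm: _CompiledModel) -> CohortTrace:
    state = np.zeros(7)
    p = initial.as_array()
    state[:6] = p[:6]
    state[6] = p[6]  # 90-day deaths enter the absorbing state directly
    occ = np.empty((cm.n_cycles + 1, 7))
    qalys = np.empty(cm.n_cycles)
    costs = np.empty(cm.n_cycles)
    for c in range(cm.n_cycles):
        occ[c] = state
        state, q, k = _single_step(
            state,
            cm.qd[c],
            cm.recur_rate[c],
            cm.u,
            cm.annual_cost,
            cm.recur_cost,
            cm.redis,
            cm.half_cycle,
        )
        qalys[c] = q
        costs[c] = k
        if abs(state.sum() - 1.0) > 1e-9:
            raise AssertionError(f"cohort mass not conserved at cycle {c + 1}")
        if state[6] < occ[c, 6] - 1e-12:
            raise AssertionError(f"dead-state mass decreased at cycle {c + 1}")
    occ[cm.n_cycles] = state
    return CohortTrace(
        cycles=np.arange(1, cm.n_cycles + 1),
        ages=cm.start_age + np.arange(cm.n_cycles),
        occupancy=occ,
        qaly_undisc=qalys,
        qaly_disc=qalys * cm.disc,
        cost_undisc=costs,
        cost_disc=costs * cm.disc,
    )


def run_cohort(initial: MRSDistribution, config: ModelConfig) -> CohortTrace:
    """Propagate a 90-day cohort to the horizon age cap with discounting."""
    return _run_compiled(initial, _CompiledModel(config))


def evaluate_strategy(window: TimeWindow, config: ModelConfig) -> StrategyOutcome:
    """Acute decision tree + lifetime Markov run for one window."""
    acute = acute_phase(window, config)
    trace = run_cohort(acute.initial_state, config)
    return StrategyOutcome(
        window=window,
        total_cost=acute.acute_cost + trace.total_cost,
        total_qaly=trace.total_qaly,
    )


def evaluate_all_strategies(config: ModelConfig) -> list[StrategyOutcome]:
    """Evaluate all six windows, sharing the per-config precomputation."""
    cm = _CompiledModel(config)
    out = []
    for w in config.windows:
        acute = acute_phase(w, config)
        trace = _run_compiled(acute.initial_state, cm)
        out.append(
            StrategyOutcome(
                window=w,
                total_cost=acute.acute_cost + trace.total_cost,
                total_qaly=trace.total_qaly,
            )
        )
    return out
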