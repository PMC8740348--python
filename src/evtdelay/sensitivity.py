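"""Deterministic (tornado) and probabilistic sensitivity analysis with CEAC.

The one-way DSA perturbs each uncertain scalar to its lower then upper bound
(everything else at base) and records the ICER of a designated window pair.
The PSA redraws every uncertain scalar from its fitted distribution — costs
from gamma, hazard ratios from log-normal, probabilities and utilities from
beta — and every mRS distribution from a Dirichlet whose concentration is an
effective sample size times the base probabilities, then re-evaluates all
six strategies.  The cost-effectiveness acceptability curve (CEAC) reports,
per willingness-to-pay value, the probability each strategy maximizes net
monetary benefit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import (
    ci_to_distribution,
    Interval,
    ModelConfig,
    MRSDistribution,
)
from .frontier import UndefinedICERError, icer
from .markov import evaluate_all_strategies, evaluate_strategy, StrategyOutcome


@dataclass(frozen=True)
class ParamRef:
    """One uncertain scalar: display name, PSA family, and an accessor that
    returns its (mutable) Interval on a given config."""

    name: str
    family: str
    get: Callable[[ModelConfig], Interval]


def uncertain_scalars(config: ModelConfig) -> list[ParamRef]:
    """All scalars with sensitivity ranges: window eligibilities and IVT
    shares (beta), hazard ratios (log-normal), utilities (beta), costs
    (gamma).  The recurrence schedule and life table carry no interval and
    stay fixed."""
    refs: list[ParamRef] = []
    for idx, w in enumerate(config.windows):
        refs.append(
            ParamRef(
                f"EVT eligibility {w.label} min",
                "beta",
                lambda c, i=idx: c.windows[i].evt_eligibility,
            )
        )
    refs.append(
        ParamRef("IVT share, EVT patients", "beta", lambda c: c.ivt.share_evt_arm)
    )
    refs.append(
        ParamRef(
            "IVT share, non-EVT patients", "beta", lambda c: c.ivt.share_nonevt_arm
        )
    )
    for s in range(6):
        refs.append(
            ParamRef(
                f"Death hazard ratio mRS {s}",
                "lognormal",
                lambda c, i=s: c.mortality.hr_by_mrs[i],
            )
        )
    for s in range(6):
        refs.append(
            ParamRef(
                f"Utility mRS {s}", "beta", lambda c, i=s: c.utilities.u[i]
            )
        )
    cost_names = {
        "acute_mrs_0_2": "Acute 90-day cost mRS 0-2",
        "acute_mrs_3_5": "Acute 90-day cost mRS 3-5",
        "acute_mrs_6": "Acute 90-day cost mRS 6",
        "longterm_mrs_0_2": "Long-term annual cost mRS 0-2",
        "longterm_mrs_3_5": "Long-term annual cost mRS 3-5",
        "addon_evt": "Additional cost of EVT",
        "addon_ivt": "Additional cost of IVT",
        "recurrent_stroke": "Cost of recurrent stroke",
    }
    for attr, name in cost_names.items():
        refs.append(
            ParamRef(name, "gamma", lambda c, a=attr: getattr(c.costs, a))
        )
    return refs


@dataclass
class TornadoEntry:
    parameter: str
    low_icer: float | None
    high_icer: float | None
    base_icer: float
    undefined: bool = False

    @property
    def width(self) -> float:
        if self.undefined or self.low_icer is None or self.high_icer is None:
            return math.nan
        return abs(self.high_icer - self.low_icer)


def _pair_icer(config: ModelConfig, pair: tuple[str, str]) -> float:
    a = evaluate_strategy(config.window(pair[0]), config)
    b = evaluate_strategy(config.window(pair[1]), config)
    return icer(a, b)


def one_way_dsa(
    config: ModelConfig, pair: tuple[str, str]
) -> list[TornadoEntry]:
    """Tornado entries for every ranged parameter, sorted by descending bar
    width (undefined entries, where a setting makes the pair's QALYs equal,
    are flagged and sorted last).  The input config is never modified."""
    base_icer = _pair_icer(config, pair)
    entries: list[TornadoEntry] = []
    for ref in uncertain_scalars(config):
        vals: list[float | None] = []
        undefined = False
        iv = ref.get(config)
        for bound in (iv.lower, iv.upper):
            work = config.model_copy(deep=True)
            ref.get(work).base = bound
            try:
                vals.append(_pair_icer(work, pair))
            except UndefinedICERError:
                vals.append(None)
                undefined = True
        entries.append(
            TornadoEntry(ref.name, vals[0], vals[1], base_icer, undefined)
        )
    entries.sort(key=lambda e: (math.isnan(e.width), -(e.width if not math.isnan(e.width) else 0.0)))
    return entries


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_icer": e.low_icer,
                "high_icer": e.high_icer,
                "base_icer": e.base_icer,
                "width": e.width,
                "undefined": e.undefined,
            }
            for e in entries
        ]
    )


def _draw_mrs(
    dist: MRSDistribution, effective_n: float, rng: np.random.Generator
) -> MRSDistribution:
    p = dist.as_array()
    pos = p > 0
    alpha = effective_n * p[pos]
    draw = np.zeros(7)
    draw[pos] = rng.dirichlet(alpha)
    # guard the simplex against float round-off
    draw = draw / draw.sum()
    return MRSDistribution(p=[float(x) for x in draw])


def draw_parameters(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """One PSA draw: a deep-copied config whose uncertain scalars and mRS
    distributions are resampled.  Deterministic given the generator state."""
    work = config.model_copy(deep=True)
    for ref in uncertain_scalars(config):
        iv = ref.get(work)
        spec = ci_to_distribution(iv.base, iv.lower, iv.upper, ref.family)
        iv.base = spec.sample(rng)
    n_eff = config.dirichlet_effective_n
    for lb, dist in config.evt_mrs_dist.items():
        work.evt_mrs_dist[lb] = _draw_mrs(dist, n_eff, rng)
    work.nonevt_mrs_dist = _draw_mrs(config.nonevt_mrs_dist, n_eff, rng)
    work.recur_mrs_dist = _draw_mrs(config.recur_mrs_dist, n_eff, rng)
    return work


@dataclass
class PSAResult:
    """Per-iteration discounted (cost, QALY) draws per strategy."""

    labels: list[str]
    costs: np.ndarray  # (n_iterations, n_strategies)
    qalys: np.ndarray
    n_iterations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for j, lb in enumerate(self.labels):
            rows[f"cost_{lb}"] = self.costs[:, j]
            rows[f"qaly_{lb}"] = self.qalys[:, j]
        df = pd.DataFrame(rows)
        df.insert(0, "iteration", np.arange(self.n_iterations))
        return df


def run_psa(
    config: ModelConfig,
    n_iterations: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Monte-Carlo re-evaluation of all six strategies under joint parameter
    uncertainty; reproducible for a given seed."""
    n = config.psa_iterations if n_iterations is None else n_iterations
    if n < 1:
        raise ValueError("need at least one PSA iteration")
    s = config.psa_seed if seed is None else seed
    rng = np.random.default_rng(s)
    labels = [w.label for w in config.windows]
    costs = np.empty((n, len(labels)))
    qalys = np.empty((n, len(labels)))
    for i in range(n):
        try:
            drawn = draw_parameters(config, rng)
            outcomes = evaluate_all_strategies(drawn)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
        for j, o in enumerate(outcomes):
            costs[i, j] = o.total_cost
            qalys[i, j] = o.total_qaly
    return PSAResult(labels=labels, costs=costs, qalys=qalys, n_iterations=n, seed=s)


@dataclass
class CEACCurve:
    """P(strategy maximizes NMB) over a WTP grid; ties split equally."""

    wtp_grid: np.ndarray
    probabilities: np.ndarray  # (len(grid), n_strategies)
    labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probabilities, columns=self.labels)
        df.insert(0, "wtp", self.wtp_grid)
        return df

    def probability_at(self, wtp: float, label: str) -> float:
        idx = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        if abs(self.wtp_grid[idx] - wtp) > 1e-9:
            raise ValueError(f"wtp {wtp} not on the grid")
        return float(self.probabilities[idx, self.labels.index(label)])


def default_wtp_grid(
    step: float = 5000.0,
    top: float = 250000.0,
    include: tuple[float, ...] = (71000.0, 213000.0),
) -> np.ndarray:
    """0 to 250,000 CNY/QALY in 5,000 steps, plus the 1x and 3x
    GDP-per-capita thresholds (71,000 and 213,000)."""
    grid = set(np.arange(0.0, top + step / 2, step)) | set(include)
    return np.array(sorted(grid))


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> CEACCurve:
    """Probability each strategy is optimal (max NMB) at each WTP value."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("WTP grid is empty")
    probs = np.empty((grid.size, len(psa.labels)))
    for g, w in enumerate(grid):
        nmb = psa.qalys * w - psa.costs
        best = nmb.max(axis=1, keepdims=True)
        winners = (nmb == best).astype(float)
        winners /= winners.sum(axis=1, keepdims=True)
        probs[g] = winners.mean(axis=0)
    return CEACCurve(wtp_grid=grid, probabilities=probs, labels=list(psa.labels))
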