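"""Cost-effectiveness comparison: ICERs, net monetary benefit, the
efficiency frontier with strict and extended dominance, and per-delay loss
metrics.

Strategies are sorted by ascending cost.  A strategy is *dominated* if some
other strategy yields at least as many QALYs at no greater cost (strictly
better in one).  Among the non-dominated set, *extended dominance* removes
strategies whose sequential ICER exceeds that of the next more effective
strategy, iterating until the sequential ICERs strictly increase; the
survivors form the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .markov import StrategyOutcome

DOMINANCE_LABELS = ("on_frontier", "dominated", "extended_dominated")


class UndefinedICERError(ValueError):
    """Raised when two strategies have identical QALYs (ICER undefined)."""


def icer(a: StrategyOutcome, b: StrategyOutcome) -> float:
    """Incremental cost-effectiveness ratio of a versus b (CNY per QALY)."""
    dq = a.total_qaly - b.total_qaly
    if dq == 0:
        raise UndefinedICERError(
            f"ICER undefined: {a.label} and {b.label} have equal QALYs"
        )
    return (a.total_cost - b.total_cost) / dq


def inmb(a: StrategyOutcome, b: StrategyOutcome, wtp: float) -> float:
    """Incremental net monetary benefit of a versus b at a WTP (CNY)."""
    return (a.total_qaly - b.total_qaly) * wtp - (a.total_cost - b.total_cost)


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit: QALYs valued at WTP minus cost (CNY)."""
    return outcome.total_qaly * wtp - outcome.total_cost


@dataclass
class FrontierEntry:
    outcome: StrategyOutcome
    dominance: str  # one of DOMINANCE_LABELS
    incremental_cost: float | None = None  # vs previous frontier member
    incremental_qaly: float | None = None
    sequential_icer: float | None = None
    inmb_vs_prev: float | None = None


@dataclass
class FrontierResult:
    """Strategies sorted by ascending cost with dominance labels; frontier
    members carry incremental quantities versus the previous frontier member."""

    entries: list[FrontierEntry]
    wtp: float

    def frontier(self) -> list[FrontierEntry]:
        return [e for e in self.entries if e.dominance == "on_frontier"]

    def labels(self) -> dict[str, str]:
        return {e.outcome.label: e.dominance for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "window": e.outcome.label,
                    "cost": e.outcome.total_cost,
                    "qaly": e.outcome.total_qaly,
                    "dominance": e.dominance,
                    "incremental_cost": e.incremental_cost,
                    "incremental_qaly": e.incremental_qaly,
                    "icer": e.sequential_icer,
                    "inmb": e.inmb_vs_prev,
                }
            )
        return pd.DataFrame(rows)


def efficiency_frontier(
    outcomes: Sequence[StrategyOutcome], wtp: float
) -> FrontierResult:
    """Classify strategies and compute sequential ICERs on the frontier.

    Cost ties sort by descending QALY; exact (cost, QALY) duplicates keep the
    first occurrence as the candidate and mark later copies dominated.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two strategies")
    order = sorted(
        range(len(outcomes)),
        key=lambda i: (outcomes[i].total_cost, -outcomes[i].total_qaly),
    )
    ordered = [outcomes[i] for i in order]
    n = len(ordered)

    dominated = [False] * n
    seen_exact: set[tuple[float, float]] = set()
    for i, oi in enumerate(ordered):
        key = (oi.total_cost, oi.total_qaly)
        if key in seen_exact:
            dominated[i] = True
            continue
        for j, oj in enumerate(ordered):
            if i == j:
                continue
            if (
                oj.total_cost <= oi.total_cost
                and oj.total_qaly >= oi.total_qaly
                and (oj.total_cost < oi.total_cost or oj.total_qaly > oi.total_qaly)
            ):
                dominated[i] = True
                break
        if not dominated[i]:
            seen_exact.add(key)

    candidates = [i for i in range(n) if not dominated[i]]
    extended: set[int] = set()
    while len(candidates) >= 3:
        icers = [
            icer(ordered[candidates[k]], ordered[candidates[k - 1]])
            for k in range(1, len(candidates))
        ]
        removed = False
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                extended.add(candidates[k + 1])
                del candidates[k + 1]
                removed = True
                break
        if not removed:
            break

    entries = []
    prev: StrategyOutcome | None = None
    for i, o in enumerate(ordered):
        if dominated[i]:
            entries.append(FrontierEntry(o, "dominated"))
        elif i in extended:
            entries.append(FrontierEntry(o, "extended_dominated"))
        else:
            e = FrontierEntry(o, "on_frontier")
            if prev is not None:
                e.incremental_cost = o.total_cost - prev.total_cost
                e.incremental_qaly = o.total_qaly - prev.total_qaly
                e.sequential_icer = icer(o, prev)
                e.inmb_vs_prev = inmb(o, prev, wtp)
            entries.append(e)
            prev = o
    return FrontierResult(entries=entries, wtp=wtp)


@dataclass(frozen=True)
class DelayLossMetrics:
    """Average loss per unit of treatment delay across the six windows."""

    qaly_per_min: float
    qaly_per_hour: float
    healthy_days_per_min: float
    healthy_days_per_hour: float
    nmb_per_min: float
    nmb_per_hour: float

    def to_dict(self) -> dict[str, float]:
        return {
            "qaly_per_min": self.qaly_per_min,
            "qaly_per_hour": self.qaly_per_hour,
            "healthy_days_per_min": self.healthy_days_per_min,
            "healthy_days_per_hour": self.healthy_days_per_hour,
            "nmb_per_min": self.nmb_per_min,
            "nmb_per_hour": self.nmb_per_hour,
        }


def _slope(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "ols":
        # covariance form: exactly zero for constant y, unlike a generic
        # least-squares solve
        dx = x - x.mean()
        dy = y - y.mean()
        return float(dx @ dy / (dx @ dx))
    if method == "endpoint":
        i, j = int(np.argmin(x)), int(np.argmax(x))
        return float((y[j] - y[i]) / (x[j] - x[i]))
    if method == "pairwise_mean":
        order = np.argsort(x)
        xs, ys = x[order], y[order]
        return float(np.mean(np.diff(ys) / np.diff(xs)))
    raise ValueError(f"unknown slope method {method!r}")


def delay_loss(
    outcomes: Sequence[StrategyOutcome],
    wtp: float,
    days_per_year: float = 365.25,
    method: str = "ols",
) -> DelayLossMetrics:
    """Average QALY, healthy-day, and NMB loss per minute/hour of delay.

    The per-minute loss is the magnitude of the regression slope of the
    lifetime outcome against the window midpoint (default OLS; ``endpoint``
    and ``pairwise_mean`` are alternatives).  Healthy days convert QALYs at
    ``days_per_year``; per-hour values are exactly 60x per-minute.
    """
    x = np.array([o.window.midpoint_min for o in outcomes], dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least two distinct window midpoints")
    qaly = np.array([o.total_qaly for o in outcomes])
    nmb_vals = np.array([nmb(o, wtp) for o in outcomes])
    q_min = abs(_slope(x, qaly, method))
    n_min = abs(_slope(x, nmb_vals, method))
    d_min = q_min * days_per_year
    return DelayLossMetrics(
        qaly_per_min=q_min,
        qaly_per_hour=60.0 * q_min,
        healthy_days_per_min=d_min,
        healthy_days_per_hour=60.0 * d_min,
        nmb_per_min=n_min,
        nmb_per_hour=60.0 * n_min,
    )
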