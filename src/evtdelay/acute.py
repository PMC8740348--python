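"""Acute-phase decision tree: 90-day outcome mixing and expected acute cost.

Within each onset-to-puncture window a fraction *e* of patients (the EVT
eligibility of that window) receives EVT and the rest receive non-EVT care.
The population-expected 90-day mRS distribution is the eligibility-weighted
mixture of the two arms' outcome distributions, and the expected acute cost
adds band-specific 90-day costs to the procedure add-ons, with the IVT
add-on scaled by each arm's share of IVT co-treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import (
    CostInputs,
    IVTShares,
    ModelConfig,
    MRSDistribution,
    TimeWindow,
)


@dataclass(frozen=True)
class AcuteResult:
    """Population-expected 90-day state and expected acute-phase cost (CNY)."""

    initial_state: MRSDistribution
    acute_cost: float


def expected_initial_state(
    window: TimeWindow,
    evt_dist: MRSDistribution,
    nonevt_dist: MRSDistribution,
) -> MRSDistribution:
    """Eligibility-weighted mixture of EVT and non-EVT 90-day mRS distributions."""
    e = window.evt_eligibility.base
    p = e * evt_dist.as_array() + (1.0 - e) * nonevt_dist.as_array()
    return MRSDistribution(p=[float(x) for x in p])


def expected_acute_cost(
    window: TimeWindow,
    state: MRSDistribution,
    costs: CostInputs,
    ivt: IVTShares,
) -> float:
    """Expected per-patient acute cost over the first 90 days (CNY).

    Band costs are weighted by the population state aggregated into mRS
    bands {0-2, 3-5, 6}; the EVT add-on applies to the eligible fraction and
    the IVT add-on to each arm's IVT share.
    """
    p = state.as_array()
    p_0_2 = float(p[0:3].sum())
    p_3_5 = float(p[3:6].sum())
    p_6 = float(p[6])
    e = window.evt_eligibility.base
    band_cost = (
        p_0_2 * costs.acute_mrs_0_2.base
        + p_3_5 * costs.acute_mrs_3_5.base
        + p_6 * costs.acute_mrs_6.base
    )
    addons = e * (costs.addon_evt.base + ivt.share_evt_arm.base * costs.addon_ivt.base)
    addons += (1.0 - e) * ivt.share_nonevt_arm.base * costs.addon_ivt.base
    return band_cost + addons


def acute_phase(window: TimeWindow, config: ModelConfig) -> AcuteResult:
    """Run the decision tree for one window of a full configuration."""
    state = expected_initial_state(
        window, config.evt_mrs_dist[window.label], config.nonevt_mrs_dist
    )
    cost = expected_acute_cost(window, state, config.costs, config.ivt)
    return AcuteResult(initial_state=state, acute_cost=cost)
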