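"""Synthetic stand-ins for the three inputs the published tables do not
print: 90-day mRS outcome distributions, the background life table, and the
annual recurrence schedule.

The mRS distributions come from a proportional-odds (ordered-logit)
construction: every distribution shares one set of cutpoints and differs
only by a latent severity shift, so a larger shift is strictly worse at
every mRS cutoff (first-order stochastic dominance by construction).  EVT
severity worsens linearly with onset-to-puncture delay; the non-EVT and
recurrent-stroke distributions carry shifts larger than the slowest EVT
window, making them strictly worse than every EVT arm.  The life table is a
Gompertz hazard, strictly increasing in age; the recurrence schedule
declines linearly from its year-1 value to a late-phase plateau.

These stand-ins have the structure the analysis relies on (stochastic
ordering, monotone mortality, bounded recurrence) but are not estimates of
the real trial or registry quantities; users holding the real inputs drop
them into the same config schema.
"""

from __future__ import annotations

import math

from pydantic import BaseModel
from scipy.special import expit, logit

from .config import (
    Interval,
    ModelConfig,
    MortalityInputs,
    MRSDistribution,
    RecurrenceSchedule,
    standard_windows,
    WINDOW_LABELS,
)

#: cutpoint offsets (log-odds) of P(mRS <= k), k = 0..5, relative to the
#: mRS <= 2 cutpoint; shaped after typical 90-day EVT-arm outcome patterns.
_CUTPOINT_OFFSETS = (-2.037, -0.860, 0.0, 0.650, 1.313, 1.895)


class FixtureSpec(BaseModel):
    """Knobs of the synthetic-input generator (all deterministic given seed)."""

    seed: int = 20240101
    p_good_first_window: float = 0.46  # P(mRS 0-2) for EVT at 61-120 min
    decay_per_hour: float = 0.20  # latent log-odds worsening per hour of delay
    nonevt_shift: float = 1.2  # log-odds shift of the non-EVT arm
    recur_shift: float = 1.3  # log-odds shift after a recurrent stroke
    gompertz_b: float = 2.5e-5  # baseline hazard scale of the life table
    gompertz_c: float = 0.095  # per-year log-hazard slope
    recur_rate_year1: float = 0.082
    recur_rate_late: float = 0.044
    recur_decline_years: int = 10


def _prop_odds(theta2: float, eta: float) -> MRSDistribution:
    cum = [expit(theta2 + off - eta) for off in _CUTPOINT_OFFSETS]
    cum.append(1.0)
    p = [cum[0]] + [cum[k] - cum[k - 1] for k in range(1, 7)]
    total = sum(p)
    return MRSDistribution(p=[float(x / total) for x in p])


def synth_mrs_by_window(
    spec: FixtureSpec,
) -> tuple[dict[str, MRSDistribution], MRSDistribution, MRSDistribution]:
    """(EVT distribution per window, non-EVT distribution, recurrence
    distribution), with later windows stochastically worse than earlier ones
    and both non-EVT arms worse than every EVT window."""
    theta2 = float(logit(spec.p_good_first_window))
    windows = standard_windows()
    anchor = windows[0].midpoint_min  # severity shift measured from 61-120
    by_window: dict[str, MRSDistribution] = {}
    for w in windows:
        eta = spec.decay_per_hour * (w.midpoint_min - anchor) / 60.0
        by_window[w.label] = _prop_odds(theta2, eta)
    max_eta = spec.decay_per_hour * (windows[-1].midpoint_min - anchor) / 60.0
    if spec.decay_per_hour > 0:
        for name, shift in (("nonevt_shift", spec.nonevt_shift),
                            ("recur_shift", spec.recur_shift)):
            if shift <= max_eta:
                raise ValueError(
                    f"{name} must exceed the slowest EVT window's severity "
                    f"shift ({max_eta:.3g}) to keep it strictly worse"
                )
    nonevt = _prop_odds(theta2, spec.nonevt_shift)
    recur = _prop_odds(theta2, spec.recur_shift)
    return by_window, nonevt, recur


def synth_life_table(
    spec: FixtureSpec, start_age: int = 66, end_age: int = 100
) -> dict[int, float]:
    """Gompertz annual death probabilities q(a) = 1 - exp(-b e^{c a}),
    strictly increasing in age for c > 0."""
    if spec.gompertz_b <= 0 or spec.gompertz_c < 0:
        raise ValueError("Gompertz parameters must be positive")
    return {
        a: min(1.0, 1.0 - math.exp(-spec.gompertz_b * math.exp(spec.gompertz_c * a)))
        for a in range(start_age, end_age + 1)
    }


def synth_recurrence(spec: FixtureSpec) -> RecurrenceSchedule:
    """Annual recurrence declining linearly from the year-1 rate to the late
    rate over ``recur_decline_years`` years, constant thereafter."""
    y1, late, k = spec.recur_rate_year1, spec.recur_rate_late, spec.recur_decline_years
    rates = {
        y: y1 + (late - y1) * (y - 1) / (k - 1) if k > 1 else y1
        for y in range(1, k + 1)
    }
    return RecurrenceSchedule(rate_by_year=rates)


def default_fixture(spec: FixtureSpec | None = None) -> ModelConfig:
    """Complete base-case configuration: published clinical/cost/utility
    inputs combined with the synthetic stand-ins above."""
    spec = spec or FixtureSpec()
    evt_by_window, nonevt, recur = synth_mrs_by_window(spec)
    return ModelConfig(
        windows=standard_windows(),
        evt_mrs_dist=evt_by_window,
        nonevt_mrs_dist=nonevt,
        recur_mrs_dist=recur,
        costs={
            "acute_mrs_0_2": Interval(base=11314, lower=11147, upper=11483),
            "acute_mrs_3_5": Interval(base=15448, lower=15109, upper=15792),
            "acute_mrs_6": Interval(base=12513, lower=11499, upper=13594),
            "longterm_mrs_0_2": Interval(base=8310, lower=8052, upper=8573),
            "longterm_mrs_3_5": Interval(base=12771, lower=11499, upper=13594),
            "addon_evt": Interval(base=12579, lower=11877, upper=13310),
            "addon_ivt": Interval(base=68436, lower=58864, upper=79115),
            "recurrent_stroke": Interval(base=15448, lower=15109, upper=15792),
        },
        utilities={
            "u": [
                Interval(base=0.92, lower=0.88, upper=0.96),
                Interval(base=0.84, lower=0.81, upper=0.87),
                Interval(base=0.74, lower=0.70, upper=0.78),
                Interval(base=0.58, lower=0.53, upper=0.63),
                Interval(base=0.37, lower=0.32, upper=0.42),
                Interval(base=0.15, lower=0.11, upper=0.19),
            ]
        },
        mortality=MortalityInputs(
            life_table=synth_life_table(spec),
            # ranges for mRS 2 and 3 are kept verbatim from the published
            # table even though they do not bracket the base values
            hr_by_mrs=[
                Interval(base=1.54, lower=1.21, upper=1.84),
                Interval(base=1.54, lower=1.21, upper=1.84),
                Interval(base=2.18, lower=1.58, upper=1.69),
                Interval(base=3.18, lower=1.58, upper=1.69),
                Interval(base=4.56, lower=2.37, upper=3.03),
                Interval(base=6.56, lower=3.83, upper=6.44),
            ],
        ),
        recurrence=synth_recurrence(spec),
        ivt={
            "share_evt_arm": Interval(base=0.83, lower=0.82, upper=0.84),
            "share_nonevt_arm": Interval(base=0.88, lower=0.87, upper=0.89),
        },
        start_age=66,
        discount_rate=0.03,
        wtp=71000.0,
        horizon_age_cap=100,
        psa_iterations=10000,
        psa_seed=spec.seed,
    )
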