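"""Published base-case reference values used for desk cross-checks.

These are the reported lifetime discounted totals (2019 CNY; QALYs) for the
six onset-to-puncture windows in the Chinese EVT-delay cost-effectiveness
study this model re-implements, together with its willingness-to-pay
threshold.  They serve as *inputs* to the frontier, ICER and delay-loss
machinery — desk-scale checks that the comparison layer reproduces the
reported rankings and ratios — not as outputs of this package's Markov
engine, whose own inputs include synthetic stand-ins (see
:mod:`evtdelay.synthetic`).
"""

from __future__ import annotations

from .config import standard_windows
from .markov import StrategyOutcome

#: reported lifetime discounted (cost CNY, QALY) per window
REFERENCE_TOTALS: dict[str, tuple[float, float]] = {
    "61-120": (158616.0, 4.81),
    "121-180": (150357.0, 4.19),
    "181-240": (140133.0, 3.57),
    "241-300": (137671.0, 3.42),
    "301-360": (128225.0, 2.95),
    "361-420": (120285.0, 2.45),
}

#: reported willingness-to-pay threshold (CNY per QALY; 1x 2019 GDP per capita)
REFERENCE_WTP: float = 71000.0


def reference_outcomes() -> list[StrategyOutcome]:
    """The reported totals wrapped as StrategyOutcome objects (window order
    61-120 ... 361-420)."""
    out = []
    for w in standard_windows():
        cost, qaly = REFERENCE_TOTALS[w.label]
        out.append(StrategyOutcome(window=w, total_cost=cost, total_qaly=qaly))
    return out
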