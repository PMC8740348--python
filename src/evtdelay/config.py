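"""Model parameters: domain types, validation, file I/O, and PSA distribution fitting.

The model compares six onset-to-puncture time windows for endovascular
therapy (EVT) in acute ischemic stroke.  Every uncertain input is stored as
an :class:`Interval` — a base-case value plus the lower/upper bounds used in
deterministic sensitivity analysis and, via :func:`ci_to_distribution`, in
probabilistic sensitivity analysis.  All monetary values are 2019 CNY.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, field_validator, model_validator

#: canonical labels of the six onset-to-treatment windows (minutes from onset)
WINDOW_LABELS: tuple[str, ...] = (
    "61-120", "121-180", "181-240", "241-300", "301-360", "361-420",
)

#: EVT eligibility by window, as tabulated for the five earliest windows; the
#: last window extends the 3%-per-30-min decay rule one step (see
#: :func:`eligibility_from_rule`).
ELIGIBILITY_BY_WINDOW: dict[str, float] = {
    "61-120": 1.00,
    "121-180": 0.94,
    "181-240": 0.88,
    "241-300": 0.82,
    "301-360": 0.76,
    "361-420": 0.70,
}

#: sensitivity ranges for eligibility; the 361-420 range extrapolates the
#: +/-0.10 pattern of the published ranges (clipped to [0, 1]).
ELIGIBILITY_RANGES: dict[str, tuple[float, float]] = {
    "61-120": (0.90, 1.00),
    "121-180": (0.84, 1.00),
    "181-240": (0.78, 0.98),
    "241-300": (0.72, 0.92),
    "301-360": (0.66, 0.86),
    "361-420": (0.60, 0.80),
}


class Interval(BaseModel):
    """A base-case value with a (lower, upper) sensitivity range."""

    base: float
    lower: float
    upper: float

    @model_validator(mode="after")
    def _ordered(self) -> "Interval":
        if self.lower > self.upper:
            raise ValueError(f"lower ({self.lower}) > upper ({self.upper})")
        return self

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def brackets_base(self) -> bool:
        return self.lower <= self.base <= self.upper

    @classmethod
    def fixed(cls, value: float) -> "Interval":
        return cls(base=value, lower=value, upper=value)


class MRSDistribution(BaseModel):
    """Probability vector over modified Rankin Scale scores 0..6.

    mRS 0 is no symptoms, mRS 6 is death; this 7-vector is the model's
    health-state currency at 90 days post stroke.
    """

    p: list[float]

    @field_validator("p")
    @classmethod
    def _simplex(cls, v: list[float]) -> list[float]:
        if len(v) != 7:
            raise ValueError(f"mRS distribution needs 7 entries, got {len(v)}")
        if any(x < 0 or x > 1 for x in v):
            raise ValueError("mRS probabilities must lie in [0, 1]")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"mRS probabilities sum to {sum(v)!r}, not 1")
        return [float(x) for x in v]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)

    def cumulative(self) -> np.ndarray:
        """Cumulative mass P(mRS <= k) for k = 0..6."""
        return np.cumsum(self.p)

    def mean_mrs(self) -> float:
        return float(np.dot(self.p, np.arange(7)))


class TimeWindow(BaseModel):
    """One onset-to-puncture window with its EVT eligibility."""

    label: str
    start_min: float
    end_min: float
    evt_eligibility: Interval

    @model_validator(mode="after")
    def _valid(self) -> "TimeWindow":
        if not (0 < self.start_min < self.end_min):
            raise ValueError(f"window {self.label}: need 0 < start < end")
        if not (0 <= self.evt_eligibility.base <= 1):
            raise ValueError(f"window {self.label}: eligibility outside [0, 1]")
        return self

    @property
    def midpoint_min(self) -> float:
        return (self.start_min + self.end_min) / 2.0


class CostInputs(BaseModel):
    """Healthcare costs (2019 CNY) by 90-day mRS band and treatment add-ons.

    Acute costs cover the index hospitalization / first 90 days; long-term
    costs are annual.  ``addon_evt`` / ``addon_ivt`` are per-procedure
    additions; ``recurrent_stroke`` is charged per recurrent event.
    """

    acute_mrs_0_2: Interval
    acute_mrs_3_5: Interval
    acute_mrs_6: Interval
    longterm_mrs_0_2: Interval
    longterm_mrs_3_5: Interval
    addon_evt: Interval
    addon_ivt: Interval
    recurrent_stroke: Interval

    @model_validator(mode="after")
    def _nonneg(self) -> "CostInputs":
        for name, iv in self.items():
            if iv.lower < 0 or iv.base < 0:
                raise ValueError(f"cost {name} must be >= 0")
            if not iv.brackets_base():
                raise ValueError(f"cost {name}: base outside [lower, upper]")
        return self

    def items(self) -> list[tuple[str, Interval]]:
        return [(k, getattr(self, k)) for k in type(self).model_fields]


class UtilityInputs(BaseModel):
    """Utility weight per living mRS state 0..5; mRS 6 (death) is fixed at 0."""

    u: list[Interval]

    @field_validator("u")
    @classmethod
    def _valid(cls, v: list[Interval]) -> list[Interval]:
        if len(v) != 6:
            raise ValueError("need 6 utility intervals (mRS 0..5)")
        for i, iv in enumerate(v):
            if not (0 <= iv.base <= 1):
                raise ValueError(f"utility mRS {i} outside [0, 1]")
            if not iv.brackets_base():
                raise ValueError(f"utility mRS {i}: base outside range")
        bases = [iv.base for iv in v]
        if any(bases[i] < bases[i + 1] - 1e-12 for i in range(5)):
            raise ValueError("utilities must be non-increasing in mRS")
        return v

    def base_array(self) -> np.ndarray:
        return np.array([iv.base for iv in self.u], dtype=float)


class MortalityInputs(BaseModel):
    """Background life-table death probabilities and mRS-specific excess-mortality
    hazard ratios relative to the age-matched general population."""

    life_table: dict[int, float]
    hr_by_mrs: list[Interval]

    @model_validator(mode="after")
    def _valid(self) -> "MortalityInputs":
        for age, q in self.life_table.items():
            if not (0 <= q <= 1):
                raise ValueError(f"life table q({age}) = {q} outside [0, 1]")
        if len(self.hr_by_mrs) != 6:
            raise ValueError("need 6 hazard ratios (mRS 0..5)")
        bases = [iv.base for iv in self.hr_by_mrs]
        if any(b < 1 for b in bases):
            raise ValueError("hazard ratios must be >= 1")
        if any(bases[i] > bases[i + 1] + 1e-12 for i in range(5)):
            raise ValueError("hazard ratios must be non-decreasing in mRS")
        # published ranges for some states do not bracket the base value;
        # keep them verbatim and only warn.
        for i, iv in enumerate(self.hr_by_mrs):
            if not iv.brackets_base():
                warnings.warn(
                    f"hazard-ratio range for mRS {i} ({iv.lower}-{iv.upper}) "
                    f"does not bracket the base value {iv.base}; stored as given",
                    stacklevel=2,
                )
        return self

    def hr_base_array(self) -> np.ndarray:
        return np.array([iv.base for iv in self.hr_by_mrs], dtype=float)


class RecurrenceSchedule(BaseModel):
    """Annual recurrent-stroke probability by years since the index stroke.

    Years beyond the last tabulated year reuse the last tabulated rate.
    """

    rate_by_year: dict[int, float]

    @model_validator(mode="after")
    def _valid(self) -> "RecurrenceSchedule":
        if not self.rate_by_year:
            raise ValueError("recurrence schedule is empty")
        for y, r in self.rate_by_year.items():
            if y < 1:
                raise ValueError("years since index stroke start at 1")
            if not (0 <= r <= 1):
                raise ValueError(f"recurrence rate year {y} outside [0, 1]")
        return self

    def rate(self, year_since_index: int) -> float:
        if year_since_index in self.rate_by_year:
            return self.rate_by_year[year_since_index]
        return self.rate_by_year[max(self.rate_by_year)]


class IVTShares(BaseModel):
    """Share of patients co-treated with intravenous thrombolysis per arm
    (cost adjustment only; no separate clinical effect is modelled)."""

    share_evt_arm: Interval
    share_nonevt_arm: Interval

    @model_validator(mode="after")
    def _valid(self) -> "IVTShares":
        for name in ("share_evt_arm", "share_nonevt_arm"):
            iv = getattr(self, name)
            if not (0 <= iv.lower and iv.upper <= 1):
                raise ValueError(f"{name} outside [0, 1]")
        return self


class ModelConfig(BaseModel):
    """Complete parameter set for the delay cost-effectiveness model."""

    windows: list[TimeWindow]
    evt_mrs_dist: dict[str, MRSDistribution]
    nonevt_mrs_dist: MRSDistribution
    recur_mrs_dist: MRSDistribution
    costs: CostInputs
    utilities: UtilityInputs
    mortality: MortalityInputs
    recurrence: RecurrenceSchedule
    ivt: IVTShares
    start_age: int = 66
    discount_rate: float = 0.03
    wtp: float = 71000.0
    horizon_age_cap: int = 100
    psa_iterations: int = 10000
    psa_seed: int = 20240101
    dirichlet_effective_n: float = 500.0
    half_cycle_correction: bool = False
    recurrence_redistribution: Literal["truncated", "untruncated"] = "truncated"

    @model_validator(mode="after")
    def _valid(self) -> "ModelConfig":
        labels = [w.label for w in self.windows]
        missing = [lb for lb in WINDOW_LABELS if lb not in labels]
        if missing:
            raise ValueError(f"missing time window(s): {', '.join(missing)}")
        if len(labels) != 6:
            raise ValueError(f"exactly six windows required, got {len(labels)}")
        for lb in WINDOW_LABELS:
            if lb not in self.evt_mrs_dist:
                raise ValueError(f"missing EVT mRS distribution for window {lb}")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")
        if not self.start_age < self.horizon_age_cap:
            raise ValueError("start_age must be below horizon_age_cap")
        for age in range(self.start_age, self.horizon_age_cap):
            if age not in self.mortality.life_table:
                raise ValueError(
                    f"life table does not cover age {age}; extend it or lower "
                    f"horizon_age_cap"
                )
        return self

    def window(self, label: str) -> TimeWindow:
        for w in self.windows:
            if w.label == label:
                return w
        raise KeyError(f"no window labelled {label!r}")


def eligibility_from_rule(midpoint_min: float) -> float:
    """EVT eligibility at a window midpoint under the stepped decay rule.

    Eligibility is 100% for presentation within 2 h of onset and falls by
    3 percentage points per 30-min step thereafter; steps are counted from
    the first window's midpoint (90 min), which reproduces the tabulated
    window values 1.00, 0.94, 0.88, 0.82, 0.76 and extends to 0.70 for the
    361-420 min window.  Floored at 0.
    """
    if midpoint_min <= 0:
        raise ValueError("midpoint_min must be positive")
    if midpoint_min <= 120:
        return 1.0
    steps = math.ceil((midpoint_min - 90.0) / 30.0)
    return max(0.0, 1.0 - 0.03 * steps)


def standard_windows() -> list[TimeWindow]:
    """The six canonical windows with eligibility bases and sensitivity ranges."""
    out = []
    for lb in WINDOW_LABELS:
        start, end = (float(x) for x in lb.split("-"))
        lo, hi = ELIGIBILITY_RANGES[lb]
        out.append(
            TimeWindow(
                label=lb,
                start_min=start,
                end_min=end,
                evt_eligibility=Interval(
                    base=ELIGIBILITY_BY_WINDOW[lb], lower=lo, upper=hi
                ),
            )
        )
    return out


class DistributionSpec(BaseModel):
    """A fitted sampling distribution for one uncertain parameter."""

    family: Literal["gamma", "lognormal", "beta", "dirichlet", "fixed"]
    params: dict[str, float]

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            return self.params["value"]
        if self.family == "gamma":
            return float(rng.gamma(self.params["shape"], self.params["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(self.params["mu"], self.params["sigma"]))
        if self.family == "beta":
            return float(rng.beta(self.params["alpha"], self.params["beta"]))
        raise ValueError(f"cannot draw a scalar from family {self.family!r}")

    def mean(self) -> float:
        if self.family == "fixed":
            return self.params["value"]
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "lognormal":
            return math.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2)
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        raise ValueError(f"no scalar mean for family {self.family!r}")


def ci_to_distribution(
    base: float, lower: float, upper: float, family: str
) -> DistributionSpec:
    """Fit a PSA sampling distribution to a base value and 95% interval.

    Method of moments: the fitted distribution has mean ``base`` and standard
    deviation ``(upper - lower) / 3.92`` (the normal-theory SE implied by a
    95% CI).  Degenerate intervals give a fixed spec.  A beta fit with mean
    exactly 0 or 1 is impossible; such boundary means are treated as fixed.
    """
    if family not in ("gamma", "lognormal", "beta"):
        raise ValueError(f"unsupported family {family!r}")
    if lower > upper:
        raise ValueError("lower > upper")
    if upper == lower:
        return DistributionSpec(family="fixed", params={"value": base})
    sd = (upper - lower) / 3.92
    var = sd * sd
    if family == "gamma":
        if base <= 0:
            raise ValueError("gamma requires a positive mean")
        return DistributionSpec(
            family="gamma",
            params={"shape": base * base / var, "scale": var / base},
        )
    if family == "lognormal":
        if base <= 0:
            raise ValueError("lognormal requires a positive mean")
        sigma2 = math.log1p(var / (base * base))
        return DistributionSpec(
            family="lognormal",
            params={"mu": math.log(base) - sigma2 / 2, "sigma": math.sqrt(sigma2)},
        )
    # beta
    if base in (0.0, 1.0):
        return DistributionSpec(family="fixed", params={"value": base})
    if not (0 < base < 1):
        raise ValueError("beta requires a mean in (0, 1)")
    if var >= base * (1 - base):
        raise ValueError(
            f"beta moments infeasible: variance {var:.4g} >= mean(1-mean) "
            f"{base * (1 - base):.4g}"
        )
    nu = base * (1 - base) / var - 1
    return DistributionSpec(
        family="beta", params={"alpha": base * nu, "beta": (1 - base) * nu}
    )


def load_config(source: str | Path) -> ModelConfig:
    """Load and validate a ModelConfig from a YAML parameter file."""
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("parameter file must hold a mapping at top level")
    return ModelConfig.model_validate(data)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Serialize a ModelConfig to YAML (full float precision; round-trips)."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False, allow_unicode=True)
    )
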