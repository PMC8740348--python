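# Methods

## The model

`evtdelay` implements a two-stage health-economic model of treatment delay
in endovascular therapy (EVT) for acute ischemic stroke, from the Chinese
healthcare-payer perspective with all costs in 2019 CNY.

**Acute decision tree.** A cohort of stroke patients aged 66 presents in
one of six onset-to-puncture windows (61–120 through 361–420 minutes).
Within a window, a fraction *e* — the window's EVT eligibility — receives
EVT and the rest receive non-EVT care. Eligibility is 100% within 2 h of
onset and falls 3 percentage points per 30-minute step; steps are counted
from the first window's midpoint (90 min), the only reading that reproduces
the tabulated window values 1.00, 0.94, 0.88, 0.82, 0.76 and extends to
0.70 for 361–420 min. The 90-day outcome of the mixed cohort is the convex
combination `e·p_EVT + (1−e)·p_nonEVT` of the arms' modified Rankin Scale
(mRS 0–6) distributions. Expected acute cost sums the 90-day cost of the
patient's mRS band {0–2, 3–5, 6} plus the EVT add-on for the eligible
fraction and the IVT add-on weighted by each arm's share of thrombolysis
co-treatment. IVT enters as a cost adjustment only; its clinical effect is
already embedded in the trial-derived outcome distributions. No utility is
accrued during the first 90 days; the lifetime clock starts at the 90-day
state, and 90-day deaths (mRS 6) incur the mRS 6 acute cost and enter the
absorbing dead state.

**Markov cohort.** From the 90-day state the cohort advances in 1-year
cycles over states {mRS 0–5, dead} until age 100 (configurable cap standing
in for a "lifetime" horizon). Within a cycle, in order:

1. *Death.* The age-specific life-table probability *q* is converted to a
   hazard, scaled by the state's excess-mortality hazard ratio, and
   converted back: `1 − (1−q)^HR`.
2. *Recurrent stroke* among survivors, at the years-since-index rate.
   Recurrence redistributes over the recurrent-stroke 90-day mRS
   distribution **truncated so disability cannot improve** (renormalized;
   mass on mRS 6 joins the dead). The untruncated variant is available via
   `recurrence_redistribution="untruncated"`. A recurrent event does not
   reset the years-since-index clock.
3. Everyone else remains in state.

Utilities (QALY weights per mRS state) and annual long-term costs accrue on
cycle **survivors**; those dying within the cycle accrue nothing that cycle.
A half-cycle correction switch (`half_cycle_correction`, default off) gives
within-cycle deaths half a year instead. The recurrence cost is added on
top of (not substituted for) that cycle's annual cost. Cycle *c* (= 1, 2,
…) is discounted by `(1+r)^−(c−1)` with r = 3%/year for both QALYs and
costs, i.e. the first cycle is undiscounted.

**Comparison layer.** Strategies are the six windows. Sorting by ascending
cost, strictly dominated strategies (no more QALYs at no less cost) are
removed, then extended dominance removes strategies whose sequential ICER
exceeds that of the next more effective strategy, iterating until the
sequential ICERs strictly increase. ICER = ΔCost/ΔQALY; INMB =
ΔQALY·WTP − ΔCost at a willingness-to-pay of ¥71,000/QALY (1× 2019 GDP per
capita). Delay-loss metrics are the magnitude of the OLS slope of the
lifetime outcome against the window midpoint; this is the definition that
reproduces the reported 0.0075 QALY/min, where the endpoint difference
(0.0079) and the mean of adjacent slopes do not (`endpoint` and
`pairwise_mean` remain available). Healthy days convert QALYs at 365.25
days/year, consistent to within ~1% with the reported 165.02 days/hour.
The reported NMB loss of ¥15,105/hour (¥252/min) is *not* recoverable from
the reported totals under any of the three slope definitions (all give
≈¥405/min, ≈¥24,300/hour); the package computes the documented definition
and treats the reported NMB-loss figures as unreproducible.

## Sensitivity analysis

**One-way DSA** sweeps exactly the 28 parameters carrying published ranges
— six window eligibilities, two IVT shares, six hazard ratios, six
utilities, eight costs — setting each to its lower then upper bound with
everything else at base, and records the 61–120 vs 301–360 min ICER.
Entries where a setting equalizes the pair's QALYs are flagged undefined,
not dropped. The mRS distributions, whose published uncertainty is "by
sample size" without ranges, are excluded from the DSA and handled in the
PSA.

**PSA.** Each iteration independently redraws every uncertain scalar —
costs from gamma, hazard ratios from log-normal, probabilities and
utilities from beta — and each mRS distribution from a Dirichlet with
concentration `dirichlet_effective_n × base probabilities` (default
effective n = 500, roughly a mid-sized trial arm), which keeps draws on the
simplex. Distributions are fitted by method of moments with mean = base and
SD = (upper − lower)/3.92, the normal-theory SE of a 95% CI; this is
standard CEA practice when the original parameterization is unreported.
Two special cases: a beta fit with mean exactly 0 or 1 is impossible, so
boundary means (the 61–120 min eligibility of 1.0) stay fixed; and where a
published hazard-ratio range does not bracket its base value (mRS 2 and 3),
the range is stored verbatim — validation warns rather than errors — and
the fitted log-normal still centres on the base. The recurrence schedule
and life table carry no interval (the published 0.044–0.082 is an envelope
of time-dependent values, not a CI) and stay fixed in the PSA. The CEAC
reports, per WTP on a 0–250,000 CNY grid (step 5,000, plus the 71,000 and
213,000 thresholds), the probability each strategy maximizes NMB, with
exact ties split equally.

## Synthetic stand-in inputs

Three inputs of the original analysis are not published: the 90-day mRS
distributions of the EVT (per window) and EVT-ineligible arms, the Chinese
life table, and the year-specific recurrence rates. `evtdelay.synthetic`
generates structural stand-ins:

- **mRS distributions** come from a proportional-odds construction: one set
  of six cutpoints (offsets shaped after typical 90-day EVT-arm outcome
  patterns, anchored so the 61–120 min arm has P(mRS 0–2) = 0.46) shifted
  by a latent severity that grows 0.20 log-odds per hour of delay, with the
  non-EVT and recurrent-stroke arms shifted 1.2 and 1.3 log-odds. Because
  all distributions share cutpoints, a larger shift is worse at *every*
  cutoff — first-order stochastic dominance holds by construction, which is
  the property the analysis' qualitative results rely on.
- **Life table**: Gompertz, `q(a) = 1 − exp(−b·e^{c·a})` with b = 2.5e-5,
  c = 0.095/year (q(66) ≈ 0.013 rising to q(100) ≈ 0.28), strictly
  increasing in age.
- **Recurrence**: 0.082 in year 1 declining linearly to 0.044 by year 10
  and constant thereafter, inside the published 0.044–0.082 envelope.

The generator parameters were chosen once so that base-case lifetime QALYs
land in the plausible 2–5 range of the original frontier; they are knobs of
a *structural* stand-in, not estimates. Consequently the fixture
reproduces the qualitative findings — QALYs strictly decreasing with
delay, the earliest window most cost-effective at ¥71,000/QALY, a positive
QALY loss per hour — but its absolute costs, QALYs, tornado endpoints and
CEAC percentages are not expected to match the published ones, and passing
tests on the fixture say nothing numeric about the real HERMES-based
inputs. Users holding the real distributions drop them into the same YAML
schema (`save_config`/`load_config` round-trip losslessly).

The published comparison layer *is* desk-reproducible: the reported
six-window cost/QALY totals are bundled as reference inputs, and the
frontier, ICER, INMB and slope machinery applied to them reproduces the
reported extended-dominance pattern, ¥15,712 and ¥16,409 ICERs (within
1–2%, the residue of the totals being printed rounded), ¥101,106 INMB
(within 1%), and the 0.0075 QALY/min / 0.45 QALY/hour / 165.02 days/hour
delay losses (within 1.5%).

## Numerical choices and degenerate inputs

- Probability vectors must sum to 1 within 1e-9; cohort mass conservation
  is asserted every cycle at the same tolerance, and the dead state must be
  non-decreasing.
- Cost ties in frontier sorting break by descending QALY; exact (cost,
  QALY) duplicates keep the first occurrence on the frontier.
- A truncated recurrence row with no remaining mass (possible only with
  hand-edited distributions) degenerates to staying in state.
- `q = 1` in the life table yields death probability 1 for every hazard
  ratio; ages beyond the table raise an error pointing at the horizon cap.
- One suspicious published pair is shipped verbatim: the "additional cost
  of IVT" (¥68,436) exceeds the "additional cost of EVT" (¥12,579), the
  reverse of what the surrounding discussion of EVT's cost implies; both
  are plain config fields, so users who conclude the labels are swapped can
  swap the values. The 361–420 min eligibility range (0.60–0.80)
  extrapolates the ±0.10 pattern of the published ranges, as no range is
  published for that window.

## Problem sizes

The default horizon is 34 annual cycles (ages 66–99). The bundled analysis
drivers and the acceptance script run the PSA at 2,000 iterations
(Monte-Carlo SE on an acceptability probability ≤ 0.011), the package's
standard interactive size; `psa_iterations = 10,000` remains the config
default for final runs via the CLI.

## Known limitations

- Cohort expectation only; no patient-level microsimulation, tunnel
  states, or age/sex-stratified utilities.
- Long-term annual costs are time-invariant apart from the recurrence
  schedule; first-years-after-stroke cost elevation is not modelled.
- PSA draws are mutually independent; no correlation structure between
  parameters.
- Indirect/productivity costs are out of scope, as in the source analysis.
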