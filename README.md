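# evtdelay

A cost-effectiveness model of treatment delay in endovascular therapy
(EVT) for acute ischemic stroke, from the Chinese healthcare perspective.

Mechanical thrombectomy improves stroke outcomes, but its benefit decays
with every minute between symptom onset and groin puncture. This package
quantifies what that delay costs — in quality-adjusted life-years (QALYs),
healthy days, and money — by comparing six onset-to-treatment windows
(61–120 up to 361–420 minutes) for a cohort of Chinese stroke patients
aged 66. It is aimed at health economists and stroke-care policy analysts
who want a transparent, fully scriptable re-implementation of the published
TreeAge-style analysis.

## The model in brief

1. **Acute decision tree.** In window *w*, a fraction `e_w` of patients is
   eligible for EVT (1.00 within 2 h, −3 percentage points per 30 min
   delay). The 90-day outcome over modified Rankin Scale states mRS 0–6 is
   the mixture `e_w·p_EVT(w) + (1−e_w)·p_nonEVT`, and acute cost adds
   band-specific 90-day costs plus EVT/IVT procedure add-ons.
2. **Markov cohort.** The 90-day cohort advances in 1-year cycles over
   {mRS 0–5, dead} to age 100. Annual death probability is
   `1 − (1−q_age)^HR_mRS`; survivors face a years-since-index recurrence
   rate that redistributes them over a (non-improving) recurrent-stroke mRS
   distribution. QALYs weight each surviving year by the state utility;
   both QALYs and costs (2019 CNY) are discounted at 3%/year.
3. **Comparison.** Strategies are ranked by cost; strict and extended
   dominance yield the efficiency frontier with sequential ICERs
   (ΔCost/ΔQALY) and INMB (ΔQALY·WTP − ΔCost) at WTP ¥71,000/QALY. The
   per-hour loss of delay is the OLS slope of lifetime outcome against
   window midpoint. Tornado (one-way) and probabilistic sensitivity
   analyses (gamma/log-normal/beta/Dirichlet draws, CEAC) assess
   robustness.

Three inputs of the original analysis are unpublished (trial 90-day mRS
distributions, the Chinese life table, year-specific recurrence rates);
`evtdelay.synthetic` generates structural stand-ins with the properties
the analysis relies on — later windows stochastically worse, mortality
increasing with age, recurrence inside the published 0.044–0.082 envelope.
See `docs/methods.md` for what the stand-ins do and do not establish.

## Worked example

```python
from evtdelay import (delay_loss, efficiency_frontier,
                      evaluate_all_strategies)
from evtdelay.synthetic import default_fixture

config = default_fixture()          # bundled base case
outcomes = evaluate_all_strategies(config)
for o in outcomes:
    print(f"{o.label:>8}: {o.total_cost:>10,.0f} CNY  {o.total_qaly:.2f} QALYs")

frontier = efficiency_frontier(outcomes, config.wtp)
print({e.outcome.label: e.dominance for e in frontier.entries})

loss = delay_loss(outcomes, config.wtp)
print(f"QALY loss per hour of delay: {loss.qaly_per_hour:.3f}")
```

prints

```
  61-120:    152,551 CNY  3.97 QALYs
 121-180:    148,554 CNY  3.57 QALYs
 181-240:    144,558 CNY  3.22 QALYs
 241-300:    140,622 CNY  2.90 QALYs
 301-360:    136,817 CNY  2.63 QALYs
 361-420:    133,223 CNY  2.39 QALYs
{'361-420': 'on_frontier', '301-360': 'extended_dominated',
 '241-300': 'extended_dominated', '181-240': 'extended_dominated',
 '121-180': 'extended_dominated', '61-120': 'on_frontier'}
QALY loss per hour of delay: 0.315
```

Treating earlier costs more up front (more patients get the expensive
procedure) but buys substantially more lifetime QALYs: under the bundled
inputs every hour of delay forfeits 0.32 QALYs, and the fastest window is
the cost-effective choice at ¥71,000/QALY.

The same pipeline is scripted in `analysis/01_build_inputs.py` through
`analysis/05_psa_ceac.py` (inputs → base case → published cross-check →
tornado → PSA/CEAC), each writing tables under `results/`, and exposed as a
CLI:

```bash
evtdelay base-case --fixture --out results/base_case
evtdelay dsa --fixture --out results/dsa --pair 61-120 301-360
evtdelay psa --fixture --out results/psa --psa-n 10000 --seed 1
```

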