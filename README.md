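# vfmchart

Decision support for **budget-constrained health technology prioritization**
based explicitly on value for money. Agencies such as a national basket
committee must choose, once a year and under a hard budget, which new
technologies (drugs, devices, procedures) to fund out of hundreds of
candidates. `vfmchart` implements a transparent framework for that choice
built on four variables per technology: incremental **benefits** to the
population, incremental **total cost** to the health system, **quality of
evidence**, and residual **"X-factors"** (strategic, legal or ethical
considerations outside the first three).

## The model

Benefits are multi-dimensional (lives saved, life prolongation,
quality-of-life gains, equity), so they are aggregated with an additive
**points system**: each dimension *d* has ordered levels with non-negative
point values *v<sub>d</sub>(ℓ)*, the bottom level worth 0, and a technology
rated at levels ℓ₁…ℓ<sub>D</sub> has total score

&nbsp;&nbsp;&nbsp;&nbsp;*S* = Σ<sub>d</sub> *v<sub>d</sub>(ℓ<sub>d</sub>)*.

Cost is deliberately **not** a dimension of the points system; each
technology is plotted at (cost, *S*) on the **value-for-money chart**, with
bubble area proportional to evidence quality and a highlight color for
X-factors. Technologies for which no alternative has both lower cost and
higher benefit form the **Pareto (efficiency) frontier** — the "best value"
candidates. Selection proceeds by funding easy winners, re-plotting the
abridged chart, and peeling successive frontiers until the budget is
exhausted; an exact 0-1 **knapsack** solver (dynamic programming over
integer-scaled costs) provides the benefit-maximizing benchmark, with
X-factor overrides expressed as lock-in/lock-out constraints.

Point values themselves are elicited from decision-makers by **pairwise
ranking** of hypothetical technologies defined on two dimensions at a time
(a PAPRIKA-style survey): every question is a genuine trade-off, answers
propagate through the transitive closure of the preference relation so
implied questions are never asked, and the completed ranking is converted to
a schedule by a linear program that maximizes the minimum margin by which
the elicited preferences hold, normalizing the top-level values to sum to 1.

## Worked example

The package bundles the illustrative five-dimension points schedule and a
table of 18 illustrative technologies assessed for Israel's health basket
(costs in millions of shekels per annum). Replaying one deliberation round:

```python
from vfmchart import *

ps = load_example_points_system()
techs = load_example_technologies(ps)
points = build_vfm_points(techs, ps)

state = new_selection(techs, budget=300.0)
state = select(state, ["t1", "t2", "t4", "t6"])   # the easy winners
print(format_millions(state.spent))               # -> 20.2

remaining = [p for p in points if p.tech_id in state.remaining]
print(pareto_frontier(remaining))
# -> ['t16', 't14', 't7', 't5', 't3']
```

The first four additions (smoking-cessation drugs, Taxotere, Elaprase,
left-ventricular assist devices) cost just 20.2 million; the committee then
faces a new frontier — contraceptives, Fuzeon, statins, Visudyne and
Herceptin — which costs 172.9 million to fund in full. Herceptin (t3)
scores only 0.024 points above Visudyne (t5) yet costs ≈ 98 million more
(`compare_costs("t3", "t5", techs)`), exactly the kind of trade-off the
chart makes visible.

The `examples/` directory has one short script per capability — scoring and
chart rendering, the deliberation loop, knapsack benchmarking with lock-ins,
a fully simulated elicitation session (111 of 247 pool questions asked, the
rest implied by transitivity), and what-if/shortlist tools. A thin CLI
mirrors the library:

```bash
vfm frontier                     # t16,t14,t2,t1
vfm knapsack --budget 50
vfm chart --out chart.svg
vfm elicit --out derived.yaml    # interactive survey
```

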