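"""Replay the worked deliberation round: pick the easy winners, peel the
frontier, and track the budget.

The committee first funds the four technologies that are obviously good
value (top benefits at low cost), then faces the new Pareto frontier of the
remaining candidates, and so on until the budget runs out.
"""

from vfmchart import (
    build_vfm_points,
    compare_costs,
    format_millions,
    load_example_points_system,
    load_example_technologies,
    new_selection,
    pareto_frontier,
    select,
)

ps = load_example_points_system()
techs = load_example_technologies(ps)
points = build_vfm_points(techs, ps)

state = new_selection(techs, budget=300.0)  # the 2010 round's budget
first = ["t1", "t2", "t4", "t6"]
state = select(state, first)
print(f"first additions {first} cost {format_millions(state.spent)} million")

d = compare_costs("t3", "t5", techs)
print(f"Herceptin (t3) is ~{format_millions(d, difference=True)} million "
      "dearer than Visudyne (t5), so it can wait")

remaining = [p for p in points if p.tech_id in state.remaining]
frontier = pareto_frontier(remaining)
print(f"new frontier: {frontier}")
state = select(state, frontier)
print(f"funding the whole frontier costs "
      f"{format_millions(sum(techs[i].total_cost for i in range(18) if techs[i].id in frontier))} "
      f"million; spent {format_millions(state.spent)} of "
      f"{format_millions(state.budget)}, "
      f"{format_millions(state.unallocated)} unallocated")
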