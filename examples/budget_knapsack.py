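"""Exact benefit-maximizing basket under a tight budget, with overrides.

The committee's trial-and-error selection can be benchmarked against the
exact 0-1 knapsack optimum.  X-factor overrides enter as lock-in (must
fund) or lock-out (must not fund) constraints — they never change scores.
"""

from vfmchart import (
    build_vfm_points,
    knapsack_optimal,
    load_example_points_system,
    load_example_technologies,
)

ps = load_example_points_system()
techs = load_example_technologies(ps)
points = build_vfm_points(techs, ps)
by_id = {p.tech_id: p for p in points}


def report(label, chosen):
    cost = sum(by_id[t].cost for t in chosen)
    benefit = sum(by_id[t].benefit for t in chosen)
    print(f"{label}: {sorted(chosen)}")
    print(f"   total benefit {benefit:.3f}, total cost {cost:.1f} million\n")


report("optimum under a 50-million budget", knapsack_optimal(points, 50.0))

# dental care (t10) was politically mandated regardless of its ranking
report(
    "same budget but dental care (t10) locked in",
    knapsack_optimal(points, 90.0, locked_in={"t10"}),
)
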