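"""Sensitivity ('what would it take?') and committee shortlist tallying.

For a technology that looks like being rejected, find the smallest set of
rating upgrades that would put it on the Pareto frontier — a systematic way
to probe how sensitive the decision is to contested ratings.  Separately,
tally 'top ten' nominations into majority and question-marked lists.
"""

from vfmchart import (
    CommitteeBallot,
    committee_shortlist,
    load_example_points_system,
    load_example_technologies,
    what_would_it_take,
)

ps = load_example_points_system()
techs = load_example_technologies(ps)

for tid in ("t16", "t9", "t12"):
    result = what_would_it_take(tid, techs, ps)
    if result.status == "on_frontier":
        print(f"{tid}: already on the frontier")
    elif result.status == "not_achievable":
        print(f"{tid}: dominated even at the best possible rating")
    else:
        ups = "; ".join(f"{d} -> {l}" for d, l in result.upgrades.items())
        print(f"{tid}: would reach the frontier if re-rated: {ups}")

ballots = [
    CommitteeBallot("chair", {"t1", "t2", "t4", "t6", "t16"}),
    CommitteeBallot("economist", {"t1", "t2", "t7", "t16"}),
    CommitteeBallot("ethicist", {"t1", "t4", "t10", "t16"}),
]
majority, marked = committee_shortlist(ballots, n_members=3, top_k=10)
print(f"\nmajority support: {majority}")
print(f"question-marked (some support): {marked}")
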