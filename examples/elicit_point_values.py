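"""Simulate a full pairwise-ranking session and recover the point values.

A respondent answering consistently from the bundled schedule is simulated;
the session asks only questions not already implied by transitivity, then a
max-min-slack linear program turns the complete ranking into a schedule.
The derived values rank every possible trade-off question exactly as the
hidden schedule does (ordinal recovery), even though the numbers differ.
"""

from vfmchart import (
    derive_point_values,
    load_example_points_system,
    pool_agreement,
    run_session,
    simulate_answers,
)

hidden = load_example_points_system()
state = run_session(hidden, simulate_answers(hidden))
print(f"pool of {state.pool_size} trade-off questions, "
      f"{len(state.answered)} actually asked "
      f"({state.pool_size - len(state.answered)} implied by transitivity)")

derived = derive_point_values(state)
print(f"\n{'dimension':<45}{'hidden top':>11}{'derived top':>12}")
for h, d in zip(hidden.dimensions, derived.dimensions):
    print(f"{h.name[:44]:<45}{h.top_value:>11.3f}{d.top_value:>12.3f}")

print(f"\nall pool pairs ranked identically: {pool_agreement(hidden, derived)}")
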