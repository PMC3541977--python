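"""Score the bundled 18-technology table and render the value-for-money chart.

Each technology's benefit total score is the sum of the point values of its
assigned levels; the chart plots benefit against annual cost with bubble
size showing evidence quality and color flagging X-factors.
"""

from vfmchart import (
    build_vfm_points,
    load_example_points_system,
    load_example_technologies,
    make_chart_spec,
    render_svg,
    total_score,
)

ps = load_example_points_system()
techs = load_example_technologies(ps)

print(f"{'id':<5}{'benefit':>8}{'cost (m)':>10}  evidence  x-factors")
for t in sorted(techs, key=lambda t: -total_score(t.rating, ps)):
    print(
        f"{t.id:<5}{total_score(t.rating, ps):>8.3f}{t.total_cost:>10.2f}"
        f"  {t.evidence:<8}  {'; '.join(t.x_factors) or '-'}"
    )

points = build_vfm_points(techs, ps)
svg = render_svg(make_chart_spec(points))
with open("vfm_chart.svg", "w", encoding="utf-8") as fh:
    fh.write(svg)
print("\nwrote vfm_chart.svg — the higher and further left a bubble, the")
print("better its value for money; the polyline is the Pareto frontier.")
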