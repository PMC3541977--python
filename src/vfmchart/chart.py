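"""Rendering of the value-for-money chart as structural SVG.

The chart is a bubble plot: benefit score on the vertical axis, total cost
(millions) on the horizontal, origin at (0, 0).  Bubble area is proportional
to the quality-of-evidence grade (poor : medium : high = 1 : 2 : 3), bubbles
with X-factors get a highlight fill, the Pareto frontier is drawn as a
polyline, and two guide lines split the plane into quadrants (good value for
money sits top-left).  The SVG is emitted directly so every element carries
a machine-countable class (``bubble``, ``frontier``, ``quadrant-guide``,
``bubble-label``) — the rendering contract is structural, not stylistic.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .portfolio import EVIDENCE_GRADES, VfMPoint, pareto_frontier

__all__ = ["ChartSpec", "make_chart_spec", "render_svg", "DEFAULT_STYLE"]

DEFAULT_STYLE: dict = {
    "width": 840,
    "height": 560,
    "margin": 70,
    # area of a poor-evidence bubble in px^2; medium and high are 2x and 3x
    "base_bubble_area": 110.0,
    "bubble_color": "#c8c8c8",
    "xfactor_color": "#5b9bd5",
    "xfactor_hatch": False,  # grayscale-safe hatch instead of color fill
    "frontier_color": "#333333",
    "guide_color": "#999999",
}


@dataclass(frozen=True)
class ChartSpec:
    """Everything needed to draw one chart, with the frontier precomputed."""

    points: tuple[VfMPoint, ...]
    frontier: tuple[str, ...]
    cost_threshold: float
    benefit_threshold: float
    title: str = "Value for Money Chart"
    style: Mapping = field(default_factory=dict)


def make_chart_spec(
    points: Sequence[VfMPoint],
    *,
    cost_threshold: Optional[float] = None,
    benefit_threshold: Optional[float] = None,
    title: str = "Value for Money Chart",
    style: Optional[Mapping] = None,
) -> ChartSpec:
    """Build a chart spec: frontier plus default quadrant thresholds.

    Quadrant guide lines default to the midrange of the plotted costs and
    benefits; pass explicit thresholds to override (a policy budget line,
    say).  Raises ``ValueError`` on an empty portfolio.
    """
    if not points:
        raise ValueError("cannot chart an empty portfolio")
    costs = [p.cost for p in points]
    benefits = [p.benefit for p in points]
    if cost_threshold is None:
        cost_threshold = (min(costs) + max(costs)) / 2.0
    if benefit_threshold is None:
        benefit_threshold = (min(benefits) + max(benefits)) / 2.0
    return ChartSpec(
        points=tuple(points),
        frontier=tuple(pareto_frontier(points)),
        cost_threshold=float(cost_threshold),
        benefit_threshold=float(benefit_threshold),
        title=title,
        style=dict(style or {}),
    )


def bubble_area(evidence: str, base_area: float) -> float:
    """Bubble area, strictly increasing in the evidence grade (1:2:3)."""
    return base_area * (EVIDENCE_GRADES.index(evidence) + 1)


def render_svg(spec: ChartSpec) -> str:
    """Serialize a chart spec to an SVG 1.1 document (returned as text).

    Structural contract: one ``circle.bubble`` per point (with class
    ``xfactor`` when flagged), one ``polyline.frontier`` whose vertex count
    equals the frontier size (a single frontier point degenerates to a
    one-vertex polyline), two ``line.quadrant-guide`` elements, axis labels
    "Benefits" and "Total Cost", and one ``text.bubble-label`` per bubble.
    """
    st = {**DEFAULT_STYLE, **spec.style}
    width, height, margin = st["width"], st["height"], st["margin"]
    plot_w, plot_h = width - 2 * margin, height - 2 * margin

    max_cost = max(max(p.cost for p in spec.points), spec.cost_threshold)
    max_benefit = max(max(p.benefit for p in spec.points), spec.benefit_threshold)
    max_cost = max_cost * 1.06 or 1.0
    max_benefit = max_benefit * 1.10 or 1.0

    def sx(cost: float) -> float:
        return margin + cost / max_cost * plot_w

    def sy(benefit: float) -> float:
        return height - margin - benefit / max_benefit * plot_h

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )
    ET.SubElement(
        svg,
        "text",
        {"x": str(width / 2), "y": "28", "class": "title", "text-anchor": "middle"},
    ).text = spec.title

    # axes through the origin
    axis = {"stroke": "#000", "stroke-width": "1.2", "class": "axis"}
    ET.SubElement(
        svg,
        "line",
        {**axis, "x1": str(sx(0)), "y1": str(sy(0)), "x2": str(sx(max_cost / 1.06)),
         "y2": str(sy(0))},
    )
    ET.SubElement(
        svg,
        "line",
        {**axis, "x1": str(sx(0)), "y1": str(sy(0)), "x2": str(sx(0)),
         "y2": str(sy(max_benefit / 1.10))},
    )
    ET.SubElement(
        svg,
        "text",
        {
            "x": str(width / 2),
            "y": str(height - 16),
            "class": "axis-label",
            "text-anchor": "middle",
        },
    ).text = "Total Cost"
    ET.SubElement(
        svg,
        "text",
        {
            "x": "22",
            "y": str(height / 2),
            "class": "axis-label",
            "text-anchor": "middle",
            "transform": f"rotate(-90 22 {height / 2})",
        },
    ).text = "Benefits"

    # quadrant guides
    guide = {
        "stroke": st["guide_color"],
        "stroke-dasharray": "6 4",
        "class": "quadrant-guide",
    }
    ET.SubElement(
        svg,
        "line",
        {**guide, "x1": str(sx(spec.cost_threshold)), "y1": str(sy(0)),
         "x2": str(sx(spec.cost_threshold)), "y2": str(margin)},
    )
    ET.SubElement(
        svg,
        "line",
        {**guide, "x1": str(sx(0)), "y1": str(sy(spec.benefit_threshold)),
         "x2": str(width - margin), "y2": str(sy(spec.benefit_threshold))},
    )

    # frontier polyline (vertices in cost order; may degenerate to one point)
    by_id = {p.tech_id: p for p in spec.points}
    vertices = " ".join(
        f"{sx(by_id[tid].cost):.2f},{sy(by_id[tid].benefit):.2f}"
        for tid in spec.frontier
    )
    ET.SubElement(
        svg,
        "polyline",
        {
            "points": vertices,
            "fill": "none",
            "stroke": st["frontier_color"],
            "stroke-width": "1.5",
            "class": "frontier",
        },
    )

    if st["xfactor_hatch"]:
        defs = ET.SubElement(svg, "defs")
        pat = ET.SubElement(
            defs,
            "pattern",
            {"id": "xhatch", "width": "6", "height": "6",
             "patternUnits": "userSpaceOnUse", "patternTransform": "rotate(45)"},
        )
        ET.SubElement(
            pat, "line",
            {"x1": "0", "y1": "0", "x2": "0", "y2": "6",
             "stroke": "#444", "stroke-width": "2"},
        )

    for p in spec.points:
        r = math.sqrt(bubble_area(p.evidence, st["base_bubble_area"]) / math.pi)
        if p.x_flag:
            fill = "url(#xhatch)" if st["xfactor_hatch"] else st["xfactor_color"]
            cls = "bubble xfactor"
        else:
            fill = st["bubble_color"]
            cls = "bubble"
        ET.SubElement(
            svg,
            "circle",
            {
                "cx": f"{sx(p.cost):.2f}",
                "cy": f"{sy(p.benefit):.2f}",
                "r": f"{r:.2f}",
                "fill": fill,
                "fill-opacity": "0.85",
                "stroke": "#555",
                "class": cls,
                "data-tech-id": p.tech_id,
                "data-evidence": p.evidence,
            },
        )
        ET.SubElement(
            svg,
            "text",
            {
                "x": f"{sx(p.cost) + r + 2:.2f}",
                "y": f"{sy(p.benefit) - 2:.2f}",
                "class": "bubble-label",
                "font-size": "11",
            },
        ).text = p.tech_id

    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        svg, encoding="unicode"
    )
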