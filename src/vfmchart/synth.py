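"""Synthetic portfolios and points systems for testing and simulation.

The generator emulates the shape of a basket-committee submission round:
a few dozen candidate technologies with log-normally distributed annual
costs (most cost a few million, a few are very expensive — matching the
3–124 million spread of the worked example), categorical benefit ratings,
mostly-high evidence grades, and occasional X-factors.  It makes no attempt
to model correlations between benefit and cost, which real submissions
plausibly have.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .points import Dimension, Level, PointsSystem, Rating
from .portfolio import EVIDENCE_GRADES, Technology

__all__ = ["SyntheticSpec", "generate_synthetic", "random_points_system"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic portfolio generator.

    Costs are drawn log-normally: ``exp(N(cost_log_mean, cost_log_sd))``
    millions, rounded to two decimals.  ``rating_weights`` optionally gives
    per-dimension categorical weights over levels (default uniform);
    ``evidence_weights`` is (poor, medium, high); ``x_factor_prob`` is the
    chance a technology carries an X-factor note.
    """

    n_technologies: int = 18
    cost_log_mean: float = 3.0
    cost_log_sd: float = 1.0
    rating_weights: Optional[dict[str, Sequence[float]]] = None
    evidence_weights: tuple[float, float, float] = (0.10, 0.25, 0.65)
    x_factor_prob: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_technologies < 1:
            raise ValueError("n_technologies must be >= 1")
        if self.cost_log_sd < 0:
            raise ValueError("cost_log_sd must be >= 0")
        if not 0 <= self.x_factor_prob <= 1:
            raise ValueError("x_factor_prob must be a probability")
        if abs(sum(self.evidence_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.evidence_weights
        ):
            raise ValueError("evidence_weights must be a probability vector")
        if self.rating_weights:
            for name, w in self.rating_weights.items():
                if abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
                    raise ValueError(
                        f"rating weights for {name!r} must be a probability vector"
                    )


def random_points_system(
    rng: np.random.Generator,
    n_dimensions: int = 4,
    levels_range: tuple[int, int] = (2, 5),
) -> PointsSystem:
    """A random valid points system on a 1e-4 value grid.

    Level values are strictly increasing within each dimension (cumulative
    sums of positive integer increments scaled by 1e-4), so a simulated
    respondent answering from it is exact and transitive.
    """
    dims = []
    for i in range(n_dimensions):
        m = int(rng.integers(levels_range[0], levels_range[1] + 1))
        increments = rng.integers(1, 2500, size=m - 1)
        values = [0] + list(np.cumsum(increments))
        dims.append(
            Dimension(
                name=f"dim{i + 1}",
                levels=tuple(
                    Level(label=f"level{l}", point_value=float(v) / 1e4)
                    for l, v in enumerate(values)
                ),
            )
        )
    return PointsSystem(dimensions=tuple(dims), name="synthetic points system")


def generate_synthetic(
    spec: SyntheticSpec, ps: Optional[PointsSystem] = None
) -> tuple[PointsSystem, list[Technology]]:
    """Generate a reproducible random portfolio under a points system.

    If no points system is given, a random one is generated from the same
    seed.  All ratings are valid against the returned system by construction
    and costs are strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    if ps is None:
        ps = random_points_system(rng)

    techs = []
    for k in range(spec.n_technologies):
        assignments = {}
        for dim in ps.dimensions:
            weights = None
            if spec.rating_weights and dim.name in spec.rating_weights:
                weights = np.asarray(spec.rating_weights[dim.name], dtype=float)
                if len(weights) != len(dim.levels):
                    raise ValueError(
                        f"rating weights for {dim.name!r} must have one entry "
                        f"per level"
                    )
            idx = int(rng.choice(len(dim.levels), p=weights))
            assignments[dim.name] = dim.levels[idx].label
        cost = round(
            float(np.exp(rng.normal(spec.cost_log_mean, spec.cost_log_sd))), 2
        )
        cost = max(cost, 0.01)
        evidence = str(
            rng.choice(EVIDENCE_GRADES, p=np.asarray(spec.evidence_weights))
        )
        x_factors = (
            ("synthetic strategic consideration",)
            if rng.random() < spec.x_factor_prob
            else ()
        )
        techs.append(
            Technology(
                id=f"s{k + 1}",
                name=f"Synthetic technology {k + 1}",
                rating=Rating(assignments),
                total_cost=cost,
                evidence=evidence,
                x_factors=x_factors,
            )
        )
    return ps, techs
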