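"""Additive points-system model for a technology's incremental benefits.

A *points system* is a schedule of ordered dimensions (benefit criteria such
as lives saved or quality-of-life gains), each with ordered achievement
levels carrying non-negative point values.  A technology is *rated* by
assigning it one level per dimension; its benefit *total score* is the sum of
the assigned levels' point values.  The bottom level of every dimension is
worth 0 points, so a technology offering no incremental benefit scores 0 and
the best conceivable rating scores :func:`max_score`.

Costs are deliberately **not** part of the points system: the framework keeps
a technology's total cost (in millions of currency, annual or NPV) as a
separate axis so that benefit/cost trade-offs stay explicit.  This module
only provides :func:`npv_cost` for collapsing a multi-period cash-flow series
to a single present-value cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Level",
    "Dimension",
    "PointsSystem",
    "Rating",
    "CashFlowSeries",
    "PointsModelError",
    "RatingMismatchError",
    "ParameterError",
    "normalize_label",
    "validate_points_system",
    "total_score",
    "max_score",
    "interpolate_mid_levels",
    "npv_cost",
    "points_system_to_dict",
    "points_system_from_dict",
]

#: Absolute tolerance for score comparisons.  Point values are printed to a
#: few decimals; anything below this is treated as a tie.
SCORE_ATOL = 1e-9


class PointsModelError(Exception):
    """Base class for points-model errors."""


class RatingMismatchError(PointsModelError):
    """A rating refers to a dimension or level the points system lacks."""


class ParameterError(PointsModelError):
    """A numeric parameter is outside its valid range."""


def normalize_label(label: str) -> str:
    """Normalize a label for matching: casefold and strip all whitespace.

    Hand-edited CSV cells routinely differ from the canonical schedule in
    capitalisation and spacing (``"None/very small"``, ``"> 500"`` vs
    ``">500"``); removing whitespace entirely and casefolding makes those
    equal without a lookup table.
    """
    return "".join(str(label).casefold().split())


@dataclass(frozen=True)
class Level:
    """One achievement level of a dimension: a label and its point value."""

    label: str
    point_value: float


@dataclass(frozen=True)
class Dimension:
    """An ordered benefit criterion, levels listed worst to best."""

    name: str
    levels: tuple[Level, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))

    @cached_property
    def _label_index(self) -> dict[str, int]:
        return {normalize_label(lv.label): i for i, lv in enumerate(self.levels)}

    def index_of(self, label: str) -> int:
        """Index of a level by (normalized) label.

        Raises :class:`RatingMismatchError` for unknown labels.
        """
        try:
            return self._label_index[normalize_label(label)]
        except KeyError:
            raise RatingMismatchError(
                f"dimension {self.name!r} has no level {label!r}"
            ) from None

    def value_of(self, label: str) -> float:
        return self.levels[self.index_of(label)].point_value

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    @property
    def top_value(self) -> float:
        return max(lv.point_value for lv in self.levels)


@dataclass(frozen=True)
class PointsSystem:
    """An ordered collection of dimensions plus free-form provenance."""

    dimensions: tuple[Dimension, ...]
    name: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions", tuple(self.dimensions))
        object.__setattr__(self, "metadata", dict(self.metadata))

    @cached_property
    def _dim_index(self) -> dict[str, Dimension]:
        return {normalize_label(d.name): d for d in self.dimensions}

    def dimension(self, name: str) -> Dimension:
        try:
            return self._dim_index[normalize_label(name)]
        except KeyError:
            raise RatingMismatchError(f"no dimension named {name!r}") from None

    @property
    def dimension_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dimensions)


@dataclass(frozen=True)
class Rating:
    """One level assignment per dimension of the governing points system."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))


@dataclass(frozen=True)
class CashFlowSeries:
    """Per-period net cash flows (millions) with an end-of-period discount rate."""

    flows: tuple[tuple[int, float], ...]
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "flows", tuple((int(t), float(a)) for t, a in self.flows)
        )


def validate_points_system(
    ps: PointsSystem, *, require_bottom_zero: bool = True
) -> list[str]:
    """Return a list of invariant violations (empty means valid).

    Checks, per dimension: at least two levels, unique level labels,
    non-negative point values, values non-decreasing from worst to best
    level, and (unless ``require_bottom_zero=False``, for foreign points
    systems that anchor elsewhere) a 0-point bottom level.  System-wide:
    at least two dimensions with unique names.
    """
    violations: list[str] = []
    if len(ps.dimensions) < 2:
        violations.append("points system must have at least 2 dimensions")
    seen: set[str] = set()
    for dim in ps.dimensions:
        key = normalize_label(dim.name)
        if key in seen:
            violations.append(f"duplicate dimension name {dim.name!r}")
        seen.add(key)
        if len(dim.levels) < 2:
            violations.append(f"dimension {dim.name!r} must have at least 2 levels")
        labels: set[str] = set()
        for lv in dim.levels:
            if not str(lv.label).strip():
                violations.append(f"dimension {dim.name!r} has an empty level label")
            lkey = normalize_label(lv.label)
            if lkey in labels:
                violations.append(
                    f"dimension {dim.name!r} has duplicate level label {lv.label!r}"
                )
            labels.add(lkey)
            if lv.point_value < 0:
                violations.append(
                    f"dimension {dim.name!r} level {lv.label!r} has negative "
                    f"point value {lv.point_value}"
                )
        for lo, hi in zip(dim.levels, dim.levels[1:]):
            if hi.point_value < lo.point_value - SCORE_ATOL:
                violations.append(
                    f"dimension {dim.name!r}: point values must be non-decreasing "
                    f"({lo.label!r}={lo.point_value} > {hi.label!r}={hi.point_value})"
                )
        if (
            require_bottom_zero
            and dim.levels
            and abs(dim.levels[0].point_value) > SCORE_ATOL
        ):
            violations.append(
                f"dimension {dim.name!r}: bottom level {dim.levels[0].label!r} "
                f"must be worth 0 points, got {dim.levels[0].point_value}"
            )
    return violations


def total_score(rating: Rating, ps: PointsSystem) -> float:
    """Sum of the point values of the rating's assigned levels.

    Requires exactly one assignment per dimension of ``ps``; unknown
    dimensions or level labels raise :class:`RatingMismatchError`.
    """
    assigned = {normalize_label(k): v for k, v in rating.assignments.items()}
    if len(assigned) != len(rating.assignments):
        raise RatingMismatchError("rating assigns the same dimension twice")
    known = {normalize_label(d.name) for d in ps.dimensions}
    extra = set(assigned) - known
    if extra:
        raise RatingMismatchError(f"rating names unknown dimension(s): {sorted(extra)}")
    score = 0.0
    for dim in ps.dimensions:
        key = normalize_label(dim.name)
        if key not in assigned:
            raise RatingMismatchError(f"rating is missing dimension {dim.name!r}")
        score += dim.value_of(assigned[key])
    return score


def max_score(ps: PointsSystem) -> float:
    """Upper bound of :func:`total_score`: the sum of each dimension's top value."""
    return sum(d.top_value for d in ps.dimensions)


def interpolate_mid_levels(ps: PointsSystem) -> PointsSystem:
    """Insert a mid level between every adjacent level pair of every dimension.

    Each inserted level carries the arithmetic mean of its flanking point
    values, easing the sensitivity of total scores to coarse ratings.
    Original levels (labels and values) are preserved, so any rating
    expressed in original levels scores identically under the result.
    """
    new_dims = []
    for dim in ps.dimensions:
        levels: list[Level] = []
        for lo, hi in zip(dim.levels, dim.levels[1:]):
            levels.append(lo)
            levels.append(
                Level(
                    label=f"mid({lo.label} | {hi.label})",
                    point_value=(lo.point_value + hi.point_value) / 2.0,
                )
            )
        levels.append(dim.levels[-1])
        new_dims.append(Dimension(name=dim.name, levels=tuple(levels)))
    return PointsSystem(
        dimensions=tuple(new_dims),
        name=ps.name,
        metadata={**ps.metadata, "mid_levels": "interpolated"},
    )


def npv_cost(series: CashFlowSeries) -> float:
    """Net present value of a cash-flow series, end-of-period discounting.

    ``sum(amount_t / (1 + r) ** t)``; with rate 0 this is the plain sum.
    """
    if series.discount_rate < 0:
        raise ParameterError(f"discount rate must be >= 0, got {series.discount_rate}")
    periods = [t for t, _ in series.flows]
    if any(t < 0 for t in periods):
        raise ParameterError("period indices must be >= 0")
    if any(b <= a for a, b in zip(periods, periods[1:])):
        raise ParameterError("period indices must be strictly increasing")
    r = series.discount_rate
    return sum(amount / (1.0 + r) ** t for t, amount in series.flows)


# ---------------------------------------------------------------------------
# plain-dict (de)serialization, shared by the YAML/JSON loaders and the
# elicitation session files


def points_system_to_dict(ps: PointsSystem) -> dict:
    return {
        "name": ps.name,
        "metadata": dict(ps.metadata),
        "dimensions": [
            {
                "name": d.name,
                "levels": [
                    {"label": lv.label, "points": lv.point_value} for lv in d.levels
                ],
            }
            for d in ps.dimensions
        ],
    }


def points_system_from_dict(data: Mapping) -> PointsSystem:
    dims = []
    for d in data.get("dimensions", []):
        levels = tuple(
            Level(label=str(lv["label"]), point_value=float(lv.get("points", 0.0)))
            for lv in d.get("levels", [])
        )
        dims.append(Dimension(name=str(d["name"]), levels=levels))
    return PointsSystem(
        dimensions=tuple(dims),
        name=str(data.get("name", "")),
        metadata=dict(data.get("metadata", {}) or {}),
    )
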