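"""File formats: points-system YAML/JSON, technology-table CSV, config.

The technology table is a UTF-8 CSV with columns ``id,name,indication,
n_patients,<one column per points-system dimension>,total_cost,evidence,
x_factors``.  Dimension columns are matched to points-system dimensions by
normalized name (case and whitespace insensitive).  An ``x_factors`` cell of
``none`` (or empty) means no X-factors; multiple notes are ``;``-separated.

Bundled fixtures reproduce the published worked example: an illustrative
five-dimension points schedule and the table of 18 illustrative technologies
assessed for Israel's health basket.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from .points import (
    PointsSystem,
    Rating,
    normalize_label,
    points_system_from_dict,
    points_system_to_dict,
    validate_points_system,
)
from .portfolio import EVIDENCE_GRADES, Technology

__all__ = [
    "FormatError",
    "load_points_system",
    "save_points_system",
    "load_portfolio",
    "write_portfolio",
    "load_example_points_system",
    "load_example_technologies",
    "example_points_path",
    "example_technologies_path",
    "DEFAULT_CONFIG",
    "load_config",
]

logger = logging.getLogger("vfmchart")


class FormatError(Exception):
    """A file failed to parse or validate; the message lists every problem."""


# ---------------------------------------------------------------------------
# points system


def load_points_system(
    path: Union[str, Path], *, require_bottom_zero: bool = True
) -> PointsSystem:
    """Read a points system from YAML or JSON (by extension) and validate it."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(data, dict) or "dimensions" not in data:
        raise FormatError(f"{path}: expected a mapping with a 'dimensions' list")
    try:
        ps = points_system_from_dict(data)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: malformed points system: {exc}") from exc
    violations = validate_points_system(ps, require_bottom_zero=require_bottom_zero)
    if violations:
        raise FormatError(
            f"{path}: invalid points system:\n  " + "\n  ".join(violations)
        )
    return ps


def save_points_system(ps: PointsSystem, path: Union[str, Path]) -> None:
    path = Path(path)
    data = points_system_to_dict(ps)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=1), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# technology table

_FIXED_COLUMNS = ("id", "name", "indication", "n_patients", "total_cost",
                  "evidence", "x_factors")


def _parse_x_factors(cell: object) -> tuple[str, ...]:
    text = "" if cell is None or (isinstance(cell, float) and pd.isna(cell)) else str(cell)
    if normalize_label(text) in ("", "none"):
        return ()
    return tuple(part.strip() for part in text.split(";") if part.strip())


def load_portfolio(
    path: Union[str, Path], ps: PointsSystem
) -> list[Technology]:
    """Read and validate a technology table against a points system.

    Every points-system dimension must map to exactly one CSV column; cell
    errors (unknown level label, negative cost, bad evidence grade) are
    collected and reported together with their row numbers.  An ``x_factors``
    cell that is literally "none" is a warning-free empty list; genuinely
    missing cells log a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"{path}: cannot read CSV: {exc}") from exc

    norm_cols = {normalize_label(c): c for c in df.columns}
    errors: list[str] = []
    dim_cols: dict[str, str] = {}
    for dim in ps.dimensions:
        key = normalize_label(dim.name)
        if key not in norm_cols:
            errors.append(f"missing column for dimension {dim.name!r}")
        else:
            dim_cols[dim.name] = norm_cols[key]
    for col in ("id", "total_cost"):
        if col not in norm_cols:
            errors.append(f"missing required column {col!r}")
    if errors:
        raise FormatError(f"{path}:\n  " + "\n  ".join(errors))

    if df.empty:
        logger.warning("%s: header-only file, empty portfolio", path)

    techs: list[Technology] = []
    seen_ids: set[str] = set()
    for row_no, row in enumerate(df.to_dict("records"), start=2):  # 1 = header
        rid = str(row.get(norm_cols.get("id", "id"), "")).strip()
        if not rid:
            errors.append(f"row {row_no}: empty id")
            continue
        if rid in seen_ids:
            errors.append(f"row {row_no}: duplicate id {rid!r}")
            continue
        seen_ids.add(rid)

        assignments = {}
        for dim in ps.dimensions:
            label = str(row[dim_cols[dim.name]]).strip()
            try:
                dim.index_of(label)
            except Exception:
                errors.append(
                    f"row {row_no} ({rid}): unknown level {label!r} for "
                    f"dimension {dim.name!r}"
                )
                continue
            assignments[dim.name] = label

        try:
            cost = float(str(row[norm_cols["total_cost"]]).strip())
        except ValueError:
            errors.append(f"row {row_no} ({rid}): total_cost is not a number")
            continue
        if cost < 0:
            errors.append(f"row {row_no} ({rid}): negative total_cost {cost}")
            continue

        evidence = str(row.get(norm_cols.get("evidence", ""), "medium")).strip() or "medium"
        if evidence not in EVIDENCE_GRADES:
            errors.append(
                f"row {row_no} ({rid}): evidence must be one of "
                f"{EVIDENCE_GRADES}, got {evidence!r}"
            )
            continue

        n_raw = str(row.get(norm_cols.get("n_patients", ""), "0")).strip()
        try:
            n_patients = int(n_raw.replace(",", "")) if n_raw else 0
        except ValueError:
            errors.append(f"row {row_no} ({rid}): n_patients is not an integer")
            continue

        if len(assignments) == len(ps.dimensions):
            techs.append(
                Technology(
                    id=rid,
                    name=str(row.get(norm_cols.get("name", ""), "")).strip(),
                    indication=str(row.get(norm_cols.get("indication", ""), "")).strip(),
                    n_patients=n_patients,
                    rating=Rating(assignments),
                    total_cost=cost,
                    evidence=evidence,
                    x_factors=_parse_x_factors(row.get(norm_cols.get("x_factors", ""), "")),
                )
            )
    if errors:
        raise FormatError(f"{path}:\n  " + "\n  ".join(errors))
    return techs


def write_portfolio(
    techs: Sequence[Technology], ps: PointsSystem, path: Union[str, Path]
) -> None:
    """Write a technology table, inverse of :func:`load_portfolio`."""
    rows = []
    for t in techs:
        norm_assign = {normalize_label(k): v for k, v in t.rating.assignments.items()}
        row = {
            "id": t.id,
            "name": t.name,
            "indication": t.indication,
            "n_patients": t.n_patients,
        }
        for dim in ps.dimensions:
            row[dim.name] = norm_assign[normalize_label(dim.name)]
        row["total_cost"] = t.total_cost
        row["evidence"] = t.evidence
        row["x_factors"] = "; ".join(t.x_factors) if t.x_factors else "none"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# bundled fixtures


def example_points_path() -> Path:
    return Path(str(resources.files("vfmchart.data") / "table1_points.yaml"))


def example_technologies_path() -> Path:
    return Path(str(resources.files("vfmchart.data") / "table2_technologies.csv"))


def load_example_points_system() -> PointsSystem:
    """The bundled illustrative points schedule (five benefit dimensions)."""
    return load_points_system(example_points_path())


def load_example_technologies(
    ps: Optional[PointsSystem] = None,
) -> list[Technology]:
    """The bundled 18 illustrative technologies."""
    if ps is None:
        ps = load_example_points_system()
    return load_portfolio(example_technologies_path(), ps)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "budget": 300.0,  # millions; configurable demo default
    "display": {"sum_decimals": 1, "large_difference_threshold": 50},
    "chart": {
        "cost_threshold": None,  # None -> midrange
        "benefit_threshold": None,
        "base_bubble_area": 110.0,
        "xfactor_hatch": False,
    },
}


def load_config(path: Optional[Union[str, Path]] = None) -> dict:
    """Merge a YAML config file over the defaults (shallow, per section)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    for key, value in data.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg
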