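"""Per-unit exposed-surface fraction from a CORINE-coded raster.

CORINE Land Cover assigns each cell one of 44 level-3 classes coded by
3-digit hierarchical numbers (1xx artificial, 2xx agricultural, 3xx
forest/semi-natural, 4xx wetlands, 5xx water).  The exposure indicator
is the fraction of a unit's pixels that are artificial or open with
little or no vegetation (level-2 group 33); water stays in the
denominator but not the numerator.  The grouping ships as a plain-text
config so alternative readings are one edit away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core import AdminUnitSet, IndicatorColumn, RasterGrid
from .errors import AlignmentError, SchemaError, UnknownClassError
from .zonal import ZonalAssignment, assign_pixels

GROUPS = ("artificial", "non_vegetated_open", "vegetated", "water")


@dataclass
class ClassGrouping:
    """Map from 3-digit land-cover codes to exposure groups."""

    code_to_group: dict[int, str]
    numerator_groups: frozenset[str] = field(
        default_factory=lambda: frozenset({"artificial", "non_vegetated_open"})
    )

    def __post_init__(self) -> None:
        if not self.numerator_groups:
            raise SchemaError("numerator_groups must be non-empty")
        unknown = set(self.code_to_group.values()) - set(GROUPS)
        if unknown:
            raise SchemaError(f"unknown groups in grouping: {sorted(unknown)}")
        bad = self.numerator_groups - set(GROUPS)
        if bad:
            raise SchemaError(f"numerator groups not defined: {sorted(bad)}")

    def group_of(self, code: int) -> str:
        try:
            return self.code_to_group[int(code)]
        except KeyError:
            raise UnknownClassError(
                f"land-cover code {code} is not in the configured classification"
            ) from None


def read_grouping(path: str | Path) -> ClassGrouping:
    """Read a ``code,group`` per-line grouping config (# comments allowed)."""
    mapping: dict[int, str] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        code_s, group = (s.strip() for s in line.split(",", 1))
        code = int(code_s)
        if code in mapping:
            raise SchemaError(f"code {code} mapped twice in {path}")
        mapping[code] = group
    if not mapping:
        raise SchemaError(f"empty grouping config {path}")
    return ClassGrouping(mapping)


def default_grouping() -> ClassGrouping:
    """The shipped 44-class CORINE grouping.

    Codes 111–142 are artificial, 331–335 open with little or no
    vegetation, 211–324 vegetated (agriculture, forest, scrub), 411–523
    wetlands and water.
    """
    ref = resources.files("heatvuln").joinpath("data/corine_groups.txt")
    with resources.as_file(ref) as path:
        grouping = read_grouping(path)
    if len(grouping.code_to_group) != 44:
        raise SchemaError("shipped CORINE grouping must cover exactly 44 classes")
    return grouping


def unit_group_fractions(
    raster: RasterGrid,
    units: AdminUnitSet,
    grouping: ClassGrouping | None = None,
    assignment: ZonalAssignment | None = None,
) -> tuple[dict[str, dict[str, float]], set[str]]:
    """Per-unit fraction of valid pixels in each exposure group.

    Returns ``(fractions, missing)`` where missing holds units with zero
    valid pixels.  Fractions over the four groups sum to 1 per unit.
    """
    if raster.semantics != "landcover_code":
        raise AlignmentError("unit_group_fractions expects a land-cover raster")
    grouping = grouping or default_grouping()
    if assignment is None:
        assignment = assign_pixels(raster, units)

    codes = raster.values.ravel()
    idx = assignment.unit_index.ravel()
    valid = (idx >= 0) & raster.valid_mask().ravel()
    present = np.unique(codes[valid])
    group_pos = {g: i for i, g in enumerate(GROUPS)}
    code_group = {int(c): group_pos[grouping.group_of(int(c))] for c in present}

    n_units = len(assignment.unit_ids)
    counts = np.zeros((n_units, len(GROUPS)), dtype=np.int64)
    gvec = np.array([code_group[int(c)] for c in codes[valid]])
    np.add.at(counts, (idx[valid], gvec), 1)

    fractions: dict[str, dict[str, float]] = {}
    missing: set[str] = set()
    for i, uid in enumerate(assignment.unit_ids):
        total = counts[i].sum()
        if total == 0:
            missing.add(uid)
        else:
            fractions[uid] = {g: counts[i, j] / total for g, j in group_pos.items()}
    return fractions, missing


def unit_exposed_fraction(
    raster: RasterGrid,
    units: AdminUnitSet,
    grouping: ClassGrouping | None = None,
    assignment: ZonalAssignment | None = None,
) -> IndicatorColumn:
    """Fraction of each unit's valid pixels in the numerator groups."""
    grouping = grouping or default_grouping()
    fractions, missing = unit_group_fractions(raster, units, grouping, assignment)
    values = {
        uid: sum(fr[g] for g in grouping.numerator_groups)
        for uid, fr in fractions.items()
    }
    return IndicatorColumn(
        name="artificial_fraction",
        values=values,
        orientation="risk",
        missing=missing,
        units_label="proportion",
    )
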