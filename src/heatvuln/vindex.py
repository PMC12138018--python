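"""Composite heatwave-vulnerability index.

The four indicators — mean summer surface temperature, deprivation
score, artificial/non-vegetated surface fraction, air-conditioning
equipment rate — are standardised as Z-scores over the full non-missing
unit set, oriented (air conditioning is the single protective layer),
and combined with equal weights:

    V_i = (z_temp,i + z_fdep,i + z_artif,i − z_ac,i) / 4

The mean of signed z-scores keeps V on a z-like scale.  Units are then
classed into k quantile bins (k = 5 by default, the quintile convention
of heat-vulnerability choropleths) for mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import AdminUnit, AdminUnitSet, IndicatorColumn
from .errors import DegenerateVarianceError, OrientationError, SchemaError

INDICATOR_NAMES = ("temperature", "fdep", "artificial_fraction", "ac_rate")


def zscore(column: IndicatorColumn) -> IndicatorColumn:
    """Standardise over non-missing units: z = (x − μ)/σ, population σ.

    Missing entries stay missing.  Requires ≥ 2 non-missing values with
    non-zero dispersion.
    """
    ids = list(column.values)
    x = np.array([column.values[u] for u in ids], dtype=float)
    if len(x) < 2:
        raise SchemaError(
            f"indicator {column.name!r}: need >= 2 non-missing values to z-score"
        )
    sd = x.std(ddof=0)
    if sd == 0:
        raise DegenerateVarianceError(
            f"indicator {column.name!r} has zero dispersion"
        )
    z = (x - x.mean()) / sd
    return column.with_values(dict(zip(ids, z.astype(float))), set(column.missing))


@dataclass(frozen=True)
class ImputationPolicy:
    """How to fill missing indicator values before compositing.

    ``drop`` leaves them missing (excluded downstream);
    ``department_median`` fills with the median of non-missing units in
    the same department; ``neighbour_mean`` with the mean over
    polygon-adjacent non-missing units.  By default only the
    deprivation score is imputable — temperature and land-cover
    missingness is structural.
    """

    mode: str = "department_median"
    applies_to: frozenset[str] = field(default_factory=lambda: frozenset({"fdep"}))

    def __post_init__(self) -> None:
        if self.mode not in ("drop", "department_median", "neighbour_mean"):
            raise SchemaError(f"unknown imputation mode {self.mode!r}")


def impute(
    column: IndicatorColumn,
    units: AdminUnitSet,
    policy: ImputationPolicy,
) -> IndicatorColumn:
    """Apply the imputation policy to one indicator column.

    Units that cannot be imputed under their policy (whole department
    missing, no non-missing neighbour) stay missing.  Imputed units are
    flagged in ``column.imputed``.
    """
    if policy.mode == "drop" or column.name not in policy.applies_to:
        return column
    if not column.missing:
        return column
    values = dict(column.values)
    missing = set(column.missing)
    imputed = set(column.imputed)
    for uid in sorted(column.missing):
        unit = units.get(uid)
        if policy.mode == "department_median":
            donors = [
                column.values[u.unit_id]
                for u in units
                if u.department_id == unit.department_id
                and u.unit_id in column.values
            ]
            fill = float(np.median(donors)) if donors else None
        else:  # neighbour_mean
            donors = [
                column.values[u.unit_id]
                for u in units
                if u.unit_id != uid
                and u.unit_id in column.values
                and u.geometry.intersects(unit.geometry)
            ]
            fill = float(np.mean(donors)) if donors else None
        if fill is not None:
            values[uid] = fill
            missing.discard(uid)
            imputed.add(uid)
    return column.with_values(values, missing, imputed)


@dataclass
class VulnerabilityScore:
    """Per-unit z-scores, composite index and mapping class."""

    unit_id: str
    z_temperature: float
    z_fdep: float
    z_artificial: float
    z_ac: float
    index: float
    quantile_class: int | None = None
    imputed: set[str] = field(default_factory=set)
    missing: bool = False


def composite_index(
    z_temp: IndicatorColumn,
    z_fdep: IndicatorColumn,
    z_artif: IndicatorColumn,
    z_ac: IndicatorColumn,
) -> list[VulnerabilityScore]:
    """Equal-weight combination of the four oriented z-score columns.

    Each indicator carries weight 1/4; the protective indicator (air
    conditioning) enters with a negative sign.  A unit missing any
    indicator is scored missing.
    """
    columns = {
        "temperature": z_temp,
        "fdep": z_fdep,
        "artificial_fraction": z_artif,
        "ac_rate": z_ac,
    }
    for name, col in columns.items():
        if col.orientation not in ("risk", "protective"):
            raise OrientationError(f"indicator {name!r} has no orientation")
    for name in ("temperature", "fdep", "artificial_fraction"):
        if columns[name].orientation != "risk":
            raise OrientationError(f"indicator {name!r} must be risk-oriented")
    if z_ac.orientation != "protective":
        raise OrientationError("ac_rate must be protective-oriented")

    all_ids = sorted(
        set().union(*(col.unit_ids for col in columns.values()))
    )
    scores: list[VulnerabilityScore] = []
    for uid in all_ids:
        vals = {name: col.values.get(uid) for name, col in columns.items()}
        imputed = {
            name for name, col in columns.items() if uid in col.imputed
        }
        if any(v is None for v in vals.values()):
            scores.append(
                VulnerabilityScore(
                    unit_id=uid,
                    z_temperature=np.nan,
                    z_fdep=np.nan,
                    z_artificial=np.nan,
                    z_ac=np.nan,
                    index=np.nan,
                    imputed=imputed,
                    missing=True,
                )
            )
            continue
        v = (
            vals["temperature"]
            + vals["fdep"]
            + vals["artificial_fraction"]
            - vals["ac_rate"]
        ) / 4.0
        scores.append(
            VulnerabilityScore(
                unit_id=uid,
                z_temperature=vals["temperature"],
                z_fdep=vals["fdep"],
                z_artificial=vals["artificial_fraction"],
                z_ac=vals["ac_rate"],
                index=float(v),
                imputed=imputed,
            )
        )
    return scores


def quantile_classes(scores: Iterable[VulnerabilityScore], k: int = 5) -> None:
    """Assign 1..k quantile classes in place over non-missing scores.

    Class c is the smallest c with V_i ≤ the c-th k-quantile (linear
    interpolation, inclusive upper edges).  With fewer distinct values
    than k the classes collapse to the distinct values, with a warning.
    """
    scores = list(scores)
    if k < 2:
        raise SchemaError("quantile_classes: k must be >= 2")
    live = [s for s in scores if not s.missing]
    if len(live) < k:
        raise SchemaError(
            f"quantile_classes: need >= {k} non-missing scores, got {len(live)}"
        )
    v = np.array([s.index for s in live])
    distinct = np.unique(v)
    if len(distinct) < k:
        warnings.warn(
            f"only {len(distinct)} distinct index values; classes collapse "
            "to distinct values",
            stacklevel=2,
        )
        for s in live:
            s.quantile_class = int(np.searchsorted(distinct, s.index) + 1)
        return
    edges = np.quantile(v, [c / k for c in range(1, k)], method="linear")
    for s in live:
        s.quantile_class = int(np.sum(s.index > edges) + 1)


def scores_frame(scores: Iterable[VulnerabilityScore]) -> pd.DataFrame:
    """Tabular view of the score set, one row per unit."""
    rows = [
        {
            "unit_id": s.unit_id,
            "z_temperature": s.z_temperature,
            "z_fdep": s.z_fdep,
            "z_artificial": s.z_artificial,
            "z_ac": s.z_ac,
            "index": s.index,
            "quantile_class": s.quantile_class,
            "imputed": ";".join(sorted(s.imputed)),
            "missing": s.missing,
        }
        for s in scores
    ]
    return pd.DataFrame(rows).set_index("unit_id")
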