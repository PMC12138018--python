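"""iCanicule heat-morbidity indicator.

Syndromic surveillance counts of emergency-department (OSCOUR-style)
and emergency-GP (SOS Médecins-style) visits for the four heat-related
causes — hyperthermia, heatstroke, dehydration, hyponatremia —
aggregated per administrative unit over a summer window.  Units with no
visits count 0 (absence of events is information, not missingness); no
small-count suppression or spatial smoothing is applied.

Cause matching is prefix-based on diagnosis codes; the shipped default
is the obvious ICD-10 reading (T67 heat effects, E86 volume depletion,
E87.1 hypo-osmolality/hyponatremia) and is user-overridable.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import AdminUnitSet, VisitRecord
from .errors import ParseError, SchemaError

CATEGORIES = ("hyperthermia_heatstroke", "dehydration", "hyponatremia")

DEFAULT_CAUSE_PREFIXES = (
    ("T67", "hyperthermia_heatstroke"),
    ("E86", "dehydration"),
    ("E87.1", "hyponatremia"),
)


@dataclass(frozen=True)
class CauseMap:
    """Prefix → category map over diagnosis codes.

    Prefixes must be non-overlapping: no code may match two categories,
    so no pattern may be a prefix of another.
    """

    patterns: tuple[tuple[str, str], ...] = DEFAULT_CAUSE_PREFIXES

    def __post_init__(self) -> None:
        prefixes = [p for p, _ in self.patterns]
        for i, a in enumerate(prefixes):
            for b in prefixes[i + 1 :]:
                if a.startswith(b) or b.startswith(a):
                    raise SchemaError(
                        f"cause prefixes {a!r} and {b!r} overlap; "
                        "a code could match two categories"
                    )
        bad = {c for _, c in self.patterns} - set(CATEGORIES)
        if bad:
            raise SchemaError(f"unknown cause categories: {sorted(bad)}")

    def category_of(self, cause_code: str) -> str | None:
        for prefix, category in self.patterns:
            if cause_code.startswith(prefix):
                return category
        return None


def read_cause_map(path: str | Path) -> CauseMap:
    """Read a ``prefix,category`` per-line cause config (# comments allowed)."""
    patterns = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        prefix, category = (s.strip() for s in line.split(",", 1))
        patterns.append((prefix, category))
    if not patterns:
        raise SchemaError(f"empty cause map {path}")
    return CauseMap(tuple(patterns))


@dataclass
class VisitRecordSet:
    """Visit events plus CSV I/O (schema: unit_id, date, source, cause_code)."""

    records: list[VisitRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VisitRecordSet":
        df = pd.read_csv(path, dtype=str)
        for col in ("unit_id", "date", "source", "cause_code"):
            if col not in df.columns:
                raise SchemaError(f"visit table missing column {col!r}")
        records = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                date = datetime.date.fromisoformat(row.date)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {i + 1}: malformed date {row.date!r} (expected ISO-8601)"
                ) from exc
            records.append(
                VisitRecord(
                    unit_id=str(row.unit_id),
                    date=date,
                    source=str(row.source),
                    cause_code=str(row.cause_code),
                )
            )
        return cls(records)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "unit_id": [r.unit_id for r in self.records],
                "date": [r.date.isoformat() for r in self.records],
                "source": [r.source for r in self.records],
                "cause_code": [r.cause_code for r in self.records],
            }
        ).to_csv(path, index=False)


def filter_heat_visits(
    records: VisitRecordSet,
    causes: CauseMap,
    window: tuple[datetime.date, datetime.date],
) -> tuple[VisitRecordSet, int]:
    """Keep visits inside the closed date window with a heat cause code.

    Returns ``(kept, n_dropped)``; kept + dropped = input size.
    """
    start, end = window
    if start > end:
        raise SchemaError(f"window start {start} is after end {end}")
    kept = [
        r
        for r in records
        if start <= r.date <= end and causes.category_of(r.cause_code) is not None
    ]
    return VisitRecordSet(kept), len(records) - len(kept)


@dataclass
class MorbidityIndicator:
    """Per-unit heat-morbidity counts for one period."""

    unit_id: str
    count: int
    by_source: dict[str, int]
    by_category: dict[str, int]
    rate_per_10k: float | None  # defined iff population > 0
    period: tuple[datetime.date, datetime.date]

    def __post_init__(self) -> None:
        if sum(self.by_source.values()) != self.count:
            raise SchemaError(
                f"unit {self.unit_id!r}: source counts do not sum to total"
            )
        if sum(self.by_category.values()) != self.count:
            raise SchemaError(
                f"unit {self.unit_id!r}: category counts do not sum to total"
            )


def aggregate_indicator(
    records: VisitRecordSet,
    units: AdminUnitSet,
    causes: CauseMap | None = None,
    period: tuple[datetime.date, datetime.date] | None = None,
) -> tuple[dict[str, MorbidityIndicator], list[VisitRecord]]:
    """Aggregate filtered visit records per unit.

    Every unit gets an indicator (count 0 if no records).  Records whose
    ``unit_id`` is absent from the unit set are returned as orphans, so
    per-unit counts + orphans always reconcile with the input.
    """
    causes = causes or CauseMap()
    if period is None:
        dates = [r.date for r in records]
        today = datetime.date.today()
        period = (min(dates, default=today), max(dates, default=today))

    known = set(units.unit_ids)
    per_unit: dict[str, list[VisitRecord]] = {uid: [] for uid in known}
    orphans: list[VisitRecord] = []
    for r in records:
        if r.unit_id in known:
            per_unit[r.unit_id].append(r)
        else:
            orphans.append(r)

    out: dict[str, MorbidityIndicator] = {}
    for u in units:
        recs = per_unit[u.unit_id]
        by_source = {"emergency_department": 0, "emergency_gp": 0}
        by_category = {c: 0 for c in CATEGORIES}
        for r in recs:
            by_source[r.source] += 1
            cat = causes.category_of(r.cause_code)
            if cat is None:
                raise SchemaError(
                    f"unfiltered record with non-heat cause {r.cause_code!r}; "
                    "run filter_heat_visits first"
                )
            by_category[cat] += 1
        count = len(recs)
        rate = 10_000.0 * count / u.population if u.population > 0 else None
        out[u.unit_id] = MorbidityIndicator(
            unit_id=u.unit_id,
            count=count,
            by_source=by_source,
            by_category=by_category,
            rate_per_10k=rate,
            period=period,
        )
    return out, orphans


def indicator_frame(indicators: dict[str, MorbidityIndicator]) -> pd.DataFrame:
    """Tabular view: counts, source/category splits, rate per 10 000."""
    rows = []
    for uid in sorted(indicators):
        ind = indicators[uid]
        row = {
            "unit_id": uid,
            "visits": ind.count,
            "visits_ed": ind.by_source["emergency_department"],
            "visits_gp": ind.by_source["emergency_gp"],
            "rate_per_10k": ind.rate_per_10k,
        }
        for c in CATEGORIES:
            row[f"visits_{c}"] = ind.by_category[c]
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")
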